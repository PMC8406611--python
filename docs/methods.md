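# Methods

## Problem

Targeted gene panels sequence the exons (plus small flanks) of a gene set to
high depth, leaving coverage deep but discontinuous. Single-exon and
partial-exon copy number variants (CNVs) are invisible to SNV/indel callers
and poorly resolved by exome-scale CNV tools, whose windows are larger than a
panel exon. `panelcnv` infers copy number from read depth: a heterozygous
deletion halves the expected depth over its span, a heterozygous duplication
raises it to 3/2, and a mosaic event shifts it by the fraction of affected
cells.

## Model

### Target-region-based sliding windows (TRSW)

Each target region of length `L_TR` is tiled with windows of length `L_SW`
(default 75 nt) advancing by `L_SL` (default 10 nt), so adjacent windows
overlap by `L_SW − L_SL` = 65 nt. The window count is

```
N_SW = floor((L_TR − L_SW) / L_SL) + 1
```

with two boundary rules: a region no longer than `L_SW` gets a single window
spanning the whole region, and the last window of a region absorbs the
division remainder `(L_TR − L_SW) mod L_SL`, ending exactly at the region
end. Windows never cross region boundaries. Coordinates are 0-based
half-open internally; per-locus I/O uses 1-based positions.

The overlap means one sliding step changes only `L_SL` of the `L_SW`
positions in a window, so a copy-number step inside an exon moves the window
mean gradually — this is what gives the method sub-exon breakpoint
resolution (about one slide length).

### Static pools of normals

Reference coverage comes from CNV-free ("normal") samples sequenced with the
same capture design. Normals with mean panel depth above a cutoff (default
100×) are sorted by ascending mean depth, and every window of `K` consecutive
samples forms a pool: `N` normals yield `M = N − K + 1` overlapping pools,
consecutive pools sharing `K − 1` members. Each pool stores `mean_TRSW`, the
per-window vector of the unweighted mean of its members' window mean depths,
plus a per-position mean depth track used for breakpoint refinement. For a
query, the pool whose overall mean depth is nearest the query's is selected
(ties go to the lower-depth pool). Pools are bound to a capture-kit lot;
scoring a query against pools from a different lot is refused unless
explicitly overridden, because lot-to-lot capture-efficiency differences
masquerade as CNVs.

### Scoring

Per window `w`:

```
logCNR(w) = log2( mean_depth_query(w) / mean_TRSW(w) )
```

Theoretical values: −1.0 for a heterozygous deletion, 0.0 for normal copy
number, +0.58 (= log2(3/2)) for a heterozygous duplication, and
log2(1 − f/2) for a single-allele deletion mosaic in a fraction `f` of cells
(f = 0.3 → ≈ −0.234). Two numerical guards:

- if the pool's window mean is below `min_pool_depth` (default 20×) the
  window is a no-call (NaN) — the reference is too shallow to divide by;
- if the query window mean is 0 against an adequate pool, the score is set
  to a finite floor (default −6.0) and the window is flagged as a possible
  homozygous deletion, instead of −∞.

### Candidate flagging

Deletion candidates are maximal runs of consecutive windows with score ≤
−0.5; duplication candidates use ≥ +0.3; both require at least 3 consecutive
windows (defaults). The duplication threshold is more permissive than the
deletion one because the duplication signal (+0.58) sits closer to 0 than
the deletion signal (−1.0). Runs never cross gene boundaries. An opt-in
mosaic pass re-scans with a low-stringency threshold (≤ −0.15) but a longer
required run (10 windows), labels its hits "possible mosaic", and skips
spans already found by the main pass.

### Breakpoint refinement

The union of flagged 75-nt windows localizes a breakpoint only to roughly
the window length. When per-base query depths and the pool's per-position
mean track are available, each coarse edge is refined by a least-squares
step fit on the per-base depth ratio within ±`L_SW` of the edge: the change
point minimizing the residual of a two-level (1 → ρ) step model. On
noise-free data this recovers breakpoints exactly; with the default 5% noise
it stays within a few bases. Without per-base data, the fallback inverts the
transition-window mean: a window straddling a breakpoint has ratio
`1 − f (1 − ρ_in)` where `f` is the fraction of the window inside the event,
solvable for the edge when `0.15 < f < 0.85`. The reported
`breakpoint_resolution` is one slide length (10 nt), the method's designed
resolution.

### Quality control

Three gates, in the order a diagnostic workflow applies them:

1. **Depth deviation** — `100 · |d_query − d_pool| / d_pool` must not exceed
   5%. The logCNR baseline shifts by `log2(d_query/d_pool)`; at 5% that is
   ±0.07, small against the ±0.3/−0.5 thresholds. A failing sample is
   re-tried against an updated pool set if provided, otherwise scoring stops
   with an escalation (re-sequencing or an orthogonal test such as MLPA).
   Samples failing this gate are *not interpreted* — all specificity numbers
   in the acceptance harness are computed over gate-passing samples, with
   escalated counts reported separately.
2. **Pool uniformity** — the coefficient of variation of the pool members'
   mean depths (sample SD, ddof = 1) must stay below 15%; otherwise the
   next-nearest pool is suggested.
3. **Run-wise cross-check** — the query is also scored against a pool built
   from the other samples of its own sequencing run (query excluded,
   minimum 3 members); windows where static and run-wise scores differ by
   more than 0.3 are flagged. Batch effects hit this check first.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `window_len` | 75 | nt | near the smallest panel exons; deep panels give stable means at this size |
| `slide_len` | 10 | nt | breakpoint resolution target; 65-nt overlap smooths step transitions |
| `pool_size` (K) | user-set (8 in examples) | samples | large enough to damp member noise, small enough to keep pools depth-homogeneous |
| `min_normal_depth` | 100 | × | below this, window means are too noisy to serve as reference |
| `deviation_cutoff_pct` | 5 | % | limits baseline shift to ±0.07 logCNR |
| `max_pool_cv_pct` | 15 | % | heterogeneous pools blur the reference |
| `runwise_delta_threshold` | 0.3 | logCNR | matches the duplication threshold: a disagreement this large can change a call |
| `min_pool_depth` | 20 | × | no-call guard for shallow reference windows |
| `floor_score` | −6.0 | logCNR | finite stand-in for log2(0); far below any real heterozygous signal |
| `del_threshold` | −0.5 | logCNR | midpoint between 0 and the −1.0 deletion signal |
| `dup_threshold` | +0.3 | logCNR | roughly midpoint between 0 and +0.58 |
| `min_consecutive` | 3 | windows | one noisy window cannot create a candidate |
| `mosaic_del_threshold` | −0.15 | logCNR | below typical noise, above a 30% mosaic's −0.234 |
| `mosaic_min_consecutive` | 10 | windows | compensates the permissive threshold with required extent |
| `min_mapq` | 20 | phred | standard mapping-quality floor for pileups |

A note on threshold monotonicity: making a threshold stricter always shrinks
the set of flagged *windows*, but can *increase* the number of candidate
runs (a long run can split into two). Tests assert the window-count
monotonicity and the candidate-count monotonicity in `min_consecutive`,
which are the forms that actually hold.

## The simulator

`panelcnv.synthetic` generates per-base integer depths as

```
depth(pos) = rint( base_depth · sample_scale · region_efficiency
                   · lot_effect · copy_ratio(pos) · block_noise(pos) )
```

- `region_efficiency`: one log-normal factor per region
  (`exp(N(0, capture_efficiency_sd))`, default sd 0.3), shared by all
  samples — capture efficiency varies strongly between probes;
- `lot_effect`: per-region log-normal multipliers shared by all samples of
  the same capture-kit lot (sd 0.1) — the batch effect the lot guard exists
  for;
- `sample_scale`: per-sample log-normal library-depth factor (sd 0.15);
- `block_noise`: one mean-1 log-normal factor per non-overlapping
  window-length block of each region, with coefficient of variation
  `noise_cv` (default 0.05), so *window mean* depths fluctuate at roughly
  that CV. Overlapping windows share blocks, preserving the spatial
  correlation that consecutive-window run rules rely on;
- `copy_ratio(pos)`: 1 outside events; 0.5 / 1.5 / 0 / 1 − f/2 inside, applied
  exactly over the event's genomic interval so partial-exon breakpoints
  land mid-region.

What it deliberately does **not** emulate: GC-content coupling between
efficiency and sequence, mappability, insert-size effects, allele-specific
capture bias, per-base (as opposed to per-block) overdispersion, and read
sampling noise (depths are rounded expectations, not Poisson draws). It is a
test harness for the normalization and detection logic, not a sequencing
simulator.

Default problem size (this package's choice for its own validation): 126
regions of 100–350 nt across 21 synthetic genes (~29 000 targeted positions,
~2 000 windows), 20 normals at ~200×. A full cohort simulation plus scoring
of all samples runs in well under 2 s on one CPU.

## Numerical choices

- Window means are computed from a cumulative sum over the flat per-position
  depth array with precomputed per-window index ranges — O(positions) per
  sample, no per-window loops.
- Pool `mean_TRSW` is the unweighted mean of member window means; member
  depth CV is computed with ddof = 1.
- Scores use IEEE double throughout; NaN encodes no-call, a documented
  finite floor encodes "depth zero".
- All randomness in the simulator flows from one `numpy` `Generator` seeded
  by the config; identical configs reproduce cohorts byte-for-byte.

## Limitations

- Sensitivity claims here are established on simulated cohorts only; the
  generator's noise is multiplicative log-normal and spatially blocked,
  which is kinder than some real capture artifacts.
- The method assumes the pool samples are genuinely CNV-free over the panel;
  a common CNV present in pool members suppresses (and self-inclusion of the
  query attenuates) the signal — for pool size K the attenuated deletion
  score is log2(0.5K/(K−0.5)) instead of −1.
- Breakpoint refinement assumes a single step per candidate edge; nested or
  adjacent events inside one refinement window are not modeled.
- Cross-lot scoring is refused rather than corrected; no in-silico batch
  correction is attempted.
- Chromosome-scale events, inversions, and copy-neutral LOH are out of
  scope: only depth-visible deletions/duplications over targeted regions are
  callable.
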
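# panelcnv

Read-depth CNV detection for targeted gene-panel sequencing: sliding-window
coverage, static pools of normal samples, per-window log2 copy-number-ratio
scoring, QC gates, candidate reporting, and a synthetic-coverage simulator
for end-to-end validation.

## The problem

Capture-based gene panels sequence selected exons to great depth, but the
coverage is discontinuous: exon-sized islands separated by kilobases. Exon-
and sub-exon-scale copy number variants (CNVs) — single-exon deletions,
partial-exon deletions, low-fraction mosaics — are below the resolution of
exome/genome CNV callers and invisible to SNV pipelines, yet they are
clinically decisive in many diagnostic panels. The read-depth signal is
simple: a heterozygous deletion halves expected coverage over its span, a
heterozygous duplication multiplies it by 3/2, and a mosaic in a fraction
`f` of cells shifts it to `1 − f/2`. The difficulty is normalization —
capture efficiency varies by orders between probes, libraries are sequenced
to different depths, and capture-kit lots differ systematically.

## The method

1. **TRSW windows.** Every target region of length `L_TR` is tiled with
   windows of `L_SW` = 75 nt sliding by `L_SL` = 10 nt (65 nt overlap):
   `N_SW = floor((L_TR − L_SW)/L_SL) + 1`, short regions get one window, the
   last window absorbs the remainder. Windows never cross region boundaries.
2. **Static pools.** Normals above 100× mean depth are sorted by depth; each
   window of `K` consecutive samples is a pool (`N` normals → `N − K + 1`
   pools sharing `K − 1` members). A query is scored against the pool with
   the nearest mean depth; pools are bound to a capture-kit lot.
3. **Scoring.** Per window, `logCNR = log2(query mean / pool mean_TRSW)`.
   Theory: −1.0 heterozygous deletion, 0.0 normal, +0.58 heterozygous
   duplication, ≈ −0.234 for a 30% mosaic deletion.
4. **QC.** Query/pool mean-depth deviation ≤ 5% (else escalate), pool member
   CV ≤ 15%, and a run-wise cross-check against the query's own sequencing
   run (per-window |Δ| ≤ 0.3).
5. **Candidates.** Runs of ≥ 3 consecutive windows beyond −0.5 (deletion) or
   +0.3 (duplication); opt-in mosaic pass at −0.15 over ≥ 10 windows;
   per-base step-fit breakpoint refinement to ~slide-length resolution.

See [docs/methods.md](docs/methods.md) for the full model, parameter
rationale, simulator scope, and limitations.

## Worked example

`examples/02_simulate_and_score.py` simulates 20 normals plus one query
carrying a heterozygous single-exon deletion, builds pools, scores the
query, and flags candidates:

```text
panel: 126 regions, 2120 windows; deletion injected at chr1:84934-85199 (GENE005)
pools: 13 overlapping pools of 8 from 20 normals
selected pool 6: mean depth 219.7x vs query 218.5x -> deviation 0.52% (interpretable)
mean logCNR inside the deleted exon: -0.997 (theory: -1.0)
mean logCNR elsewhere: 0.006 (theory: 0.0)
candidate: deletion chr1:84934-85199 in GENE005, 20 windows, mean score -0.997
one candidate, matching the injected span
```

The other examples cover window geometry (`01`), mosaic detection with the
low-stringency pass (`03`), and the three QC gates including an escalated
over-sequenced library (`04`).

## Command line

The same pipeline as a shell tool (exit codes: 0 ok, 2 QC failure, 3 input
error):

```bash
panelcnv simulate  --out cohort/ --seed 1 --with-events
panelcnv make-pools --bed cohort/panel.bed --coverage-dir cohort/ \
                    --out pools/ -k 8
panelcnv score     --bed cohort/panel.bed --pools pools/ \
                    --query cohort/EV03.coverage.tsv --out scores/
panelcnv qc        --bed cohort/panel.bed --pools pools/ \
                    --query cohort/NORM001.coverage.tsv --out qc.tsv
panelcnv report    --bed cohort/panel.bed --scores scores/EV03.logcnr.tsv \
                    --out report/
```

Coverage can come from per-locus TSV files (`Locus<TAB>Total_Depth`, 1-based
`chrom:pos`) or directly from indexed BAMs via
`panelcnv.compute_bam_coverage` (mapping-quality ≥ 20, duplicates excluded
by default).

## Layout

```
src/panelcnv/    library (windows, coverage, pooling, scoring, qc,
                 reporting, synthetic, pipeline, config, cli)
examples/        four narrative scripts, each printing computed numbers
tests/           unit, property-based, and acceptance tests
scripts/         acceptance.py — recompute the headline numbers
docs/methods.md  model, parameters, simulator scope, limitations
```
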
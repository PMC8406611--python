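"""Synthetic deep-panel coverage with injected CNV events.

The generator emulates the statistical structure that pool-based read-depth
CNV calling relies on, so that every pipeline stage is testable without
sequencing data:

* a panel of target regions (synthetic genes, each a handful of
  exon-sized regions) on one synthetic chromosome;
* per-region capture efficiency (log-normal across regions, shared by all
  samples — deep panels cover different regions at very different depths);
* per-lot capture batch effects (log-normal per-region multipliers shared
  by every sample sequenced with the same capture-kit lot);
* per-sample depth scaling (libraries are sequenced to different depths);
* multiplicative log-normal noise at probe scale: one factor per
  non-overlapping window-length block of each region, so window mean depths
  fluctuate with roughly the configured coefficient of variation;
* CNV events as per-position depth multipliers — 0.5 for a heterozygous
  deletion, 1.5 for a heterozygous duplication, 0.0 for a homozygous
  deletion, and 1 - f/2 for a single-allele deletion mosaic in a fraction
  f of cells — applied exactly over their genomic interval, so partial-exon
  breakpoints land inside regions.

Expected depth at a position is therefore
``base_depth * sample_scale * region_efficiency * lot_effect * copy_ratio``
times noise, rounded to an integer.  A fixed seed reproduces the cohort
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import SampleCoverage, write_per_locus_coverage
from .errors import InputError, InvalidParameterError
from .windows import (
    DEFAULT_SLIDE_LEN,
    DEFAULT_WINDOW_LEN,
    TargetRegion,
    WindowTemplate,
    write_bed,
)


@dataclass(frozen=True)
class CNVEvent:
    """One injected CNV: a depth multiplier over a genomic span.

    The span is either a whole synthetic gene (``gene=...``) or an explicit
    interval (``chrom/start/end``), which may cut through a region to model
    partial-exon breakpoints.
    """

    sample_id: str
    copy_ratio: float
    gene: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if self.copy_ratio < 0:
            raise InvalidParameterError(f"copy_ratio must be >= 0, got {self.copy_ratio}")
        explicit = self.chrom is not None and self.start is not None and self.end is not None
        if not explicit and self.gene is None:
            raise InputError("CNVEvent needs either a gene or an explicit chrom/start/end")

    @property
    def direction(self) -> str:
        return "duplication" if self.copy_ratio > 1 else "deletion"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate a 126-region diagnostic panel sequenced to ~200x with
    probe-scale coverage noise of 5% CV, region capture efficiencies
    spreading depths ~exp(N(0, 0.3)) across regions, and per-sample library
    scaling of ~15% (log scale).
    """

    seed: int = 0
    n_regions: int = 126
    n_genes: int = 21
    region_length_range: tuple[int, int] = (100, 350)
    n_normals: int = 20
    n_runs: int = 2
    n_lots: int = 1
    base_depth: float = 200.0
    capture_efficiency_sd: float = 0.3
    lot_effect_sd: float = 0.1
    sample_depth_sd: float = 0.15
    noise_cv: float = 0.05
    window_len: int = DEFAULT_WINDOW_LEN
    slide_len: int = DEFAULT_SLIDE_LEN
    events: list[CNVEvent] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_regions < 1:
            raise InputError(f"n_regions must be >= 1, got {self.n_regions}")
        if self.n_genes < 1 or self.n_genes > self.n_regions:
            raise InputError(
                f"n_genes must be in [1, n_regions], got {self.n_genes}"
            )
        lo, hi = self.region_length_range
        if lo < 1 or hi < lo:
            raise InputError(f"degenerate region_length_range {self.region_length_range}")
        if self.base_depth <= 0:
            raise InputError(f"base_depth must be > 0, got {self.base_depth}")
        for name in ("capture_efficiency_sd", "lot_effect_sd", "sample_depth_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.n_runs < 1 or self.n_lots < 1 or self.n_lots > self.n_runs:
            raise InputError("need 1 <= n_lots <= n_runs")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    run_id: str = "run_1"
    lot_id: str = "lot_1"
    depth_scale: float | None = None  # None: drawn from the sample-scale model
    events: tuple[CNVEvent, ...] = ()


@dataclass
class SyntheticCohort:
    """A simulated cohort: coverage, sample manifest, and the event truth set."""

    config: SimulationConfig
    regions: list[TargetRegion]
    template: WindowTemplate
    samples: list[SampleCoverage]
    manifest: pd.DataFrame
    truth: pd.DataFrame

    def sample(self, sample_id: str) -> SampleCoverage:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise InputError(f"no sample '{sample_id}' in cohort")

    def normals(self) -> list[SampleCoverage]:
        normal_ids = set(self.manifest.loc[self.manifest["is_normal"], "sample_id"])
        return [s for s in self.samples if s.sample_id in normal_ids]

    def event_samples(self) -> list[SampleCoverage]:
        ids = set(self.manifest.loc[~self.manifest["is_normal"], "sample_id"])
        return [s for s in self.samples if s.sample_id in ids]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_bed(self.regions, directory / "panel.bed")
        for s in self.samples:
            write_per_locus_coverage(s, directory / f"{s.sample_id}.coverage.tsv")
        self.manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None
                   ) -> list[TargetRegion]:
    """Synthetic panel: n_regions exon-sized intervals split across n_genes."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.region_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_regions)
    gaps = rng.integers(500, 5001, size=config.n_regions)
    # regions per gene: as even a split as possible
    per_gene = np.full(config.n_genes, config.n_regions // config.n_genes)
    per_gene[: config.n_regions % config.n_genes] += 1
    gene_of_region = np.repeat(np.arange(config.n_genes), per_gene)

    regions = []
    pos = 10_000
    exon_no = 0
    prev_gene = -1
    for i in range(config.n_regions):
        g = int(gene_of_region[i])
        exon_no = exon_no + 1 if g == prev_gene else 1
        prev_gene = g
        start = pos + int(gaps[i])
        end = start + int(lengths[i])
        regions.append(
            TargetRegion("chr1", start, end, gene=f"GENE{g + 1:03d}", label=f"exon{exon_no}")
        )
        pos = end
    return regions


def _event_span(regions: list[TargetRegion], event: CNVEvent) -> tuple[str, int, int]:
    if event.chrom is not None:
        return event.chrom, int(event.start), int(event.end)
    spans = [(r.chrom, r.start, r.end) for r in regions if r.gene == event.gene]
    if not spans:
        raise InputError(f"event gene '{event.gene}' not in panel")
    chrom = spans[0][0]
    return chrom, min(s for _, s, _ in spans), max(e for _, _, e in spans)


def _copy_ratio_track(
    regions: list[TargetRegion],
    template: WindowTemplate,
    events: tuple[CNVEvent, ...],
) -> np.ndarray:
    ratio = np.ones(template.n_positions)
    for ev in events:
        chrom, start, end = _event_span(regions, ev)
        hit = False
        offset = 0
        for r in regions:
            if r.chrom == chrom:
                lo, hi = max(start, r.start), min(end, r.end)
                if hi > lo:
                    ratio[offset + lo - r.start : offset + hi - r.start] = ev.copy_ratio
                    hit = True
            offset += r.length
        if not hit:
            raise InputError(
                f"event {chrom}:{start}-{end} for {ev.sample_id} overlaps no target region"
            )
    return ratio


def _lognormal_mean1(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal factors with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _block_noise(
    regions: list[TargetRegion],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multiplicative factor per window-length block of each region."""
    if config.noise_cv == 0:
        return np.ones(sum(r.length for r in regions))
    parts = []
    for r in regions:
        n_blocks = -(-r.length // config.window_len)
        factors = _lognormal_mean1(rng, config.noise_cv, n_blocks)
        parts.append(np.repeat(factors, config.window_len)[: r.length])
    return np.concatenate(parts)


def simulate_sample(
    regions: list[TargetRegion],
    template: WindowTemplate,
    config: SimulationConfig,
    spec: SampleSpec,
    region_efficiency: np.ndarray,
    lot_effects: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> SampleCoverage:
    """Per-base integer depths for one sample under the cohort's effects."""
    scale = spec.depth_scale
    if scale is None:
        scale = float(np.exp(rng.normal(0.0, config.sample_depth_sd)))
    lot_eff = lot_effects[spec.lot_id]
    region_mult = region_efficiency * lot_eff
    per_pos_mult = np.repeat(region_mult, [r.length for r in regions])
    ratio = _copy_ratio_track(regions, template, spec.events)
    noise = _block_noise(regions, config, rng)
    expected = config.base_depth * scale * per_pos_mult * ratio * noise
    depths = np.rint(expected).astype(np.int64)
    np.clip(depths, 0, None, out=depths)
    return SampleCoverage(
        spec.sample_id, depths, template, run_id=spec.run_id, lot_id=spec.lot_id
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate the panel, the normals, and every event-carrying sample."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = simulate_panel(config, rng)
    template = WindowTemplate(regions, config.window_len, config.slide_len)

    region_efficiency = np.exp(
        rng.normal(0.0, config.capture_efficiency_sd, size=config.n_regions)
    )
    lot_ids = [f"lot_{i + 1}" for i in range(config.n_lots)]
    lot_effects = {
        lot: np.exp(rng.normal(0.0, config.lot_effect_sd, size=config.n_regions))
        for lot in lot_ids
    }
    run_ids = [f"run_{i + 1}" for i in range(config.n_runs)]
    run_lot = {
        run: lot_ids[i * config.n_lots // config.n_runs]
        for i, run in enumerate(run_ids)
    }

    specs: list[SampleSpec] = []
    for i in range(config.n_normals):
        run = run_ids[i % config.n_runs]
        specs.append(
            SampleSpec(f"NORM{i + 1:03d}", run_id=run, lot_id=run_lot[run])
        )
    by_sample: dict[str, list[CNVEvent]] = {}
    for ev in config.events:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    for i, (sid, evs) in enumerate(sorted(by_sample.items())):
        run = run_ids[i % config.n_runs]
        specs.append(
            SampleSpec(sid, run_id=run, lot_id=run_lot[run], events=tuple(evs))
        )

    samples = [
        simulate_sample(regions, template, config, spec, region_efficiency, lot_effects, rng)
        for spec in specs
    ]
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "run_id": [s.run_id for s in samples],
            "lot_id": [s.lot_id for s in samples],
            "is_normal": [len(sp.events) == 0 for sp in specs],
            "mean_depth": [s.mean_depth for s in samples],
        }
    )
    truth_rows = []
    for ev in config.events:
        chrom, start, end = _event_span(regions, ev)
        truth_rows.append(
            {
                "sample_id": ev.sample_id,
                "gene": ev.gene
                or next(
                    (r.gene for r in regions if r.chrom == chrom and r.start < end and start < r.end),
                    "",
                ),
                "chrom": chrom,
                "start": start,
                "end": end,
                "copy_ratio": ev.copy_ratio,
                "direction": ev.direction,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene", "chrom", "start", "end", "copy_ratio", "direction"],
    )
    return SyntheticCohort(
        config=config,
        regions=regions,
        template=template,
        samples=samples,
        manifest=manifest,
        truth=truth,
    )


# ----------------------------------------------------------------------
# canonical event suite used by the validation simulations
# ----------------------------------------------------------------------

def standard_event_suite(regions: list[TargetRegion]) -> list[CNVEvent]:
    """Ten events covering the CNV classes a diagnostic panel must detect.

    One event per sample: whole-gene, multi-exon and single-exon
    heterozygous deletions and duplications, a homozygous whole-gene
    deletion, and two partial-exon deletions with breakpoints inside a
    region.  Genes and regions are chosen deterministically from the panel.
    """
    by_gene: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_gene.setdefault(r.gene, []).append(r)
    genes = [g for g, rs in by_gene.items() if len(rs) >= 3]
    if len(genes) < 10:
        raise InputError("event suite needs at least 10 genes with >= 3 regions")

    def multi_exon_span(gene: str, n_exons: int = 3) -> tuple[str, int, int]:
        rs = by_gene[gene][:n_exons]
        return rs[0].chrom, rs[0].start, rs[-1].end

    def long_region(gene: str, min_len: int = 250) -> TargetRegion:
        cands = [r for r in by_gene[gene] if r.length >= min_len]
        return cands[0] if cands else max(by_gene[gene], key=lambda r: r.length)

    events = [
        CNVEvent("EV01", 0.5, gene=genes[0]),  # whole-gene het deletion
        CNVEvent("EV02", 0.5, chrom=multi_exon_span(genes[1])[0],
                 start=multi_exon_span(genes[1])[1], end=multi_exon_span(genes[1])[2]),
        CNVEvent("EV03", 0.5, chrom=by_gene[genes[2]][1].chrom,
                 start=by_gene[genes[2]][1].start, end=by_gene[genes[2]][1].end),
        CNVEvent("EV04", 1.5, gene=genes[3]),  # whole-gene het duplication
        CNVEvent("EV05", 1.5, chrom=multi_exon_span(genes[4])[0],
                 start=multi_exon_span(genes[4])[1], end=multi_exon_span(genes[4])[2]),
        CNVEvent("EV06", 1.5, chrom=by_gene[genes[5]][1].chrom,
                 start=by_gene[genes[5]][1].start, end=by_gene[genes[5]][1].end),
        CNVEvent("EV07", 0.0, gene=genes[6]),  # homozygous whole-gene deletion
    ]
    # partial-exon deletion: interior chunk, both breakpoints inside the region
    r8 = long_region(genes[7])
    margin = max(30, r8.length // 5)
    events.append(CNVEvent("EV08", 0.5, chrom=r8.chrom,
                           start=r8.start + margin, end=r8.end - margin))
    # single + partial exon deletion: whole first region plus part of the next
    rs9 = by_gene[genes[8]]
    events.append(CNVEvent("EV09", 0.5, chrom=rs9[0].chrom,
                           start=rs9[0].start, end=rs9[1].start + rs9[1].length // 2))
    events.append(CNVEvent("EV10", 0.5, chrom=by_gene[genes[9]][0].chrom,
                           start=by_gene[genes[9]][0].start, end=by_gene[genes[9]][0].end))
    return events


def mosaic_event(regions: list[TargetRegion], sample_id: str = "MOSAIC01",
                 fraction: float = 0.3, n_exons: int = 4, gene: str | None = None
                 ) -> CNVEvent:
    """A multi-exon single-allele deletion mosaic: copy ratio 1 - f/2."""
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"mosaic fraction must be in (0, 1], got {fraction}")
    by_gene: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_gene.setdefault(r.gene, []).append(r)
    if gene is None:
        gene = next(g for g, rs in by_gene.items() if len(rs) >= n_exons)
    rs = by_gene[gene][:n_exons]
    return CNVEvent(
        sample_id, 1.0 - fraction / 2.0, chrom=rs[0].chrom, start=rs[0].start, end=rs[-1].end
    )


def event_free_config(**overrides) -> SimulationConfig:
    """Convenience: the default study conditions without any events."""
    return replace(SimulationConfig(), **overrides)
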
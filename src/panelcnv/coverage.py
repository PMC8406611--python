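"""Per-base coverage over the target panel.

Coverage comes either from a per-locus depth table (the dialect emitted by
standard depth-of-coverage tools: a header line, then ``chrom:pos`` with a
1-based position and a total depth column) or directly from an indexed BAM
by counting aligned read bases over the targeted positions.

Depths are stored as a flat integer array aligned to the template's
position order; targeted positions absent from the input are zero-filled.
Window-level and sample-level mean depths are the two quantities the rest
of the pipeline consumes: the sample mean is taken over unique targeted
positions (not over windows, which overlap and would multiply-count
interior bases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, InputError, InvalidParameterError, ParseError
from .windows import SlidingWindow, WindowTemplate

logger = logging.getLogger("panelcnv")

DEFAULT_MIN_MAPQ = 20


@dataclass
class SampleCoverage:
    """Per-base depths of one sample over all targeted positions."""

    sample_id: str
    depths: np.ndarray  # int64, aligned to template flat position order
    template: WindowTemplate
    run_id: str = ""
    lot_id: str = ""
    _window_means: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.shape != (self.template.n_positions,):
            raise InputError(
                f"depth array of {self.sample_id} has {self.depths.size} positions, "
                f"template has {self.template.n_positions}"
            )
        if (self.depths < 0).any():
            raise InputError(f"negative depths in sample {self.sample_id}")

    @property
    def mean_depth(self) -> float:
        """Mean depth over all unique targeted positions (reads/position)."""
        return float(self.depths.mean())

    def window_means(self) -> np.ndarray:
        """Mean depth of every template window (cached)."""
        if self._window_means is None:
            cs = np.concatenate([[0], np.cumsum(self.depths, dtype=np.float64)])
            t = self.template
            self._window_means = (
                cs[t.window_end_idx] - cs[t.window_start_idx]
            ) / t.window_lengths
        return self._window_means


def sample_mean_depth(cov: SampleCoverage) -> float:
    """Sample-level mean depth over unique targeted positions."""
    return cov.mean_depth


def window_mean_depth(cov: SampleCoverage, window: SlidingWindow) -> float:
    """Arithmetic mean of per-base depths over one window's positions."""
    i0, i1 = cov.template.index_range(window.chrom, window.start, window.end)
    return float(cov.depths[i0:i1].mean())


def load_per_locus_coverage(
    path: str | Path,
    template: WindowTemplate,
    sample_id: str | None = None,
    run_id: str = "",
    lot_id: str = "",
) -> SampleCoverage:
    """Load a per-locus depth table restricted to the targeted positions.

    The file has a header line and at least two columns: ``Locus``
    (``chrom:pos``, 1-based) and ``Total_Depth``; extra columns are ignored.
    Targeted positions missing from the file are zero-filled (with a
    warning); off-target positions are silently dropped (count logged).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read per-locus table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: per-locus table needs >= 2 columns", 1)

    locus = df.iloc[:, 0].astype(str)
    parts = locus.str.rsplit(":", n=1, expand=True)
    if parts.shape[1] < 2 or parts[1].isna().any():
        bad = int(np.argmax(parts[1].isna().to_numpy())) if parts.shape[1] >= 2 else 0
        raise ParseError(f"malformed locus '{locus.iloc[bad]}'", bad + 2)
    pos = pd.to_numeric(parts[1], errors="coerce")
    if pos.isna().any():
        bad = int(np.argmax(pos.isna().to_numpy()))
        raise ParseError(f"malformed locus '{locus.iloc[bad]}'", bad + 2)
    depth = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if depth.isna().any():
        bad = int(np.argmax(depth.isna().to_numpy()))
        raise ParseError(f"non-numeric depth '{df.iloc[bad, 1]}'", bad + 2)

    chroms = parts[0].to_numpy()
    pos0 = pos.to_numpy(dtype=np.int64) - 1  # 1-based file -> 0-based internal
    depths_in = depth.to_numpy(dtype=np.float64)

    flat = np.full(len(pos0), -1, dtype=np.int64)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        flat[mask] = template.locate(chrom, pos0[mask])

    on_target = flat >= 0
    n_outside = int((~on_target).sum())
    if on_target.sum() == 0:
        raise EmptyOverlapError(
            f"{path}: no positions overlap the target panel "
            f"(first locus: {locus.iloc[0] if len(locus) else 'none'})"
        )
    depths = np.zeros(template.n_positions, dtype=np.int64)
    depths[flat[on_target]] = np.rint(depths_in[on_target]).astype(np.int64)

    n_missing = template.n_positions - int(on_target.sum())
    if n_missing > 0:
        logger.warning(
            "%s: %d targeted positions missing from coverage file, set to depth 0",
            sample_id,
            n_missing,
        )
    if n_outside > 0:
        logger.info("%s: ignored %d off-target positions", sample_id, n_outside)
    return SampleCoverage(sample_id, depths, template, run_id=run_id, lot_id=lot_id)


def write_per_locus_coverage(cov: SampleCoverage, path: str | Path) -> None:
    """Write coverage in the per-locus dialect (Locus chrom:pos 1-based)."""
    pos = cov.template.positions()
    locus = pos["chrom"].astype(str) + ":" + (pos["pos"] + 1).astype(str)
    pd.DataFrame({"Locus": locus, "Total_Depth": cov.depths}).to_csv(
        path, sep="\t", index=False
    )


def compute_bam_coverage(
    path: str | Path,
    template: WindowTemplate,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    count_duplicates: bool = False,
    sample_id: str | None = None,
    run_id: str = "",
    lot_id: str = "",
) -> SampleCoverage:
    """Per-base depth over targeted positions by pileup from an indexed BAM.

    Counts aligned bases of primary reads with MAPQ >= ``min_mapq``;
    duplicate-flagged reads are excluded unless ``count_duplicates``.
    """
    import pysam

    if min_mapq < 0:
        raise InvalidParameterError(f"min_mapq must be >= 0, got {min_mapq}")
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    bam = pysam.AlignmentFile(str(path), "rb")
    if not bam.has_index():
        raise InputError(
            f"{path} has no index; create one (e.g. `samtools index {path.name}`)"
        )
    refs = set(bam.references)
    depths = np.zeros(template.n_positions, dtype=np.int64)
    offset = 0
    for region in template.regions:
        chrom = region.chrom
        if chrom not in refs:
            alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            if alt in refs:
                raise InputError(
                    f"contig naming mismatch: panel uses '{chrom}' but BAM uses '{alt}'"
                )
            raise InputError(f"contig '{chrom}' absent from BAM {path}")
        for read in bam.fetch(chrom, region.start, region.end):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_duplicate and not count_duplicates:
                continue
            for bstart, bend in read.get_blocks():
                lo = max(bstart, region.start)
                hi = min(bend, region.end)
                if hi > lo:
                    depths[offset + lo - region.start : offset + hi - region.start] += 1
        offset += region.length
    bam.close()
    return SampleCoverage(sample_id, depths, template, run_id=run_id, lot_id=lot_id)


def load_coverage_dir(
    directory: str | Path,
    template: WindowTemplate,
    manifest: pd.DataFrame | None = None,
    pattern: str = "*.coverage.tsv",
) -> list[SampleCoverage]:
    """Load every per-locus coverage file in a directory.

    An optional manifest (columns sample_id, run_id, lot_id) attaches run
    and lot identifiers to each sample.
    """
    directory = Path(directory)
    meta: dict[str, tuple[str, str]] = {}
    if manifest is not None:
        for _, row in manifest.iterrows():
            meta[str(row["sample_id"])] = (
                str(row.get("run_id", "")),
                str(row.get("lot_id", "")),
            )
    covs = []
    files = sorted(directory.glob(pattern))
    if not files:
        raise InputError(f"no coverage files matching {pattern} in {directory}")
    for f in files:
        sid = f.name.split(".")[0]
        run_id, lot_id = meta.get(sid, ("", ""))
        covs.append(
            load_per_locus_coverage(f, template, sample_id=sid, run_id=run_id, lot_id=lot_id)
        )
    return covs
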
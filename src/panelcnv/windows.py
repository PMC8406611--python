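"""Target-region-based sliding windows (TRSW).

A targeted gene panel captures a discontinuous set of genomic intervals
(exons/UTRs plus small intronic flanks).  To score copy number at sub-exon
resolution, each target region is tiled with overlapping fixed-size windows:
the first window is anchored at the region start, successive windows slide
forward by a fixed sliding length, and any remainder shorter than the
sliding length is absorbed into the last window, which therefore ends
exactly at the region end.  Regions shorter than the window size yield a
single window spanning the whole region.  Windows never cross region
boundaries.

With the default window size of 75 nt (half a 150-nt read) and sliding
length of 10 nt, adjacent windows overlap by 65 nt and CNV breakpoints are
resolved to roughly the sliding length.

All coordinates are 0-based half-open (BED convention); conversion to the
1-based per-locus dialect happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, InvalidParameterError, ParseError

DEFAULT_WINDOW_LEN = 75
DEFAULT_SLIDE_LEN = 10


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval of the panel (0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise InputError(
                f"region {self.chrom}:{self.start}-{self.end} has non-positive length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SlidingWindow:
    """One sliding window, fully contained in its parent region."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    region_label: str = ""
    index: int = 0  # 0-based ordinal within the parent region

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_window_params(region_len: int, window_len: int, slide_len: int) -> None:
    if region_len < 1 or window_len < 1 or slide_len < 1:
        raise InvalidParameterError(
            f"region_len={region_len}, window_len={window_len}, slide_len={slide_len}: "
            "all must be >= 1"
        )
    if slide_len > window_len:
        raise InvalidParameterError(
            f"slide_len ({slide_len}) must not exceed window_len ({window_len})"
        )


def count_windows(region_len: int, window_len: int, slide_len: int) -> int:
    """Number of sliding windows for a region of ``region_len`` nt.

    N = floor((L_region - L_window) / L_slide) + 1, with a single window
    when the region is no longer than the window size.
    """
    _check_window_params(region_len, window_len, slide_len)
    if region_len <= window_len:
        return 1
    return (region_len - window_len) // slide_len + 1


def build_region_windows(
    region: TargetRegion, window_len: int, slide_len: int
) -> list[SlidingWindow]:
    """Tile one region with sliding windows.

    All windows have length ``window_len`` except the last, which absorbs
    the remainder ``(L_region - L_window) mod L_slide`` and ends exactly at
    the region end.  Regions shorter than ``window_len`` get one window
    spanning the whole region.
    """
    n = count_windows(region.length, window_len, slide_len)
    windows = []
    for i in range(n):
        start = region.start + i * slide_len
        end = region.end if i == n - 1 else start + window_len
        if region.length <= window_len:
            end = region.end
        windows.append(
            SlidingWindow(
                chrom=region.chrom,
                start=start,
                end=end,
                gene=region.gene,
                region_label=region.label,
                index=i,
            )
        )
    return windows


class WindowTemplate:
    """Panel-wide ordered set of sliding windows over merged target regions.

    Besides the window list, the template pre-computes the flat array of
    targeted genomic positions (region intervals concatenated in panel
    order) and, for every window, its index range into that array, so that
    per-window mean depths reduce to cumulative-sum arithmetic.
    """

    def __init__(
        self,
        regions: list[TargetRegion],
        window_len: int = DEFAULT_WINDOW_LEN,
        slide_len: int = DEFAULT_SLIDE_LEN,
    ):
        if not regions:
            raise InputError("cannot build a window template from zero regions")
        _check_window_params(1, window_len, slide_len)
        _check_disjoint(regions)
        self.window_len = int(window_len)
        self.slide_len = int(slide_len)
        self.regions = list(regions)
        self.windows: list[SlidingWindow] = []
        self.window_region_index: list[int] = []
        for ri, region in enumerate(self.regions):
            ws = build_region_windows(region, window_len, slide_len)
            self.windows.extend(ws)
            self.window_region_index.extend([ri] * len(ws))

        lengths = np.array([r.length for r in self.regions], dtype=np.int64)
        self._region_offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.n_positions = int(self._region_offsets[-1])
        self.n_windows = len(self.windows)

        # flat position-index range of each window
        self.window_start_idx = np.empty(self.n_windows, dtype=np.int64)
        self.window_end_idx = np.empty(self.n_windows, dtype=np.int64)
        for wi, w in enumerate(self.windows):
            ri = self.window_region_index[wi]
            off = self._region_offsets[ri] - self.regions[ri].start
            self.window_start_idx[wi] = off + w.start
            self.window_end_idx[wi] = off + w.end
        self.window_lengths = self.window_end_idx - self.window_start_idx

        # per-chromosome lookup tables for (chrom, pos) -> flat index
        self._chrom_tables: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for ri, r in enumerate(self.regions):
            by_chrom.setdefault(r.chrom, []).append(ri)
        for chrom, idxs in by_chrom.items():
            idxs = sorted(idxs, key=lambda i: self.regions[i].start)
            starts = np.array([self.regions[i].start for i in idxs], dtype=np.int64)
            ends = np.array([self.regions[i].end for i in idxs], dtype=np.int64)
            offs = np.array([self._region_offsets[i] for i in idxs], dtype=np.int64)
            self._chrom_tables[chrom] = (starts, ends, offs)

    # ------------------------------------------------------------------
    def locate(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Map 0-based positions on ``chrom`` to flat indices (-1 = off-target)."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, -1, dtype=np.int64)
        table = self._chrom_tables.get(chrom)
        if table is None:
            return out
        starts, ends, offs = table
        ri = np.searchsorted(starts, positions, side="right") - 1
        valid = (ri >= 0) & (positions < ends[np.clip(ri, 0, len(ends) - 1)])
        ri_v = ri[valid]
        out[valid] = offs[ri_v] + positions[valid] - starts[ri_v]
        return out

    def index_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Flat index range of a sub-interval that lies within one region."""
        idx = self.locate(chrom, np.array([start, end - 1]))
        if idx[0] < 0 or idx[1] < 0 or idx[1] - idx[0] != end - 1 - start:
            raise InputError(
                f"interval {chrom}:{start}-{end} does not lie within a single target region"
            )
        return int(idx[0]), int(idx[1]) + 1

    def positions(self) -> pd.DataFrame:
        """DataFrame of all targeted positions (chrom, pos 0-based) in flat order."""
        chroms = np.concatenate(
            [np.repeat(r.chrom, r.length) for r in self.regions]
        )
        pos = np.concatenate(
            [np.arange(r.start, r.end, dtype=np.int64) for r in self.regions]
        )
        return pd.DataFrame({"chrom": chroms, "pos": pos})

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene)
        return list(seen)

    def gene_window_indices(self, gene: str) -> np.ndarray:
        return np.array(
            [i for i, w in enumerate(self.windows) if w.gene == gene], dtype=np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "gene": [w.gene for w in self.windows],
                "region_label": [w.region_label for w in self.windows],
                "window_index": [w.index for w in self.windows],
            }
        )

    def same_shape(self, other: "WindowTemplate") -> bool:
        return (
            self.n_windows == other.n_windows
            and all(
                a.chrom == b.chrom and a.start == b.start and a.end == b.end
                for a, b in zip(self.windows, other.windows)
            )
        )


def _check_disjoint(regions: list[TargetRegion]) -> None:
    by_chrom: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise InputError(
                    f"overlapping target regions on {chrom}: "
                    f"{a.start}-{a.end} ({a.gene}) and {b.start}-{b.end} ({b.gene})"
                )


def build_template(
    regions: list[TargetRegion],
    window_len: int = DEFAULT_WINDOW_LEN,
    slide_len: int = DEFAULT_SLIDE_LEN,
) -> WindowTemplate:
    """Build the panel-wide window template from validated regions."""
    return WindowTemplate(regions, window_len, slide_len)


def load_bed(path: str | Path) -> list[TargetRegion]:
    """Load and validate panel regions from a BED file.

    Column 4, when present, is parsed as ``GENE|label`` (or a bare gene
    symbol).  Overlapping or book-ended intervals of the same gene are
    merged so that duplicate capture probes cannot double-count windows;
    any overlap remaining between different genes is an error.  Regions are
    ordered by chromosome (first appearance) then start.
    """
    raw: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"BED line has {len(fields)} columns, need >= 3", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer BED coordinates: {exc}", lineno) from exc
            gene, label = "", ""
            if len(fields) >= 4 and fields[3]:
                gene, _, label = fields[3].partition("|")
            if end <= start:
                raise ParseError(f"empty interval {fields[0]}:{start}-{end}", lineno)
            raw.append(TargetRegion(fields[0], start, end, gene, label))
    if not raw:
        raise InputError(f"no regions found in {path}")

    chrom_order = {r.chrom: i for i, r in enumerate(raw)}
    raw.sort(key=lambda r: (chrom_order[r.chrom], r.start, r.end))

    merged: list[TargetRegion] = []
    for r in raw:
        if (
            merged
            and merged[-1].chrom == r.chrom
            and merged[-1].gene == r.gene
            and r.start <= merged[-1].end
        ):
            prev = merged.pop()
            label = prev.label if prev.label == r.label else f"{prev.label}+{r.label}"
            merged.append(
                TargetRegion(r.chrom, prev.start, max(prev.end, r.end), r.gene, label)
            )
        else:
            merged.append(r)
    _check_disjoint(merged)
    return merged


def write_template(template: WindowTemplate, path: str | Path) -> None:
    """Write the window template as an audit TSV."""
    template.to_frame().to_csv(path, sep="\t", index=False)


def write_bed(regions: list[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.gene}|{r.label}" if r.label else r.gene
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
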
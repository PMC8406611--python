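"""Static and run-wise reference pools of normal samples.

The expected (CNV-free) depth of every window is estimated from pools of
normal samples with similar overall coverage.  Eligible normals (mean depth
above a cutoff) are sorted in increasing order of mean depth; pool j holds
samples j..j+K-1 of that list, so N normals yield M = N - K + 1 overlapping
pools and consecutive pools share K - 1 members.  For each pool the
per-window reference is the unweighted mean of the members' window means
(mean_TRSW).  A query is scored against the pool whose mean depth is
nearest its own.

Because capture kits have lot-to-lot batch effects, pools carry the
capture-kit lot they were built from and pool selection refuses cross-lot
matches unless explicitly allowed.

Run-wise pools — built from the other samples of the query's own sequencing
run — serve as a QC cross-check on static-pool results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import SampleCoverage
from .errors import (
    CrossLotError,
    InputError,
    InsufficientNormalsError,
    InvalidParameterError,
    NoEligibleNormalsError,
    TemplateMismatchError,
)
from .windows import WindowTemplate

DEFAULT_MIN_NORMAL_DEPTH = 100.0


@dataclass
class StaticPool:
    """An ordered group of normal samples and its per-window reference."""

    pool_id: int
    members: list[str]
    member_mean_depths: np.ndarray
    mean_trsw: np.ndarray  # per-window mean of member window means
    lot_id: str = ""
    mean_depth_per_pos: np.ndarray | None = field(default=None, repr=False)

    @property
    def pool_mean_depth(self) -> float:
        """Mean of member sample mean depths."""
        return float(np.mean(self.member_mean_depths))

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PoolSet:
    """All static pools built from one sorted list of normals."""

    pools: list[StaticPool]
    K: int
    N: int
    lot_id: str = ""

    def __len__(self) -> int:
        return len(self.pools)


def select_normals(
    samples: list[SampleCoverage], min_mean_depth: float = DEFAULT_MIN_NORMAL_DEPTH
) -> list[SampleCoverage]:
    """Normals above the depth cutoff, sorted ascending by mean depth.

    Ties are broken by sample_id so the ordering (and hence pool membership)
    is reproducible.
    """
    if not samples:
        raise InputError("no samples provided")
    eligible = [s for s in samples if s.mean_depth > min_mean_depth]
    if not eligible:
        raise NoEligibleNormalsError(
            f"no sample exceeds the mean-depth cutoff of {min_mean_depth} "
            f"(best: {max(s.mean_depth for s in samples):.1f})"
        )
    return sorted(eligible, key=lambda s: (s.mean_depth, s.sample_id))


def _make_pool(
    members: list[SampleCoverage],
    pool_id: int,
    lot_id: str = "",
    keep_per_position: bool = True,
) -> StaticPool:
    mean_trsw = np.mean([m.window_means() for m in members], axis=0)
    per_pos = None
    if keep_per_position:
        per_pos = np.mean([m.depths for m in members], axis=0)
    return StaticPool(
        pool_id=pool_id,
        members=[m.sample_id for m in members],
        member_mean_depths=np.array([m.mean_depth for m in members]),
        mean_trsw=mean_trsw,
        lot_id=lot_id,
        mean_depth_per_pos=per_pos,
    )


def build_static_pools(
    normals: list[SampleCoverage], K: int, lot_id: str = ""
) -> PoolSet:
    """Build the M = N - K + 1 overlapping pools from sorted normals."""
    if K < 2:
        raise InvalidParameterError(f"pool size K must be >= 2, got {K}")
    N = len(normals)
    if N < K:
        raise InsufficientNormalsError(
            f"need at least K={K} normal samples, have N={N}"
        )
    pools = [
        _make_pool(normals[j : j + K], pool_id=j, lot_id=lot_id)
        for j in range(N - K + 1)
    ]
    return PoolSet(pools=pools, K=K, N=N, lot_id=lot_id)


def select_pool(
    query: SampleCoverage, pools: PoolSet, allow_cross_lot: bool = False
) -> StaticPool:
    """Pool whose mean depth is nearest the query's mean depth.

    Ties go to the lower-depth pool.  Cross-lot selection is refused unless
    ``allow_cross_lot`` (capture-kit batch effects make cross-lot references
    unreliable).
    """
    if not pools.pools:
        raise InputError("empty pool set")
    if (
        not allow_cross_lot
        and pools.lot_id
        and query.lot_id
        and pools.lot_id != query.lot_id
    ):
        raise CrossLotError(
            f"query lot '{query.lot_id}' differs from pool lot '{pools.lot_id}'; "
            "pass allow_cross_lot=True / --allow-cross-lot to override"
        )
    qd = query.mean_depth
    return min(
        pools.pools, key=lambda p: (abs(p.pool_mean_depth - qd), p.pool_mean_depth, p.pool_id)
    )


def build_runwise_pool(
    run_samples: list[SampleCoverage], query_id: str
) -> StaticPool:
    """Single pool from the query's own run, excluding the query itself."""
    members = sorted(
        (s for s in run_samples if s.sample_id != query_id),
        key=lambda s: (s.mean_depth, s.sample_id),
    )
    if len(members) < 3:
        raise InsufficientNormalsError(
            f"run-wise pool needs >= 3 non-query samples, have {len(members)}"
        )
    lots = {m.lot_id for m in members if m.lot_id}
    lot = lots.pop() if len(lots) == 1 else ""
    return _make_pool(members, pool_id=-1, lot_id=lot)


# ----------------------------------------------------------------------
# on-disk pool store: manifest TSV + per-pool mean_TRSW TSV keyed by window
# ----------------------------------------------------------------------

def save_pools(pools: PoolSet, template: WindowTemplate, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools.pools],
            "members": [",".join(p.members) for p in pools.pools],
            "member_mean_depths": [
                ",".join(f"{d:.6f}" for d in p.member_mean_depths) for p in pools.pools
            ],
            "pool_mean_depth": [p.pool_mean_depth for p in pools.pools],
            "lot_id": [p.lot_id for p in pools.pools],
        }
    )
    header = pd.DataFrame({"K": [pools.K], "N": [pools.N], "lot_id": [pools.lot_id]})
    header.to_csv(directory / "poolset.tsv", sep="\t", index=False)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)

    trsw = template.to_frame()
    for p in pools.pools:
        trsw[f"pool_{p.pool_id}"] = p.mean_trsw
    trsw.to_csv(directory / "mean_trsw.tsv", sep="\t", index=False)

    per_pos = template.positions()
    cols = {}
    for p in pools.pools:
        if p.mean_depth_per_pos is not None:
            cols[f"pool_{p.pool_id}"] = p.mean_depth_per_pos
    if cols:
        pd.concat([per_pos, pd.DataFrame(cols)], axis=1).to_csv(
            directory / "per_position_mean.tsv", sep="\t", index=False
        )


def load_pools(directory: str | Path, template: WindowTemplate) -> PoolSet:
    directory = Path(directory)
    header = pd.read_csv(directory / "poolset.tsv", sep="\t", dtype=str).iloc[0]
    manifest = pd.read_csv(
        directory / "manifest.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    trsw = pd.read_csv(directory / "mean_trsw.tsv", sep="\t")
    ref = template.to_frame()
    if len(trsw) != len(ref) or not (
        (trsw["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
        and (trsw["start"].to_numpy() == ref["start"].to_numpy()).all()
        and (trsw["end"].to_numpy() == ref["end"].to_numpy()).all()
    ):
        raise TemplateMismatchError(
            f"pool store in {directory} was built from a different window template"
        )
    per_pos_path = directory / "per_position_mean.tsv"
    per_pos = pd.read_csv(per_pos_path, sep="\t") if per_pos_path.exists() else None
    if per_pos is not None and len(per_pos) != template.n_positions:
        raise TemplateMismatchError(
            f"per-position pool means in {directory} do not match the template"
        )
    pools = []
    for _, row in manifest.iterrows():
        pid = int(row["pool_id"])
        col = f"pool_{pid}"
        pools.append(
            StaticPool(
                pool_id=pid,
                members=row["members"].split(","),
                member_mean_depths=np.array(
                    [float(x) for x in row["member_mean_depths"].split(",")]
                ),
                mean_trsw=trsw[col].to_numpy(dtype=np.float64),
                lot_id=row["lot_id"],
                mean_depth_per_pos=(
                    per_pos[col].to_numpy(dtype=np.float64)
                    if per_pos is not None and col in per_pos
                    else None
                ),
            )
        )
    return PoolSet(
        pools=pools,
        K=int(header["K"]),
        N=int(header["N"]),
        lot_id="" if pd.isna(header["lot_id"]) else str(header["lot_id"]),
    )
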
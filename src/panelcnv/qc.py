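"""Quality control of a query sample against its reference pools.

Three checks guard against the main noise sources of pool-based read-depth
scoring:

1. query-vs-pool depth deviation — the percentage deviation of the query's
   mean depth from the selected pool's mean depth must stay under a lab
   cutoff (default 5%); otherwise the sample is re-analyzed against an
   updated pool list and, failing that, escalated to re-sequencing or an
   orthogonal wet-lab test;
2. static-pool uniformity — the coefficient of variation of member mean
   depths; heterogeneous pools inject noise into every window;
3. static vs run-wise agreement — per-window score differences between the
   static-pool profile and a profile computed against the query's own run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, InvalidParameterError, TemplateMismatchError
from .pooling import StaticPool
from .scoring import LogCNRProfile

DEFAULT_DEVIATION_CUTOFF_PCT = 5.0
DEFAULT_MAX_POOL_CV_PCT = 15.0
DEFAULT_RUNWISE_DELTA_THRESHOLD = 0.3


@dataclass
class RunwiseDelta:
    """Summary of |static - run-wise| score differences per window."""

    max_delta: float
    mean_delta: float
    n_compared: int
    n_flagged: int
    flagged_windows: np.ndarray
    threshold: float


@dataclass
class QCReport:
    sample_id: str
    pool_id: int
    pct_deviation: float
    deviation_cutoff_pct: float
    pool_cv: float
    max_pool_cv_pct: float
    runwise: RunwiseDelta | None = None
    suggested_pool_id: int | None = None

    @property
    def deviation_pass(self) -> bool:
        return self.pct_deviation <= self.deviation_cutoff_pct

    @property
    def pool_cv_pass(self) -> bool:
        return self.pool_cv <= self.max_pool_cv_pct

    def to_frame(self) -> pd.DataFrame:
        row = {
            "sample_id": self.sample_id,
            "pool_id": self.pool_id,
            "pct_deviation": self.pct_deviation,
            "deviation_pass": self.deviation_pass,
            "pool_cv_pct": self.pool_cv,
            "pool_cv_pass": self.pool_cv_pass,
            "suggested_pool_id": self.suggested_pool_id,
        }
        if self.runwise is not None:
            row.update(
                runwise_max_delta=self.runwise.max_delta,
                runwise_mean_delta=self.runwise.mean_delta,
                runwise_n_flagged=self.runwise.n_flagged,
            )
        return pd.DataFrame([row])


def percent_deviation(query_mean: float, pool_mean: float) -> float:
    """100 * |query - pool| / pool, the query-vs-pool depth deviation."""
    if pool_mean <= 0:
        raise InvalidParameterError(f"pool mean depth must be > 0, got {pool_mean}")
    return 100.0 * abs(query_mean - pool_mean) / pool_mean


def pool_uniformity(pool: StaticPool, member_means=None) -> float:
    """Coefficient of variation (%) of member mean depths (sd with n-1)."""
    means = np.asarray(
        pool.member_mean_depths if member_means is None else member_means, dtype=float
    )
    if means.size < 2:
        raise InputError("pool uniformity (CV) is undefined for fewer than 2 members")
    return float(100.0 * means.std(ddof=1) / means.mean())


def compare_static_vs_runwise(
    static_profile: LogCNRProfile,
    runwise_profile: LogCNRProfile,
    delta_threshold: float = DEFAULT_RUNWISE_DELTA_THRESHOLD,
) -> RunwiseDelta:
    """Per-window |static - run-wise| score differences on mutually called windows."""
    if static_profile.sample_id != runwise_profile.sample_id:
        raise InputError(
            f"profiles are for different samples: {static_profile.sample_id} vs "
            f"{runwise_profile.sample_id}"
        )
    if not static_profile.template.same_shape(runwise_profile.template):
        raise TemplateMismatchError("profiles were built from different window templates")
    called = ~(static_profile.no_call_mask | runwise_profile.no_call_mask)
    deltas = np.abs(static_profile.scores[called] - runwise_profile.scores[called])
    flagged = np.flatnonzero(called)[deltas > delta_threshold]
    return RunwiseDelta(
        max_delta=float(deltas.max()) if deltas.size else 0.0,
        mean_delta=float(deltas.mean()) if deltas.size else 0.0,
        n_compared=int(called.sum()),
        n_flagged=int(flagged.size),
        flagged_windows=flagged,
        threshold=delta_threshold,
    )


def run_qc(
    query_mean: float,
    pool: StaticPool,
    sample_id: str,
    deviation_cutoff_pct: float = DEFAULT_DEVIATION_CUTOFF_PCT,
    max_pool_cv_pct: float = DEFAULT_MAX_POOL_CV_PCT,
    static_profile: LogCNRProfile | None = None,
    runwise_profile: LogCNRProfile | None = None,
    runwise_delta_threshold: float = DEFAULT_RUNWISE_DELTA_THRESHOLD,
) -> QCReport:
    """Assemble the QC report for one scored query."""
    runwise = None
    if static_profile is not None and runwise_profile is not None:
        runwise = compare_static_vs_runwise(
            static_profile, runwise_profile, runwise_delta_threshold
        )
    return QCReport(
        sample_id=sample_id,
        pool_id=pool.pool_id,
        pct_deviation=percent_deviation(query_mean, pool.pool_mean_depth),
        deviation_cutoff_pct=deviation_cutoff_pct,
        pool_cv=pool_uniformity(pool),
        max_pool_cv_pct=max_pool_cv_pct,
        runwise=runwise,
    )


def write_qc_report(report: QCReport, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
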
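"""Per-window log copy-number-ratio (logCNR) scoring.

For each sliding window the query's mean depth is divided by the selected
pool's mean_TRSW for that window and the ratio is taken to log2:

    logCNR = log2( mean depth of query over the window
                   / mean over pool members of their window mean depths )

Theoretical values are 0.0 for the normal two-allele state, -1.0 for a
heterozygous deletion (depth halved), +0.58 for a heterozygous duplication
(depth x 1.5), and log2(1 - f/2) for a single-allele deletion mosaic in a
fraction f of cells.

Windows whose pool reference is below a minimum depth are masked as
no-calls rather than scored: low-capture regions are where read-depth
methods produce false positives, and masking makes that failure mode
explicit.  A query depth of exactly zero against an adequately covered pool
would give -infinity; it is reported as a configurable floor score and
flagged as a possible homozygous deletion instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import SampleCoverage
from .errors import InvalidParameterError, TemplateMismatchError
from .pooling import StaticPool
from .windows import WindowTemplate

DEFAULT_MIN_POOL_DEPTH = 20.0
DEFAULT_FLOOR_SCORE = -6.0


@dataclass
class LogCNRProfile:
    """Per-window logCNR scores of one query sample against one pool."""

    sample_id: str
    pool_id: int
    scores: np.ndarray  # float64; NaN where no_call
    no_call_mask: np.ndarray  # bool; True where pool depth too low to score
    floor_mask: np.ndarray  # bool; True where query depth 0 -> floor score
    template: WindowTemplate
    qc: object | None = field(default=None, compare=False)

    def to_frame(self) -> pd.DataFrame:
        df = self.template.to_frame()
        df["score"] = self.scores
        df["no_call"] = self.no_call_mask
        df["possible_homozygous_deletion"] = self.floor_mask
        return df


def logcnr(
    query_window_mean: float,
    pool_window_mean: float,
    min_pool_depth: float = DEFAULT_MIN_POOL_DEPTH,
    floor_score: float = DEFAULT_FLOOR_SCORE,
) -> float:
    """logCNR of one window; NaN marks a no-call (pool depth below floor)."""
    if query_window_mean < 0 or pool_window_mean < 0:
        raise InvalidParameterError("window mean depths must be >= 0")
    if pool_window_mean < min_pool_depth:
        return float("nan")
    if query_window_mean == 0:
        return floor_score
    return float(np.log2(query_window_mean / pool_window_mean))


def score_sample(
    query: SampleCoverage,
    pool: StaticPool,
    template: WindowTemplate,
    min_pool_depth: float = DEFAULT_MIN_POOL_DEPTH,
    floor_score: float = DEFAULT_FLOOR_SCORE,
) -> LogCNRProfile:
    """Score every template window of the query against the pool."""
    if pool.mean_trsw.shape != (template.n_windows,):
        raise TemplateMismatchError(
            f"pool {pool.pool_id} has {pool.mean_trsw.size} windows, "
            f"template has {template.n_windows}"
        )
    if query.template is not template and not query.template.same_shape(template):
        raise TemplateMismatchError("query coverage was built from a different template")

    q = query.window_means()
    p = pool.mean_trsw
    n = template.n_windows
    scores = np.full(n, np.nan)
    no_call = p < min_pool_depth
    floor = (~no_call) & (q == 0)
    ok = (~no_call) & (q > 0)
    scores[floor] = floor_score
    with np.errstate(divide="ignore"):
        scores[ok] = np.log2(q[ok] / p[ok])
    return LogCNRProfile(
        sample_id=query.sample_id,
        pool_id=pool.pool_id,
        scores=scores,
        no_call_mask=no_call,
        floor_mask=floor,
        template=template,
    )


def write_profile(profile: LogCNRProfile, path) -> None:
    """Write the per-window logCNR table (scores keyed by window)."""
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_profile(path, template: WindowTemplate, sample_id: str = "", pool_id: int = -1
                 ) -> LogCNRProfile:
    """Load a logCNR table written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t")
    ref = template.to_frame()
    if len(df) != len(ref) or not (
        (df["start"].to_numpy() == ref["start"].to_numpy()).all()
        and (df["chrom"].astype(str).to_numpy() == ref["chrom"].to_numpy()).all()
    ):
        raise TemplateMismatchError(f"profile {path} does not match the window template")
    return LogCNRProfile(
        sample_id=sample_id,
        pool_id=pool_id,
        scores=df["score"].to_numpy(dtype=np.float64),
        no_call_mask=df["no_call"].to_numpy(dtype=bool),
        floor_mask=df["possible_homozygous_deletion"].to_numpy(dtype=bool),
        template=template,
    )
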
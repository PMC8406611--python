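"""End-to-end orchestration: pool selection, scoring, QC, reporting.

``run_score`` is the one-call path a diagnostic workflow uses per query
sample: select the nearest static pool, score every window, run QC, and
emit the logCNR table, QC report, candidate shortlist, and (optionally)
per-gene plots.  When the query's depth deviates from the selected pool by
more than the cutoff, the sample is re-analyzed against an updated pool set
if one is provided; otherwise scoring stops with the documented escalation
(re-sequencing or an orthogonal wet-lab test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import pooling, qc, reporting, scoring
from .config import PipelineConfig
from .coverage import SampleCoverage
from .errors import QCFailureError
from .pooling import PoolSet, StaticPool
from .qc import QCReport
from .scoring import LogCNRProfile
from .windows import WindowTemplate

logger = logging.getLogger("panelcnv")

ESCALATION_MESSAGE = (
    "query/pool mean-depth deviation {dev:.1f}% exceeds the {cutoff:.1f}% cutoff "
    "and no updated pool set resolved it; escalate to re-sequencing or an "
    "orthogonal test (e.g. MLPA), depending on the genes requested"
)


@dataclass
class ScoreResult:
    profile: LogCNRProfile
    pool: StaticPool
    qc_report: QCReport
    candidates: list[reporting.CNVCandidate]
    used_updated_pools: bool = False


def _select_passing_pool(
    query: SampleCoverage,
    pools: PoolSet,
    updated_pools: PoolSet | None,
    cfg: PipelineConfig,
    allow_cross_lot: bool,
) -> tuple[StaticPool, bool]:
    pool = pooling.select_pool(query, pools, allow_cross_lot=allow_cross_lot)
    dev = qc.percent_deviation(query.mean_depth, pool.pool_mean_depth)
    if dev <= cfg.deviation_cutoff_pct:
        return pool, False
    logger.warning(
        "%s: deviation %.1f%% from pool %d exceeds %.1f%%",
        query.sample_id, dev, pool.pool_id, cfg.deviation_cutoff_pct,
    )
    if updated_pools is not None:
        pool2 = pooling.select_pool(query, updated_pools, allow_cross_lot=allow_cross_lot)
        dev2 = qc.percent_deviation(query.mean_depth, pool2.pool_mean_depth)
        if dev2 <= cfg.deviation_cutoff_pct:
            logger.info(
                "%s: updated pool %d passes (deviation %.1f%%)",
                query.sample_id, pool2.pool_id, dev2,
            )
            return pool2, True
        dev = min(dev, dev2)
    raise QCFailureError(
        ESCALATION_MESSAGE.format(dev=dev, cutoff=cfg.deviation_cutoff_pct)
    )


def run_score(
    cfg: PipelineConfig,
    template: WindowTemplate,
    query: SampleCoverage,
    pools: PoolSet,
    out_dir: str | Path | None = None,
    updated_pools: PoolSet | None = None,
    run_samples: list[SampleCoverage] | None = None,
    allow_cross_lot: bool = False,
    plots: bool = False,
    mosaic_pass: bool = False,
) -> ScoreResult:
    """Score one query sample end to end.

    ``run_samples`` (the other samples of the query's sequencing run)
    enables the run-wise cross-check.  Raises :class:`QCFailureError` when
    the deviation check fails after the optional updated-pool retry.
    """
    pool, used_updated = _select_passing_pool(
        query, pools, updated_pools, cfg, allow_cross_lot
    )
    profile = scoring.score_sample(
        query, pool, template,
        min_pool_depth=cfg.min_pool_depth, floor_score=cfg.floor_score,
    )
    runwise_profile = None
    if run_samples:
        runwise = pooling.build_runwise_pool(run_samples, query.sample_id)
        runwise_profile = scoring.score_sample(
            query, runwise, template,
            min_pool_depth=cfg.min_pool_depth, floor_score=cfg.floor_score,
        )
    report = qc.run_qc(
        query.mean_depth, pool, query.sample_id,
        deviation_cutoff_pct=cfg.deviation_cutoff_pct,
        max_pool_cv_pct=cfg.max_pool_cv_pct,
        static_profile=profile,
        runwise_profile=runwise_profile,
        runwise_delta_threshold=cfg.runwise_delta_threshold,
    )
    if not report.pool_cv_pass and len(pools.pools) > 1:
        remaining = PoolSet(
            pools=[p for p in pools.pools if p.pool_id != pool.pool_id],
            K=pools.K, N=pools.N, lot_id=pools.lot_id,
        )
        report.suggested_pool_id = pooling.select_pool(
            query, remaining, allow_cross_lot=allow_cross_lot
        ).pool_id
        logger.warning(
            "%s: pool %d CV %.1f%% exceeds %.1f%%; next-nearest pool is %d",
            query.sample_id, pool.pool_id, report.pool_cv,
            cfg.max_pool_cv_pct, report.suggested_pool_id,
        )
    profile.qc = report

    candidates = reporting.flag_candidates(
        profile,
        del_threshold=cfg.del_threshold,
        dup_threshold=cfg.dup_threshold,
        min_consecutive=cfg.min_consecutive,
        include_mosaic_pass=mosaic_pass,
        mosaic_del_threshold=cfg.mosaic_del_threshold,
        mosaic_min_consecutive=cfg.mosaic_min_consecutive,
        query=query,
        pool=pool,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sid = query.sample_id
        scoring.write_profile(profile, out_dir / f"{sid}.logcnr.tsv")
        qc.write_qc_report(report, out_dir / f"{sid}.qc.tsv")
        reporting.write_candidates_tsv(candidates, out_dir / f"{sid}.candidates.tsv")
        reporting.write_candidates_bed(candidates, out_dir / f"{sid}.candidates.bed")
        if plots:
            plot_dir = out_dir / f"{sid}_plots"
            plot_dir.mkdir(exist_ok=True)
            for gene in template.genes():
                df = reporting.gene_plot(profile, gene, plot_dir / f"{gene}.png")
                df.to_csv(plot_dir / f"{gene}.tsv", sep="\t", index=False)

    return ScoreResult(
        profile=profile, pool=pool, qc_report=report,
        candidates=candidates, used_updated_pools=used_updated,
    )
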
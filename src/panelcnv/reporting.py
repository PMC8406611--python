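"""Per-gene tables, plots, and the advisory CNV candidate flagger.

The primary output of the pipeline is the per-window logCNR table and plot
for each gene, read by a human: points near 0 are normal, points near -1.0
indicate a heterozygous deletion and points near +0.58 a heterozygous
duplication.  Merged per-run overlays (optionally anonymized to avoid
incidental findings) and static-vs-run-wise comparison plots support QC.

On top of the manual-review outputs, ``flag_candidates`` produces a
machine-readable shortlist: maximal runs of consecutive windows beyond a
deletion or duplication threshold.  Flagging is advisory — it never
suppresses the full table or plot.  Because duplication signals
(+0.58) are weaker than deletion signals (-1.0), the duplication threshold
sits proportionally closer to zero.  Candidate spans are refined to
approximately sliding-length resolution, and to a few nucleotides when the
per-base query and pool depths are available, by fitting a step to the
depth ratio around each span edge (the equivalent of consulting the
nucleotide-level coverage files to locate the exact breakpoint).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .coverage import SampleCoverage
from .errors import InputError, TemplateMismatchError, UnknownGeneError
from .pooling import StaticPool
from .scoring import LogCNRProfile
from .windows import WindowTemplate

DEFAULT_DEL_THRESHOLD = -0.5
DEFAULT_DUP_THRESHOLD = 0.3
DEFAULT_MIN_CONSECUTIVE = 3
MOSAIC_DEL_THRESHOLD = -0.15
MOSAIC_MIN_CONSECUTIVE = 10

DELETION_LINE = -1.0
DUPLICATION_LINE = 0.58


@dataclass
class CNVCandidate:
    """One maximal run of flagged windows, as a genomic span."""

    gene: str
    chrom: str
    start: int
    end: int
    direction: str  # "deletion" | "duplication"
    mean_score: float
    n_windows: int
    breakpoint_resolution: int  # nt; the template slide length
    note: str = ""


def _gene_windows(profile: LogCNRProfile, gene: str) -> np.ndarray:
    idx = profile.template.gene_window_indices(gene)
    if idx.size == 0:
        raise UnknownGeneError(
            f"gene '{gene}' not in panel; panel genes: "
            + ", ".join(profile.template.genes())
        )
    return idx


def gene_table(profile: LogCNRProfile, gene: str) -> pd.DataFrame:
    """Window/score table for one gene, in genomic order, grouped by region."""
    idx = _gene_windows(profile, gene)
    df = profile.to_frame().iloc[idx].reset_index(drop=True)
    return df


def gene_plot(
    profile: LogCNRProfile, gene: str, out_path: str | Path
) -> pd.DataFrame:
    """Scatter of window scores for one gene with the -1.0/+0.58 reference lines.

    No-call windows are rendered as gaps.  Returns the plotted data (the
    plot's sidecar), which is also what makes plot output comparable across
    reruns.
    """
    df = gene_table(profile, gene)
    y = df["score"].to_numpy(dtype=float).copy()
    y[df["no_call"].to_numpy(dtype=bool)] = np.nan
    x = np.arange(len(df))

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.axhline(DELETION_LINE, color="tab:red", lw=0.8, ls="--", label="deletion (-1.00)")
    ax.axhline(
        DUPLICATION_LINE, color="tab:blue", lw=0.8, ls="--", label="duplication (+0.58)"
    )
    ax.axhline(0.0, color="grey", lw=0.6)
    labels = df["region_label"].to_numpy()
    for i in np.flatnonzero(labels[1:] != labels[:-1]) + 1:
        ax.axvline(i - 0.5, color="lightgrey", lw=0.5)
    ax.plot(x, y, ".-", ms=4, lw=0.7, color="black")
    ax.set_xlabel(f"{gene} sliding windows (genomic order)")
    ax.set_ylabel("logCNR score (log2)")
    ax.set_title(f"{profile.sample_id} — {gene}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return df


def merged_run_plot(
    profiles: list[LogCNRProfile],
    gene: str,
    out_path: str | Path,
    anonymize: bool = False,
) -> list[str]:
    """Overlay one gene's score traces for all samples of a run.

    With ``anonymize`` the legend carries anonymous sample numbers so that
    the overlay cannot leak incidental findings.  Returns the legend labels.
    """
    if len(profiles) < 2:
        raise InputError("merged run plot needs at least 2 profiles")
    t0 = profiles[0].template
    for p in profiles[1:]:
        if not t0.same_shape(p.template):
            raise TemplateMismatchError("profiles were built from different templates")
    idx = _gene_windows(profiles[0], gene)
    labels = [
        f"sample {i + 1}" if anonymize else p.sample_id
        for i, p in enumerate(profiles)
    ]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.axhline(DELETION_LINE, color="tab:red", lw=0.8, ls="--")
    ax.axhline(DUPLICATION_LINE, color="tab:blue", lw=0.8, ls="--")
    ax.axhline(0.0, color="grey", lw=0.6)
    x = np.arange(idx.size)
    for label, p in zip(labels, profiles):
        y = p.scores[idx].copy()
        y[p.no_call_mask[idx]] = np.nan
        ax.plot(x, y, "-", lw=0.8, alpha=0.8, label=label)
    ax.set_xlabel(f"{gene} sliding windows (genomic order)")
    ax.set_ylabel("logCNR score (log2)")
    ax.set_title(f"merged run — {gene}")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return labels


# ----------------------------------------------------------------------
# candidate flagging
# ----------------------------------------------------------------------

def _runs(mask: np.ndarray, indices: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of template-consecutive flagged windows within `indices`."""
    flagged = indices[mask]
    if flagged.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(flagged) != 1) + 1
    return np.split(flagged, breaks)


def _step_fit_edge(
    ratio: np.ndarray, rho_in: float, left: bool
) -> int:
    """Least-squares change point of a 1 -> rho_in step in a depth-ratio track.

    For a left edge the model is ratio=1 before the cut and rho_in after;
    for a right edge the reverse.  Returns the cut index (0..n)."""
    a = (ratio - 1.0) ** 2  # cost of calling a position "normal"
    c = (ratio - rho_in) ** 2  # cost of calling a position "in event"
    if not left:
        a, c = c, a
    # cost(k) = sum(a[:k]) + sum(c[k:])
    costs = np.concatenate([[0.0], np.cumsum(a)]) + np.concatenate(
        [np.cumsum(c[::-1])[::-1], [0.0]]
    )
    return int(np.argmin(costs))


def _refine_edge_per_base(
    template: WindowTemplate,
    query: SampleCoverage,
    pool: StaticPool,
    region,
    coarse: int,
    rho_in: float,
    left: bool,
) -> int:
    lo = max(region.start, coarse - template.window_len)
    hi = min(region.end, coarse + template.window_len)
    if hi - lo < 2:
        return coarse
    i0, i1 = template.index_range(region.chrom, lo, hi)
    p = pool.mean_depth_per_pos[i0:i1]
    q = query.depths[i0:i1].astype(float)
    usable = p >= 1.0
    if usable.sum() < 2:
        return coarse
    ratio = np.ones(i1 - i0)
    ratio[usable] = q[usable] / p[usable]
    return lo + _step_fit_edge(ratio, rho_in, left)


def _refine_edge_window_means(
    template: WindowTemplate,
    profile: LogCNRProfile,
    run: np.ndarray,
    rho_in: float,
    left: bool,
) -> int | None:
    """Invert transition-window scores to a breakpoint estimate.

    A window that straddles the edge of an event with inside-depth ratio
    rho_in shows ratio 1 + f*(rho_in - 1), f being the fraction of the
    window inside the event; solving for f places the breakpoint within the
    window.  Averages the estimates of all transition windows.
    """
    edge_wi = run[0] if left else run[-1]
    region_i = template.window_region_index[edge_wi]
    span = template.window_len // template.slide_len + 1
    lo = max(0, edge_wi - span)
    hi = min(template.n_windows - 1, edge_wi + span)
    estimates = []
    for wi in range(lo, hi + 1):
        if template.window_region_index[wi] != region_i:
            continue
        s = profile.scores[wi]
        if not np.isfinite(s):
            continue
        rho = 2.0 ** s
        f = (1.0 - rho) / (1.0 - rho_in)
        if not 0.15 < f < 0.85:
            continue
        w = template.windows[wi]
        if left:
            estimates.append(w.end - f * w.length)
        else:
            estimates.append(w.start + f * w.length)
    if not estimates:
        return None
    return int(round(float(np.mean(estimates))))


def _candidate_from_run(
    profile: LogCNRProfile,
    run: np.ndarray,
    direction: str,
    query: SampleCoverage | None,
    pool: StaticPool | None,
    refine: bool,
    note: str = "",
) -> CNVCandidate:
    template = profile.template
    ws = [template.windows[i] for i in run]
    start = min(w.start for w in ws)
    end = max(w.end for w in ws)
    scores = profile.scores[run]
    mean_score = float(np.nanmean(scores))
    rho_in = float(2.0 ** np.nanmedian(scores))

    if refine and abs(rho_in - 1.0) > 1e-6:
        first_region = template.regions[template.window_region_index[run[0]]]
        last_region = template.regions[template.window_region_index[run[-1]]]
        per_base = (
            query is not None
            and pool is not None
            and pool.mean_depth_per_pos is not None
        )
        if per_base:
            start = _refine_edge_per_base(
                template, query, pool, first_region, start, rho_in, left=True
            )
            end = _refine_edge_per_base(
                template, query, pool, last_region, end, rho_in, left=False
            )
        else:
            left = _refine_edge_window_means(template, profile, run, rho_in, left=True)
            right = _refine_edge_window_means(template, profile, run, rho_in, left=False)
            if left is not None:
                start = max(first_region.start, left)
            if right is not None:
                end = min(last_region.end, right)
        if end <= start:  # degenerate refinement; fall back to the window union
            start = min(w.start for w in ws)
            end = max(w.end for w in ws)

    return CNVCandidate(
        gene=ws[0].gene,
        chrom=ws[0].chrom,
        start=int(start),
        end=int(end),
        direction=direction,
        mean_score=mean_score,
        n_windows=len(run),
        breakpoint_resolution=template.slide_len,
        note=note,
    )


def flag_candidates(
    profile: LogCNRProfile,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    dup_threshold: float = DEFAULT_DUP_THRESHOLD,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
    refine: bool = True,
    include_mosaic_pass: bool = False,
    mosaic_del_threshold: float = MOSAIC_DEL_THRESHOLD,
    mosaic_min_consecutive: int = MOSAIC_MIN_CONSECUTIVE,
    query: SampleCoverage | None = None,
    pool: StaticPool | None = None,
) -> list[CNVCandidate]:
    """Shortlist maximal runs of windows beyond the deletion/duplication thresholds.

    Runs never cross gene boundaries.  The optional mosaic pass rescans with
    a low deletion threshold and a longer run requirement (a 30% mosaic
    single-allele deletion scores only ~ -0.23) and labels its extra hits
    "possible mosaic".  Passing ``query`` and ``pool`` enables per-base
    breakpoint refinement.
    """
    if not (del_threshold < 0 < dup_threshold):
        raise InputError("need del_threshold < 0 < dup_threshold")
    template = profile.template
    scores = profile.scores
    candidates: list[CNVCandidate] = []
    main_runs: list[np.ndarray] = []
    for gene in template.genes():
        idx = template.gene_window_indices(gene)
        s = scores[idx]
        with np.errstate(invalid="ignore"):
            del_mask = s <= del_threshold
            dup_mask = s >= dup_threshold
        for mask, direction in ((del_mask, "deletion"), (dup_mask, "duplication")):
            for run in _runs(mask, idx):
                if run.size >= min_consecutive:
                    main_runs.append(run)
                    candidates.append(
                        _candidate_from_run(
                            profile, run, direction, query, pool, refine
                        )
                    )
        if include_mosaic_pass:
            with np.errstate(invalid="ignore"):
                mosaic_mask = s <= mosaic_del_threshold
            covered = set(np.concatenate(main_runs).tolist()) if main_runs else set()
            for run in _runs(mosaic_mask, idx):
                if run.size < mosaic_min_consecutive:
                    continue
                if any(int(i) in covered for i in run):
                    continue
                candidates.append(
                    _candidate_from_run(
                        profile, run, "deletion", query, pool, refine,
                        note="possible mosaic",
                    )
                )
    candidates.sort(key=lambda c: (c.chrom, c.start, c.end))
    return candidates


def candidates_to_frame(candidates: list[CNVCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in candidates],
            "chrom": [c.chrom for c in candidates],
            "start": [c.start for c in candidates],
            "end": [c.end for c in candidates],
            "direction": [c.direction for c in candidates],
            "mean_score": [c.mean_score for c in candidates],
            "n_windows": [c.n_windows for c in candidates],
            "breakpoint_resolution_nt": [c.breakpoint_resolution for c in candidates],
            "note": [c.note for c in candidates],
        }
    )


def write_candidates_tsv(candidates: list[CNVCandidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def write_candidates_bed(candidates: list[CNVCandidate], path: str | Path) -> None:
    """Candidates as BED (0-based half-open) for genome-browser loading."""
    with open(path, "w") as fh:
        for c in candidates:
            name = f"{c.gene}_{c.direction}"
            if c.note:
                name += "_" + c.note.replace(" ", "-")
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{c.mean_score:.3f}\n"
            )
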
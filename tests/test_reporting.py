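import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelcnv.errors import InputError, UnknownGeneError
from panelcnv.pooling import build_static_pools, select_pool
from panelcnv.reporting import (
    flag_candidates,
    gene_plot,
    gene_table,
    merged_run_plot,
    write_candidates_bed,
    write_candidates_tsv,
)
from panelcnv.scoring import LogCNRProfile, score_sample
from panelcnv.synthetic import (
    CNVEvent,
    SimulationConfig,
    simulate_cohort,
    simulate_panel,
)
from panelcnv.windows import TargetRegion, WindowTemplate

from conftest import constant_coverage


def profile_from_scores(template, scores, sample_id="Q"):
    scores = np.asarray(scores, dtype=float)
    return LogCNRProfile(
        sample_id=sample_id,
        pool_id=0,
        scores=scores,
        no_call_mask=np.isnan(scores),
        floor_mask=np.zeros(template.n_windows, dtype=bool),
        template=template,
    )


@pytest.fixture
def deletion_cohort():
    """Noise-free cohort with a heterozygous deletion of GENE002 exon2."""
    cfg = SimulationConfig(
        seed=3, n_regions=12, n_genes=3, n_normals=8,
        noise_cv=0.0, sample_depth_sd=0.0, lot_effect_sd=0.0,
    )
    regions = simulate_panel(cfg)
    target = [r for r in regions if r.gene == "GENE002"][1]
    ev = CNVEvent("Q1", 0.5, chrom=target.chrom, start=target.start, end=target.end)
    cohort = simulate_cohort(dataclasses.replace(cfg, events=[ev]))
    pools = build_static_pools(cohort.normals(), 8)
    query = cohort.sample("Q1")
    pool = select_pool(query, pools)
    profile = score_sample(query, pool, cohort.template)
    return cohort, query, pool, profile, target


def test_gene_table_rows_grouped_in_genomic_order(deletion_cohort):
    cohort, _, _, profile, target = deletion_cohort
    df = gene_table(profile, "GENE002")
    assert (df["gene"] == "GENE002").all()
    assert list(df["start"]) == sorted(df["start"])
    # deleted exon scores ~ -1, neighbours ~ 0
    in_exon = (df["start"] >= target.start) & (df["end"] <= target.end)
    assert np.allclose(df.loc[in_exon, "score"], -1.0, atol=1e-9)
    assert np.allclose(df.loc[~in_exon, "score"], 0.0, atol=1e-9)


def test_gene_table_unknown_gene_lists_valid_genes(deletion_cohort):
    _, _, _, profile, _ = deletion_cohort
    with pytest.raises(UnknownGeneError, match="GENE001"):
        gene_table(profile, "NOSUCH")


def test_gene_plot_writes_file_and_returns_sidecar(deletion_cohort, tmp_path):
    _, _, _, profile, _ = deletion_cohort
    out = tmp_path / "g.png"
    df = gene_plot(profile, "GENE002", out)
    assert out.exists() and out.stat().st_size > 0
    assert {"score", "no_call"} <= set(df.columns)


def test_no_call_windows_render_as_gaps(small_template, tmp_path):
    scores = np.zeros(small_template.n_windows)
    scores[2] = np.nan
    profile = profile_from_scores(small_template, scores)
    df = gene_plot(profile, "GENE_A", tmp_path / "a.png")
    assert df["no_call"].iloc[2]


def test_merged_run_plot_anonymizes_labels(deletion_cohort, tmp_path):
    cohort, _, pool, _, _ = deletion_cohort
    pools = build_static_pools(cohort.normals(), 8)
    profiles = [
        score_sample(s, select_pool(s, pools), cohort.template)
        for s in cohort.normals()[:5]
    ]
    labels = merged_run_plot(profiles, "GENE001", tmp_path / "m.png", anonymize=True)
    ids = {p.sample_id for p in profiles}
    assert not any(lbl in ids for lbl in labels)
    labels2 = merged_run_plot(profiles, "GENE001", tmp_path / "m2.png")
    assert set(labels2) == ids
    with pytest.raises(InputError):
        merged_run_plot(profiles[:1], "GENE001", tmp_path / "m3.png")


# ----------------------------------------------------------------------
# candidate flagging
# ----------------------------------------------------------------------

def test_all_zero_profile_yields_no_candidates(small_template):
    profile = profile_from_scores(small_template, np.zeros(small_template.n_windows))
    assert flag_candidates(profile) == []


def test_threshold_order_enforced(small_template):
    profile = profile_from_scores(small_template, np.zeros(small_template.n_windows))
    with pytest.raises(InputError):
        flag_candidates(profile, del_threshold=0.5, dup_threshold=0.3)


def test_single_exon_deletion_yields_one_exact_candidate(deletion_cohort):
    _, query, pool, profile, target = deletion_cohort
    cands = flag_candidates(profile, query=query, pool=pool)
    assert len(cands) == 1
    c = cands[0]
    assert c.direction == "deletion" and c.gene == "GENE002"
    assert c.breakpoint_resolution == profile.template.slide_len
    # noise-free per-base refinement recovers the exact exon span
    assert (c.start, c.end) == (target.start, target.end)


def test_partial_exon_breakpoints_within_slide_length():
    cfg = SimulationConfig(
        seed=4, n_regions=12, n_genes=3, n_normals=8, region_length_range=(250, 350),
    )
    regions = simulate_panel(cfg)
    r = [x for x in regions if x.gene == "GENE001"][0]
    b, e = r.start + 90, r.end - 70
    ev = CNVEvent("Q1", 0.5, chrom=r.chrom, start=b, end=e)
    cohort = simulate_cohort(dataclasses.replace(cfg, events=[ev]))
    pools = build_static_pools(cohort.normals(), 8)
    query = cohort.sample("Q1")
    pool = select_pool(query, pools)
    profile = score_sample(query, pool, cohort.template)
    cands = [c for c in flag_candidates(profile, query=query, pool=pool)
             if c.gene == "GENE001"]
    assert len(cands) == 1
    assert abs(cands[0].start - b) <= cohort.template.slide_len
    assert abs(cands[0].end - e) <= cohort.template.slide_len


def test_window_mean_fallback_refinement_close_to_truth():
    """Without per-base data, transition-window inversion still places the
    breakpoints to about sliding-length accuracy (noise-free)."""
    cfg = SimulationConfig(
        seed=5, n_regions=8, n_genes=2, n_normals=8, region_length_range=(300, 350),
        noise_cv=0.0, sample_depth_sd=0.0,
    )
    regions = simulate_panel(cfg)
    r = [x for x in regions if x.gene == "GENE001"][0]
    b, e = r.start + 97, r.end - 83
    ev = CNVEvent("Q1", 0.5, chrom=r.chrom, start=b, end=e)
    cohort = simulate_cohort(dataclasses.replace(cfg, events=[ev]))
    pools = build_static_pools(cohort.normals(), 8)
    query = cohort.sample("Q1")
    profile = score_sample(query, select_pool(query, pools), cohort.template)
    cands = flag_candidates(profile)  # no query/pool: window-mean fallback
    c = [c for c in cands if c.gene == "GENE001"][0]
    assert abs(c.start - b) <= cohort.template.slide_len
    assert abs(c.end - e) <= cohort.template.slide_len


def two_gene_templates():
    ra = TargetRegion("chr1", 0, 300, "GA", "e1")
    rb = TargetRegion("chr1", 1000, 1300, "GB", "e1")
    t_ab = WindowTemplate([ra, rb], 75, 10)
    t_ba = WindowTemplate([rb, ra], 75, 10)
    return t_ab, t_ba


def test_candidates_invariant_to_gene_order():
    t_ab, t_ba = two_gene_templates()
    n = t_ab.n_windows // 2
    scores_a = np.full(n, -1.0)
    scores_b = np.zeros(n)
    prof_ab = profile_from_scores(t_ab, np.concatenate([scores_a, scores_b]))
    prof_ba = profile_from_scores(t_ba, np.concatenate([scores_b, scores_a]))
    c_ab = {(c.gene, c.start, c.end, c.direction) for c in flag_candidates(prof_ab, refine=False)}
    c_ba = {(c.gene, c.start, c.end, c.direction) for c in flag_candidates(prof_ba, refine=False)}
    assert c_ab == c_ba == {("GA", 0, 300, "deletion")}


def test_candidate_spans_never_cross_gene_boundaries():
    t_ab, _ = two_gene_templates()
    # every window deleted in both genes: must yield one candidate per gene
    profile = profile_from_scores(t_ab, np.full(t_ab.n_windows, -1.0))
    cands = flag_candidates(profile, refine=False)
    assert sorted((c.gene, c.start, c.end) for c in cands) == [
        ("GA", 0, 300), ("GB", 1000, 1300),
    ]


@settings(max_examples=50, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=10_000),
    mc=st.integers(min_value=1, max_value=6),
)
def test_raising_min_consecutive_never_adds_candidates(seed, mc):
    t_ab, _ = two_gene_templates()
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 0.6, t_ab.n_windows)
    profile = profile_from_scores(t_ab, scores)
    n1 = len(flag_candidates(profile, min_consecutive=mc, refine=False))
    n2 = len(flag_candidates(profile, min_consecutive=mc + 1, refine=False))
    assert n2 <= n1


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_raising_thresholds_never_adds_flagged_windows(seed):
    """Stricter thresholds shrink the set of windows inside candidate spans
    (the run count itself can change when a long run splits)."""
    t_ab, _ = two_gene_templates()
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 0.6, t_ab.n_windows)
    profile = profile_from_scores(t_ab, scores)

    def flagged_windows(del_t, dup_t):
        total = 0
        for c in flag_candidates(profile, del_threshold=del_t, dup_threshold=dup_t,
                                 min_consecutive=1, refine=False):
            total += c.n_windows
        return total

    assert flagged_windows(-0.8, 0.5) <= flagged_windows(-0.5, 0.3)


def test_mosaic_pass_labels_and_does_not_duplicate(deletion_cohort):
    _, query, pool, profile, _ = deletion_cohort
    cands = flag_candidates(profile, include_mosaic_pass=True, query=query, pool=pool)
    # the clear heterozygous deletion is caught by the main pass only
    assert sum(c.note == "possible mosaic" for c in cands) == 0
    assert len(cands) == 1


def test_candidate_writers(deletion_cohort, tmp_path):
    _, query, pool, profile, _ = deletion_cohort
    cands = flag_candidates(profile, query=query, pool=pool)
    write_candidates_tsv(cands, tmp_path / "c.tsv")
    write_candidates_bed(cands, tmp_path / "c.bed")
    bed_fields = (tmp_path / "c.bed").read_text().strip().split("\t")
    assert bed_fields[0] == cands[0].chrom
    assert int(bed_fields[1]) == cands[0].start
    assert "deletion" in bed_fields[3]
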
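import logging

import numpy as np
import pytest

from panelcnv.coverage import (
    SampleCoverage,
    compute_bam_coverage,
    load_per_locus_coverage,
    sample_mean_depth,
    window_mean_depth,
    write_per_locus_coverage,
)
from panelcnv.errors import EmptyOverlapError, InputError, ParseError
from panelcnv.windows import TargetRegion, WindowTemplate

from conftest import constant_coverage


def write_locus_file(path, rows):
    with open(path, "w") as fh:
        fh.write("Locus\tTotal_Depth\tAverage_Depth\n")
        for chrom, pos1, depth in rows:
            fh.write(f"{chrom}:{pos1}\t{depth}\t{depth}\n")


def test_per_locus_round_trip(small_template, tmp_path):
    rng = np.random.default_rng(0)
    depths = rng.integers(0, 500, small_template.n_positions)
    cov = SampleCoverage("S1", depths, small_template)
    path = tmp_path / "S1.coverage.tsv"
    write_per_locus_coverage(cov, path)
    back = load_per_locus_coverage(path, small_template)
    assert back.sample_id == "S1"
    np.testing.assert_array_equal(back.depths, depths)


def test_constant_depth_gives_that_mean(small_template, tmp_path):
    pos = small_template.positions()
    write_locus_file(
        tmp_path / "c.tsv",
        [(c, p + 1, 100) for c, p in zip(pos["chrom"], pos["pos"])],
    )
    cov = load_per_locus_coverage(tmp_path / "c.tsv", small_template)
    assert cov.mean_depth == 100.0


def test_missing_positions_zero_filled_with_warning(small_template, tmp_path, caplog):
    pos = small_template.positions()
    rows = [(c, p + 1, 200) for c, p in zip(pos["chrom"], pos["pos"])]
    kept = rows[: len(rows) - 25]  # drop 25 targeted positions
    write_locus_file(tmp_path / "m.tsv", kept)
    with caplog.at_level(logging.WARNING, logger="panelcnv"):
        cov = load_per_locus_coverage(tmp_path / "m.tsv", small_template)
    assert (cov.depths == 0).sum() == 25
    assert "25 targeted positions missing" in caplog.text
    # zero-filling can only lower the mean
    assert cov.mean_depth < 200.0


def test_off_target_positions_ignored(small_template, tmp_path):
    pos = small_template.positions()
    rows = [(c, p + 1, 50) for c, p in zip(pos["chrom"], pos["pos"])]
    rows += [("chr9", 12345, 999), ("chr1", 1, 999)]
    write_locus_file(tmp_path / "o.tsv", rows)
    cov = load_per_locus_coverage(tmp_path / "o.tsv", small_template)
    assert cov.depths.max() == 50


def test_malformed_locus_reports_line_number(small_template, tmp_path):
    with open(tmp_path / "bad.tsv", "w") as fh:
        fh.write("Locus\tTotal_Depth\nchr1:1001\t5\nnot-a-locus\t7\n")
    with pytest.raises(ParseError, match="line 3"):
        load_per_locus_coverage(tmp_path / "bad.tsv", small_template)


def test_no_overlap_is_an_error(small_template, tmp_path):
    write_locus_file(tmp_path / "e.tsv", [("chrX", 1, 10), ("chrX", 2, 10)])
    with pytest.raises(EmptyOverlapError):
        load_per_locus_coverage(tmp_path / "e.tsv", small_template)


def test_window_mean_examples(small_template):
    t = small_template
    cov = constant_coverage(t, 200)
    assert window_mean_depth(cov, t.windows[0]) == 200.0

    # halves at 100/300 average to 200 over an even-length window
    depths = np.full(t.n_positions, 100, dtype=np.int64)
    w = t.windows[0]  # 75 nt; use its first 74 positions? window is odd;
    # use the 40-nt chr2 region instead (even length)
    i0, i1 = t.index_range("chr2", 500, 540)
    depths[i0 : i0 + 20] = 100
    depths[i0 + 20 : i1] = 300
    cov2 = SampleCoverage("S", depths, t)
    w_b = [w for w in t.windows if w.chrom == "chr2"][0]
    assert window_mean_depth(cov2, w_b) == 200.0

    # 84-nt last window of the 134-nt region, one covered base
    depths = np.zeros(t.n_positions, dtype=np.int64)
    last = t.windows[5]
    assert last.length == 84
    i0, _ = t.index_range(last.chrom, last.start, last.end)
    depths[i0] = 1
    cov3 = SampleCoverage("S", depths, t)
    assert window_mean_depth(cov3, last) == pytest.approx(1 / 84, abs=1e-12)


def test_window_means_match_per_position_oracle(small_template):
    rng = np.random.default_rng(1)
    depths = rng.integers(0, 400, small_template.n_positions)
    cov = SampleCoverage("S", depths, small_template)
    means = cov.window_means()
    for wi, w in enumerate(small_template.windows):
        i0, i1 = small_template.index_range(w.chrom, w.start, w.end)
        assert means[wi] == pytest.approx(depths[i0:i1].sum() / (i1 - i0), abs=1e-9)


def test_sample_mean_is_position_weighted_and_window_invariant(small_regions):
    rng = np.random.default_rng(2)
    t1 = WindowTemplate(small_regions, 75, 10)
    t2 = WindowTemplate(small_regions, 50, 5)
    depths = rng.integers(0, 400, t1.n_positions)
    m1 = SampleCoverage("S", depths, t1).mean_depth
    m2 = SampleCoverage("S", depths, t2).mean_depth
    assert m1 == m2 == pytest.approx(depths.sum() / depths.size)
    # two equal-length regions at 100x and 200x average to 150x
    regs = [
        TargetRegion("chr1", 0, 100, "G", "e1"),
        TargetRegion("chr1", 500, 600, "G", "e2"),
    ]
    t3 = WindowTemplate(regs, 75, 10)
    d = np.concatenate([np.full(100, 100), np.full(100, 200)])
    assert sample_mean_depth(SampleCoverage("S", d, t3)) == 150.0


# ----------------------------------------------------------------------
# BAM pileup
# ----------------------------------------------------------------------

def make_bam(path, reads, chrom="chr1", ref_len=5000):
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": ref_len}]}
    reads = sorted(reads, key=lambda r: r[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, start, length, mapq, flag in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = "A" * length
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = f"{length}M"
            a.flag = flag
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            bam.write(a)
    pysam.index(str(path))


@pytest.fixture
def one_region_template():
    return WindowTemplate([TargetRegion("chr1", 1000, 1075, "G", "e1")], 75, 10)


def test_bam_full_coverage(one_region_template, tmp_path):
    bam = tmp_path / "a.bam"
    make_bam(bam, [(f"r{i}", 990, 100, 60, 0) for i in range(50)])
    cov = compute_bam_coverage(bam, one_region_template)
    assert (cov.depths == 50).all()


def test_bam_mapq_filter_zeroes_depth(one_region_template, tmp_path):
    bam = tmp_path / "b.bam"
    make_bam(bam, [(f"r{i}", 990, 100, 10, 0) for i in range(5)])
    cov = compute_bam_coverage(bam, one_region_template, min_mapq=30)
    assert (cov.depths == 0).all()


def test_bam_duplicates_excluded_by_default(one_region_template, tmp_path):
    bam = tmp_path / "c.bam"
    DUP = 0x400
    reads = [("r1", 990, 100, 60, 0), ("r2", 990, 100, 60, 0),
             ("d1", 990, 100, 60, DUP), ("d2", 990, 100, 60, DUP),
             ("d3", 990, 100, 60, DUP)]
    cov = make_bam(bam, reads)
    cov = compute_bam_coverage(bam, one_region_template)
    assert (cov.depths == 2).all()
    cov_all = compute_bam_coverage(bam, one_region_template, count_duplicates=True)
    assert (cov_all.depths == 5).all()


def test_bam_missing_index_is_actionable(one_region_template, tmp_path):
    bam = tmp_path / "d.bam"
    make_bam(bam, [("r1", 990, 100, 60, 0)])
    (tmp_path / "d.bam.bai").unlink()
    with pytest.raises(InputError, match="index"):
        compute_bam_coverage(bam, one_region_template)


def test_bam_contig_dialect_mismatch_named(tmp_path):
    template = WindowTemplate([TargetRegion("1", 1000, 1075, "G", "e1")], 75, 10)
    bam = tmp_path / "e.bam"
    make_bam(bam, [("r1", 990, 100, 60, 0)], chrom="chr1")
    with pytest.raises(InputError, match="'1'.*'chr1'"):
        compute_bam_coverage(bam, template)
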
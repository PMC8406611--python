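import numpy as np
import pytest

from panelcnv.coverage import SampleCoverage
from panelcnv.windows import TargetRegion, WindowTemplate


@pytest.fixture
def small_regions():
    """Two genes, three regions: one long, one window-sized, one short."""
    return [
        TargetRegion("chr1", 1000, 1134, gene="GENE_A", label="exon1"),  # 134 nt
        TargetRegion("chr1", 2000, 2075, gene="GENE_A", label="exon2"),  # 75 nt
        TargetRegion("chr2", 500, 540, gene="GENE_B", label="exon1"),  # 40 nt
    ]


@pytest.fixture
def small_template(small_regions):
    return WindowTemplate(small_regions, window_len=75, slide_len=10)


def constant_coverage(template, depth, sample_id="S", run_id="run_1", lot_id=""):
    depths = np.full(template.n_positions, depth, dtype=np.int64)
    return SampleCoverage(sample_id, depths, template, run_id=run_id, lot_id=lot_id)


@pytest.fixture
def flat_cov():
    return constant_coverage


def tile_oracle(region_len, window_len, slide_len):
    """Brute-force cursor tiling: slide until the next full window would pass
    the region end, then absorb the remainder into the last window."""
    if region_len <= window_len:
        return [(0, region_len)]
    starts = [0]
    while starts[-1] + slide_len + window_len <= region_len:
        starts.append(starts[-1] + slide_len)
    windows = [(s, s + window_len) for s in starts]
    windows[-1] = (windows[-1][0], region_len)
    return windows
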
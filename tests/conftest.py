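import numpy as np
import pytest

from ampdel.io import CopyNumberSegment, GeneLocus, ReadDepthTrack, SVJunction
from ampdel.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_samples=100, seed=7))


@pytest.fixture
def locus():
    return GeneLocus("GENE", "chr1", 1_000_000, 1_100_000, window=(1_010_000, 1_090_000))


def make_segments(sample, chrom, pieces):
    """pieces: list of (start, end, total_cn[, minor_cn])."""
    out = []
    for p in pieces:
        start, end, total = p[0], p[1], p[2]
        minor = p[3] if len(p) > 3 else None
        out.append(CopyNumberSegment(sample, chrom, start, end, total, minor))
    return out


def make_track(sample, chrom, start, end, ratio_fn, bin_size=200):
    """Constant-width depth track with per-bin ratio from ratio_fn(mid)."""
    starts = np.arange(start, end, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, end)
    ratios = np.array([ratio_fn((s + e) / 2) for s, e in zip(starts, ends)], dtype=float)
    return ReadDepthTrack(sample, chrom, starts, ends, ratios)


def deletion_junction(sample, chrom, start, end, name="del1"):
    return SVJunction(sample, chrom, start, "+", chrom, end, "-", name=name)
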
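import numpy as np
import pytest

from selnc.formats_io import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10000,
                     max_len=500, prefix="iv"):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, f"{prefix}{i}"))
    return out


def brute_force_overlaps(intervals, chrom, start, end):
    """O(n) oracle for interval index queries (half-open semantics)."""
    from selnc.se_catalog import norm_chrom

    return [
        iv for iv in intervals
        if norm_chrom(iv.chrom) == norm_chrom(chrom)
        and iv.start < end and iv.end > start
    ]


def sw_affine_oracle(q, t, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Brute-force affine-gap local alignment DP (score only).

    Independent of the package's aligner: three-state DP where a gap of
    length L costs gap_open + L * gap_extend.
    """
    n, m = len(q), len(t)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ok = q[i - 1] in "ACGT" and q[i - 1] == t[j - 1]
            s = match if ok else mismatch
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                                   Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                           Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                           Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def random_dna(rng, length):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def small_bundle():
    """One shared synthetic bundle for cross-module tests."""
    from selnc.synthetic_data import SimConfig, simulate_bundle

    return simulate_bundle(SimConfig(seed=20240917))
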
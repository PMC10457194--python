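"""Peak caller unit and property tests against the brute-force oracle."""

import numpy as np
import pytest

from kappacascade.peakcall import (PeakCallParams, PeakSet, call_peaks,
                                   intersect_replicates, overlap_fraction)

from conftest import make_library
from oracle import oracle_call_peaks

CHROM = {"chr1": 1_000_000}


def _peaks_as_tuples(ps: PeakSet):
    return [(p.chrom, p.start, p.end, p.summit_bp, p.tag_count) for p in ps]


def test_minimal_threshold_four_tags_two_per_strand():
    """Four tags, two per strand, in one 200-bp span yield exactly one peak."""
    tags = [("chr1", 5000, "+"), ("chr1", 5050, "+"),
            ("chr1", 5120, "-"), ("chr1", 5180, "-")]
    lib = make_library(CHROM, tags)
    ps = call_peaks(lib, None, PeakCallParams())
    assert len(ps) == 1
    p = ps.peaks[0]
    assert p.tag_count == 4
    assert p.start <= 5000 and p.end > 5180


def test_strand_rule_three_one_split_rejected():
    """A 3+/1- strand split fails the two-per-strand requirement."""
    tags = [("chr1", 5000, "+"), ("chr1", 5050, "+"), ("chr1", 5100, "+"),
            ("chr1", 5150, "-")]
    lib = make_library(CHROM, tags)
    assert len(call_peaks(lib, None, PeakCallParams())) == 0
    # the same tags pass when the strand rule is disabled (ATAC mode)
    atac = make_library(CHROM, tags, assay="atac", factor=None)
    assert len(call_peaks(atac, None, PeakCallParams())) == 1


def test_empty_library_returns_empty_peakset():
    lib = make_library(CHROM, [])
    assert len(call_peaks(lib, None, PeakCallParams())) == 0


def test_zero_depth_input_rejected():
    lib = make_library(CHROM, [("chr1", 100, "+"), ("chr1", 110, "+"),
                               ("chr1", 120, "-"), ("chr1", 130, "-")])
    empty_input = make_library(CHROM, [], assay="input", factor=None)
    with pytest.raises(ValueError):
        call_peaks(lib, empty_input, PeakCallParams())


def _random_instance(rng):
    L = int(rng.integers(20_000, 100_001))
    chroms = {"chr1": L}
    n_bg = int(rng.integers(0, 300))
    tags = [("chr1", int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-")
            for _ in range(n_bg)]
    # plant a few dense clumps so candidates and merging are exercised
    for _ in range(int(rng.integers(1, 6))):
        c = int(rng.integers(500, L - 500))
        for _ in range(int(rng.integers(3, 15))):
            off = int(rng.integers(-150, 150))
            strand = "+" if rng.random() < 0.5 else "-"
            tags.append(("chr1", min(max(c + off, 0), L - 1), strand))
    if len(tags) > 500:
        tags = tags[:500]
    params = PeakCallParams(
        window_bp=int(rng.choice([100, 200, 300])),
        step_bp=int(rng.choice([20, 25, 50])),
        min_reads=int(rng.choice([3, 4, 6])),
        min_reads_per_strand=int(rng.choice([1, 2])),
        fdr_max=float(rng.choice([0.05, 0.1, 0.3])),
        min_fold_vs_input=float(rng.choice([1.0, 2.0])),
        merge_gap_bp=int(rng.choice([100, 200, 400])),
        factor_fold_filter=[None, 5.0][int(rng.integers(0, 2))],
    )
    with_input = rng.random() < 0.5
    input_lib = None
    if with_input:
        n_in = int(rng.integers(50, 400))
        in_tags = [("chr1", int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-")
                   for _ in range(n_in)]
        input_lib = make_library(chroms, in_tags, assay="input", factor=None)
    return make_library(chroms, tags), input_lib, params


@pytest.mark.parametrize("seed", range(40))
def test_call_peaks_matches_bruteforce_oracle(seed):
    """call_peaks reproduces the literal window-enumeration oracle."""
    rng = np.random.default_rng(1000 + seed)
    lib, input_lib, params = _random_instance(rng)
    got = call_peaks(lib, input_lib, params)
    expected = oracle_call_peaks(lib, input_lib, params)
    assert _peaks_as_tuples(got) == [e[:5] for e in expected]
    for p, e in zip(got, expected):
        assert np.isclose(p.input_count_scaled, e[5], atol=1e-9)
        assert np.isclose(p.pvalue, e[6], atol=1e-12)
        assert np.isclose(p.qvalue, e[7], atol=1e-12)


def test_fold_filter_monotonicity():
    """Raising input-fold thresholds never adds peaks."""
    rng = np.random.default_rng(42)
    lib, input_lib, params = _random_instance(rng)
    params.factor_fold_filter = None
    base = {(p.chrom, p.start, p.end) for p in call_peaks(lib, input_lib, params)}
    prev = base
    for fold in (2.0, 5.0, 10.0):
        params.factor_fold_filter = fold
        cur = {(p.chrom, p.start, p.end) for p in call_peaks(lib, input_lib, params)}
        assert cur <= prev
        prev = cur


def _peakset(intervals):
    from kappacascade.peakcall import Peak
    return PeakSet([
        Peak("chr1", s, e, (s + e) // 2, 10, 1.0, 1e-4, 1e-3) for s, e in intervals
    ])


def test_intersect_replicates_idempotent_and_disjoint():
    a = _peakset([(100, 300), (1000, 1200)])
    assert _peaks_as_tuples(intersect_replicates(a, a)) == _peaks_as_tuples(a)
    b = _peakset([(5000, 5200)])
    assert len(intersect_replicates(a, b)) == 0


def test_intersect_replicates_union_interval():
    a = _peakset([(100, 300)])
    b = _peakset([(250, 500)])
    out = intersect_replicates(a, b)
    assert [(p.start, p.end) for p in out] == [(100, 500)]


def test_overlap_fraction_cases():
    q = _peakset([(100, 300), (1000, 1200), (5000, 5100)])
    ref = _peakset([(250, 400)])
    assert overlap_fraction(q, ref) == pytest.approx(1 / 3)
    assert overlap_fraction(_peakset([(250, 260)]), q) == 1.0
    assert overlap_fraction(_peakset([(90_000, 90_100)]), q) == 0.0
    with pytest.warns(UserWarning):
        assert overlap_fraction(_peakset([]), q) == 0.0
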
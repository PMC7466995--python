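from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covsize.depth_core import (
    DepthParams,
    estimate_coverage,
    iqr_filter,
    lander_waterman,
    mito_screen,
    trim_flanks,
)
from covsize.errors import EstimationError, LocusTooShortError
from covsize.io_formats import CoverageSet, LibraryStats

from _oracles import naive_estimate_coverage, naive_iqr_keep, naive_trim, revcomp
from conftest import random_seq


# ---------------------------------------------------------------------------
# trim_flanks


def test_trimming_constant_profile_preserves_mean():
    profile = np.full(300, 10)
    trimmed = trim_flanks(profile, 75)
    assert trimmed.size == 150
    assert trimmed.mean() == 10


def test_untrimmable_locus_signals_too_short():
    with pytest.raises(LocusTooShortError):
        trim_flanks(np.full(150, 5), 75)
    # strictly greater than 2t is required
    assert trim_flanks(np.full(151, 5), 75).size == 1


def test_trimming_ramped_flanks_recovers_plateau_mean():
    # mapper-style ramp: 0..99 up, plateau at 50, mirrored ramp down
    ramp = np.arange(100) * 50 // 99
    profile = np.concatenate([ramp, np.full(400, 50), ramp[::-1]])
    trimmed = trim_flanks(profile, 75)
    expected = naive_trim(profile.tolist(), 75)
    assert trimmed.tolist() == expected
    assert trimmed.mean() == sum(expected) / len(expected)
    # the trimmed mean sits far closer to the plateau than the raw mean
    assert abs(trimmed.mean() - 50) < abs(profile.mean() - 50)


# ---------------------------------------------------------------------------
# iqr_filter


def test_zero_iqr_degenerate_input_keeps_everything():
    assert iqr_filter([5, 5, 5, 5], 3.0).tolist() == [0, 1, 2, 3]


def test_fewer_than_four_values_kept_with_warning():
    with pytest.warns(UserWarning, match="IQR filter skipped"):
        kept = iqr_filter([1.0, 100.0], 3.0)
    assert kept.tolist() == [0, 1]


def test_high_coverage_outlier_loci_are_removed(rng):
    # 71 plausible single-copy coverages plus 3 grossly inflated loci,
    # the signature of a non-single-copy reference gene
    values = np.concatenate(
        [rng.uniform(2.10, 9.27, size=71), rng.uniform(160.0, 200.0, size=3)]
    )
    kept = iqr_filter(values, 3.0)
    assert set(kept) == set(range(71))
    assert sorted(set(range(74)) - set(kept)) == [71, 72, 73]
    assert kept.tolist() == naive_iqr_keep(values.tolist(), 3.0)


@given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=4, max_size=120))
@settings(max_examples=200)
def test_iqr_filter_matches_brute_force(values):
    assert iqr_filter(values, 3.0).tolist() == naive_iqr_keep(values, 3.0)


# ---------------------------------------------------------------------------
# estimate_coverage


def _const_locus(depth, length=300):
    return np.full(length, depth)


def test_locus_mean_averages_per_locus_means():
    cov = CoverageSet({"a": _const_locus(10), "b": _const_locus(20)})
    summary = estimate_coverage(cov, DepthParams(trim_bases=75))
    assert summary.mean_coverage == 15.0
    assert summary.n_kept == 2


def test_reordering_and_relabeling_loci_leaves_estimate_unchanged(rng):
    loci = {f"x{i}": rng.integers(5, 40, size=int(rng.integers(200, 400)))
            for i in range(12)}
    params = DepthParams(trim_bases=20)
    c1 = estimate_coverage(CoverageSet(dict(loci)), params).mean_coverage
    shuffled = {f"renamed_{k}": v for k, v in reversed(list(loci.items()))}
    c2 = estimate_coverage(CoverageSet(shuffled), params).mean_coverage
    assert c1 == c2


def test_pooled_untrimmed_unfiltered_is_naive_total_ratio(rng):
    loci = {f"x{i}": rng.integers(0, 30, size=int(rng.integers(50, 200)))
            for i in range(8)}
    params = DepthParams(trim_bases=0, iqr_multiplier=float("inf"), averaging="pooled")
    c = estimate_coverage(CoverageSet(dict(loci)), params).mean_coverage
    total = sum(int(v.sum()) for v in loci.values())
    bases = sum(v.size for v in loci.values())
    assert c == pytest.approx(total / bases, rel=1e-12)


def test_rejection_reasons_and_priority(rng):
    loci = {f"ok{i}": _const_locus(10 + i % 3, 400) for i in range(6)}
    loci["short"] = _const_locus(10, 100)           # untrimmable at t=75
    loci["hot"] = _const_locus(500, 400)            # coverage outlier
    loci["hot_and_long"] = _const_locus(500, 5000)  # fails both filters
    summary = estimate_coverage(CoverageSet(loci), DepthParams(trim_bases=75))
    reason = dict(zip(summary.table["locus_id"], summary.table["reason"]))
    assert reason["short"] == "too_short"
    assert reason["hot"] == "coverage_outlier"
    assert reason["hot_and_long"] == "coverage_outlier"  # coverage > length priority
    assert summary.n_kept == 6
    assert summary.rejection_counts == {"too_short": 1, "coverage_outlier": 2}


def test_all_loci_rejected_is_an_explicit_failure():
    cov = CoverageSet({"a": _const_locus(10, 100), "b": _const_locus(10, 120)})
    with pytest.raises(EstimationError, match="too short"):
        estimate_coverage(cov, DepthParams(trim_bases=75))


@pytest.mark.parametrize("averaging", ["locus_mean", "pooled"])
def test_estimate_matches_brute_force_pipeline(rng, averaging):
    for _ in range(20):
        n = int(rng.integers(5, 25))
        loci = {
            f"loc{i}": rng.integers(0, 60, size=int(rng.integers(100, 500)))
            for i in range(n)
        }
        params = DepthParams(trim_bases=30, iqr_multiplier=3.0, averaging=averaging)
        summary = estimate_coverage(CoverageSet(dict(loci)), params)
        c_ref, kept_ref = naive_estimate_coverage(
            {k: v.tolist() for k, v in loci.items()}, 30, 3.0, averaging
        )
        kept = set(summary.table.loc[summary.table["kept"], "locus_id"])
        assert kept == kept_ref
        assert summary.mean_coverage == pytest.approx(c_ref, rel=1e-12)


# ---------------------------------------------------------------------------
# lander_waterman


def test_lander_waterman_identity():
    stats = LibraryStats(n_reads=100, total_bases=10_000)
    est = lander_waterman(stats, 1.0)
    assert est.size_bases == 10_000


def test_genome_size_times_coverage_recovers_effective_bases():
    stats = LibraryStats(n_reads=1000, total_bases=123_457)
    est = lander_waterman(stats, 7.3)
    assert est.size_exact * est.coverage == pytest.approx(est.effective_bases, rel=1e-12)
    assert abs(est.size_bases - est.size_exact) <= 0.5


def test_published_coverage_size_pairs_are_consistent():
    # one library, three single-copy gene sets: the product G*C is the
    # library's base count, so each coverage implies the matching size
    b = int(round(96.18 * 1101e6))
    stats = LibraryStats(n_reads=b // 151, total_bases=b)
    odb = lander_waterman(stats, 93.36)
    busco = lander_waterman(stats, 94.89)
    assert odb.size_mb == pytest.approx(1134.0, rel=1e-3)
    assert busco.size_mb == pytest.approx(1115.9, rel=1e-3)


def test_mito_exclusion_shrinks_effective_bases():
    stats = LibraryStats(n_reads=100, total_bases=10_000, n_mito_reads=2, mito_bases=200)
    est = lander_waterman(stats, 2.0, exclude_mito=True)
    assert est.effective_bases == 9_800
    assert est.size_bases == 4_900


def test_nonpositive_coverage_rejected():
    stats = LibraryStats(n_reads=10, total_bases=1000)
    with pytest.raises(EstimationError):
        lander_waterman(stats, 0.0)
    with pytest.raises(EstimationError):
        lander_waterman(stats, -3.0)


# ---------------------------------------------------------------------------
# mito_screen


def test_read_copied_from_mito_reference_is_flagged(tmp_path, rng, fastq_file):
    mito = random_seq(rng, 2000)
    (tmp_path / "mito.fa").write_text(f">mito\n{mito}\n")
    reads = [
        ("mito_read", mito[500:600]),
        ("mito_rc", revcomp(mito[800:900])),   # canonicalisation: strand must not matter
        ("nuclear", random_seq(rng, 100)),
    ]
    path = fastq_file(reads)
    kept, stats = mito_screen([path], tmp_path / "mito.fa", k=21)
    assert [rid for rid, _s, _q in kept] == ["nuclear"]
    assert stats.n_mito_reads == 2
    assert stats.mito_bases == 200
    assert stats.n_reads == 3
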
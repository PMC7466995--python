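from __future__ import annotations

import numpy as np
import pytest

from covsize.depth_core import DepthParams, estimate_coverage, lander_waterman, mito_screen
from covsize.errors import SimulationError
from covsize.io_formats import read_basecov, read_bed, read_fasta, scan_reads
from covsize.simulate import (
    RepeatFamily,
    SimConfig,
    genome_depth,
    make_diploid,
    make_genome,
    project_locus_coverage,
    run_simulation,
    simulate_reads,
    write_outputs,
)

_DECODE = "ACGT"


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[b] for b in arr)


# ---------------------------------------------------------------------------
# make_genome


def test_background_genome_has_target_size_and_gc():
    cfg = SimConfig(genome_size=100_000, gc=0.4, n_loci=0, seed=1)
    genome, loci, _truth = make_genome(cfg)
    assert genome.size == 100_000
    assert loci == []
    gc = float(np.isin(genome, [1, 2]).mean())
    assert abs(gc - 0.4) < 0.01


def test_exact_repeat_copies_are_findable_by_string_search():
    cfg = SimConfig(
        genome_size=200_000,
        n_loci=0,
        repeat_spec=(RepeatFamily(unit_length=500, copy_number=100, divergence=0.0),),
        seed=2,
    )
    genome, _loci, truth = make_genome(cfg)
    assert len(truth.repeats) == 100
    text = decode(genome)
    s0, e0, _fam = truth.repeats[0]
    unit = text[s0:e0]
    found = 0
    start = 0
    while (hit := text.find(unit, start)) != -1:
        found += 1
        start = hit + 1
    assert found == 100


def test_same_seed_reproduces_identical_genome():
    cfg = SimConfig(genome_size=50_000, n_loci=5, seed=3)
    g1, loci1, _ = make_genome(cfg)
    g2, loci2, _ = make_genome(cfg)
    np.testing.assert_array_equal(g1, g2)
    assert loci1 == loci2


def test_loci_within_bounds_and_non_overlapping():
    cfg = SimConfig(genome_size=120_000, n_loci=20, locus_length=1500, seed=4)
    _genome, loci, _ = make_genome(cfg)
    assert len(loci) == 20
    spans = sorted((s, e) for s, e, _n in loci)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    assert spans[0][0] >= 0 and spans[-1][1] <= 120_000


def test_infeasible_packing_is_an_error():
    with pytest.raises((SimulationError, ValueError)):
        make_genome(SimConfig(genome_size=10_000, n_loci=7, locus_length=1500, seed=5))


# ---------------------------------------------------------------------------
# make_diploid


def test_zero_heterozygosity_yields_identical_haplotypes(rng):
    hap = rng.integers(0, 4, size=10_000).astype(np.uint8)
    a, b, pos = make_diploid(hap, 0.0, rng)
    np.testing.assert_array_equal(a, b)
    assert pos.size == 0


def test_heterozygous_site_count_is_binomial(rng):
    hap = rng.integers(0, 4, size=100_000).astype(np.uint8)
    _a, b, pos = make_diploid(hap, 0.01, rng)
    n = pos.size
    assert abs(n - 1000) < 3 * np.sqrt(1000 * 0.99)
    # every recorded position differs, nothing else does
    diffs = np.flatnonzero(hap != b)
    np.testing.assert_array_equal(diffs, pos)


# ---------------------------------------------------------------------------
# simulate_reads


def test_read_count_follows_coverage_arithmetic():
    cfg = SimConfig(genome_size=1_000_000, depth=30, read_length=100)
    assert cfg.n_reads == 300_000


def test_error_free_reads_match_reference_substring(rng):
    cfg = SimConfig(genome_size=20_000, n_loci=0, depth=0.1, read_length=100, seed=6)
    genome, _loci, _ = make_genome(cfg)
    reads, origins = simulate_reads(
        {"hapA": genome},
        cfg,
        np.random.default_rng(1),
        np.random.default_rng(2),
    )
    for i in range(reads.shape[0]):
        start = origins.loc[i, "start"]
        ref = genome[start : start + 100]
        if origins.loc[i, "strand"] == 1:
            ref = (3 - ref)[::-1]
        np.testing.assert_array_equal(reads[i], ref)


def test_realized_depth_matches_target(rng):
    cfg = SimConfig(genome_size=100_000, n_loci=0, depth=10, read_length=100, seed=7)
    res = run_simulation(cfg)
    assert res.truth.realized_depth_mean == pytest.approx(10.0, rel=0.02)


def test_substitution_errors_appear_at_configured_rate():
    cfg = SimConfig(genome_size=50_000, n_loci=0, depth=5, read_length=100,
                    error_rate=0.01, seed=8)
    genome, _loci, _ = make_genome(cfg)
    rng_r, rng_e = np.random.default_rng(1), np.random.default_rng(2)
    reads, origins = simulate_reads({"hapA": genome}, cfg, rng_r, rng_e)
    mism = 0
    total = 0
    for i in range(reads.shape[0]):
        start = origins.loc[i, "start"]
        ref = genome[start : start + 100]
        read = reads[i]
        if origins.loc[i, "strand"] == 1:
            read = (3 - read)[::-1]
        mism += int((read != ref).sum())
        total += 100
    rate = mism / total
    assert 0.007 < rate < 0.013


# ---------------------------------------------------------------------------
# locus projection (mapper overlap contract)


def test_full_overlap_contract_single_read_inside_locus():
    import pandas as pd

    origins = pd.DataFrame({"source": ["hapA"], "start": [1200], "strand": [0]})
    cov = project_locus_coverage(origins, [(1000, 2500, "loc")], 100, 1.0)
    profile = cov["loc"]
    assert profile[200:300].tolist() == [1] * 100
    assert profile.sum() == 100


def test_zero_overlap_contract_equals_genomewide_depth(rng):
    cfg = SimConfig(genome_size=50_000, n_loci=4, locus_length=1500, depth=8, seed=9)
    res = run_simulation(cfg)
    depth = genome_depth(res.origins, cfg.genome_size, cfg.read_length)
    cov = project_locus_coverage(res.origins, res.loci, cfg.read_length, 0.0)
    for s, e, name in res.loci:
        np.testing.assert_array_equal(cov[name], depth[s:e])


def test_full_overlap_contract_produces_flank_ramps():
    cfg = SimConfig(genome_size=100_000, n_loci=6, locus_length=1500, depth=30, seed=10)
    res = run_simulation(cfg)
    cov = project_locus_coverage(res.origins, res.loci, cfg.read_length, 1.0)
    flank = np.mean([np.concatenate([p[:75], p[-75:]]).mean() for p in cov.loci.values()])
    interior = np.mean([p[99:-99].mean() for p in cov.loci.values()])
    assert flank < 0.75 * interior
    assert interior == pytest.approx(30.0, rel=0.1)


# ---------------------------------------------------------------------------
# mitochondrial contamination accounting


def test_mito_fraction_recovery_and_size_correction(tmp_path):
    cfg = SimConfig(genome_size=300_000, depth=30, mito_fraction=0.02,
                    mito_size=16_000, n_loci=40, seed=11)
    res = run_simulation(cfg)
    paths = write_outputs(res, tmp_path / "sim")
    _kept, stats = mito_screen([paths["reads"]], paths["mito"], k=21)
    flagged = stats.n_mito_reads / stats.n_reads
    assert 0.01 <= flagged <= 0.03  # plausible mito fractions for animal libraries

    cov = read_basecov(paths["basecov"], "bbmap_basecov")
    c = estimate_coverage(cov, DepthParams()).mean_coverage
    with_mito = lander_waterman(stats, c, exclude_mito=False)
    no_mito = lander_waterman(stats, c, exclude_mito=True)
    # subtracting mito bases removes the ~2% inflation of the naive estimate
    g = cfg.genome_size
    assert abs(no_mito.size_exact - g) < abs(with_mito.size_exact - g)
    assert with_mito.size_exact / no_mito.size_exact == pytest.approx(1.02, abs=0.01)


# ---------------------------------------------------------------------------
# outputs round-trip


def test_written_outputs_are_consistent_with_truth(tmp_path):
    cfg = SimConfig(genome_size=30_000, n_loci=3, locus_length=1500, depth=5, seed=12)
    res = run_simulation(cfg)
    paths = write_outputs(res, tmp_path / "out")
    fasta = read_fasta(paths["genome"])
    assert len(fasta["genome"]) == 30_000
    bed = read_bed(paths["loci"])
    assert [(s, e, n) for _c, s, e, n in bed] == res.loci
    stats = scan_reads(paths["reads"])
    assert stats.n_reads == res.truth.n_reads
    assert stats.mean_read_length == cfg.read_length
    cov = read_basecov(paths["basecov"], "bbmap_basecov")
    assert set(cov) == {n for _s, _e, n in res.loci}


def test_diploid_simulation_is_seed_deterministic():
    cfg = SimConfig(genome_size=20_000, n_loci=2, depth=3, het_rate=0.01, seed=13)
    r1 = run_simulation(cfg)
    r2 = run_simulation(cfg)
    np.testing.assert_array_equal(r1.reads, r2.reads)
    assert r1.origins.equals(r2.origins)
    assert r1.truth.to_dict() == r2.truth.to_dict()
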
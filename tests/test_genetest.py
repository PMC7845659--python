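"""Gene-based permutation test: mapping, pruning, statistic, calibration."""

import numpy as np
import pandas as pd
import pytest

from ssripgx import genetest
from ssripgx.synthio import GenotypeMatrix, SimulationConfig, VariantInfo, \
    simulate_genotypes


def _matrix(calls, positions):
    calls = np.asarray(calls, dtype=np.int8)
    variants = [VariantInfo(f"v{j}", "13", p, "A", "G")
                for j, p in enumerate(positions)]
    return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], variants, calls)


def test_map_variants_inclusive_flank_boundaries():
    region = genetest.GeneRegion("G", "13", 1_000_000, 1_010_000, flank=50_000)
    positions = [950_000, 949_999, 1_060_000, 1_060_001, 1_005_000,
                 951_234, 980_000, 1_020_000, 1_059_000, 2_000_000]
    calls = np.zeros((4, len(positions)), dtype=np.int8)
    calls[0, :] = 1
    g = _matrix(calls, positions)
    mapped = genetest.map_variants(g, region)
    assert 0 in mapped            # start - flank exactly
    assert 1 not in mapped        # one bp outside
    assert 2 in mapped            # end + flank exactly
    assert 3 not in mapped
    assert len(mapped) == 7       # 7 in-window of the 10


def test_map_variants_respects_chromosome():
    region = genetest.GeneRegion("G", "7", 100, 200)
    g = _matrix(np.ones((3, 2), dtype=np.int8), [150, 160])
    assert genetest.map_variants(g, region) == []


def test_ld_r2_identity_flip_and_null_level():
    rng = np.random.default_rng(0)
    a = rng.binomial(2, 0.3, 1000).astype(float)
    assert genetest.ld_r2(a, a) == pytest.approx(1.0)
    assert genetest.ld_r2(a, 2 - a) == pytest.approx(1.0)
    n = 1000
    r2s = [genetest.ld_r2(rng.binomial(2, 0.3, n).astype(float),
                          rng.binomial(2, 0.3, n).astype(float))
           for _ in range(300)]
    mean_r2 = np.mean(r2s)
    se = np.std(r2s, ddof=1) / np.sqrt(len(r2s))
    assert abs(mean_r2 - 1 / (n - 1)) < 3 * se
    with pytest.raises(ValueError):
        genetest.ld_r2([1.0], [2.0])


def test_prune_keeps_independent_drops_duplicates():
    rng = np.random.default_rng(1)
    indep = rng.binomial(2, 0.3, (200, 3)).astype(np.int8)
    g = _matrix(indep, [100, 200, 300])
    assert genetest.prune_ld(g, [0, 1, 2]) == [0, 1, 2]
    dup = np.column_stack([indep[:, 0], indep[:, 0], indep[:, 1]]).astype(np.int8)
    g2 = _matrix(dup, [100, 200, 300])
    assert genetest.prune_ld(g2, [0, 1, 2]) == [0, 2]  # first by position kept


def test_prune_one_variant_per_tight_block():
    cfg = SimulationConfig(n_subjects={"A": 500}, n_variants=15, block_size=5,
                           block_rho=0.995, maf_range=(0.3, 0.35), seed=3)
    g = simulate_genotypes(cfg)
    retained = genetest.prune_ld(g, list(range(15)), r2_max=0.5)
    assert len(retained) == 3
    assert retained == [0, 5, 10]


def test_prune_is_phenotype_independent(small_genotypes):
    idx = list(range(small_genotypes.n_variants))
    r1 = genetest.prune_ld(small_genotypes, idx)
    r2 = genetest.prune_ld(small_genotypes, idx)
    assert r1 == r2  # deterministic, no phenotype argument at all


def test_gene_statistic_closed_forms():
    assert genetest.gene_statistic([0.5, 0.2, 0.99]) == 0.0
    assert genetest.gene_statistic([0.01]) == pytest.approx(-2 * np.log(0.01))
    assert genetest.gene_statistic([0.05, 0.5]) == pytest.approx(
        -2 * np.log(0.05))
    with pytest.raises(ValueError):
        genetest.gene_statistic([0.0, 0.5])


def test_empty_signal_gene_has_large_empirical_p(null_phenotype_table):
    cfg = SimulationConfig(n_subjects={"A": 200}, n_variants=5, seed=4)
    g = simulate_genotypes(cfg)
    tab = null_phenotype_table(g.subjects, seed=4)
    # constant phenotype rank: use a phenotype uncorrelated with genotype
    region = genetest.GeneRegion("G", "13", 47_400_000, 47_402_500, flank=0)
    res = genetest.gene_empirical_p(g, tab, "pct_change", region,
                                    family="linear", n_permutations=199, seed=5)
    if res.t_observed == 0.0:
        # zero-signal gene: p reflects at least the mass of nonzero null sums
        assert res.empirical_p > 0.05
    assert 1 / 200 <= res.empirical_p <= 1.0


def test_single_snp_gene_matches_marker_permutation_p(null_phenotype_table):
    rng = np.random.default_rng(6)
    n, k = 300, 2000
    calls = rng.binomial(2, 0.3, (n, 1)).astype(np.int8)
    g = _matrix(calls, [47_400_000])
    tab = null_phenotype_table(g.subjects, seed=6)
    tab["pct_change"] += 0.08 * calls[:, 0]  # moderate signal
    region = genetest.GeneRegion("G", "13", 47_399_000, 47_401_000, flank=0)
    res = genetest.gene_empirical_p(g, tab, "pct_change", region,
                                    family="linear", n_permutations=k, seed=7)
    # direct marker-level permutation of the same single-marker p-value
    eng = genetest.MarkerPvalueEngine(tab["pct_change"].to_numpy(),
                                      tab[["age", "sex"]].to_numpy(float), "linear")
    gcol = calls.astype(float)
    p_obs = eng.pvalues(gcol)[0]
    rng2 = np.random.default_rng(8)
    exceed = sum(eng.pvalues(gcol[rng2.permutation(n)])[0] <= p_obs
                 for _ in range(k))
    marker_p = (exceed + 1) / (k + 1)
    tol = 3 * np.sqrt(marker_p * (1 - marker_p) / k)
    assert abs(res.empirical_p - marker_p) < tol


def test_gene_scan_consistency_and_skips(small_genotypes, small_phenotypes):
    regions = [genetest.GeneRegion("HIT", "13", 47_400_000, 47_420_000, flank=0),
               genetest.GeneRegion("EMPTY", "2", 1, 2, flank=0)]
    tab = small_phenotypes.dropna(subset=["pct_change"]).reset_index(drop=True)
    scan = genetest.gene_scan(small_genotypes, tab, "pct_change", regions,
                              n_permutations=99, seed=9)
    assert list(scan["gene_id"]) == ["HIT", "EMPTY"]
    assert scan.iloc[1]["status"].startswith("skipped")
    single = genetest.gene_empirical_p(small_genotypes, tab, "pct_change",
                                       regions[0], n_permutations=99, seed=9)
    assert scan.iloc[0]["empirical_p"] == pytest.approx(single.empirical_p)
    assert single.n_contributing <= single.n_retained <= single.n_mapped


def test_prop_significant_counts_mapped_markers(small_genotypes, small_phenotypes):
    region = genetest.GeneRegion("G", "13", 47_400_000, 47_420_000, flank=0)
    tab = small_phenotypes.dropna(subset=["pct_change"]).reset_index(drop=True)
    res = genetest.gene_empirical_p(small_genotypes, tab, "pct_change", region,
                                    n_permutations=49, seed=10)
    k, n = map(int, res.prop_significant.split("/"))
    assert n == res.n_mapped and 0 <= k <= n


def test_empirical_p_bounds_and_seed_determinism(small_genotypes,
                                                 small_phenotypes):
    region = genetest.GeneRegion("G", "13", 47_400_000, 47_410_000, flank=0)
    tab = small_phenotypes.dropna(subset=["remitted_code"]).reset_index(drop=True)
    r1 = genetest.gene_empirical_p(small_genotypes, tab, "remitted_code", region,
                                   n_permutations=199, seed=11)
    r2 = genetest.gene_empirical_p(small_genotypes, tab, "remitted_code", region,
                                   n_permutations=199, seed=11)
    assert r1.empirical_p == r2.empirical_p
    assert 1 / 200 <= r1.empirical_p <= 1.0
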
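"""Marker and sample quality control."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from ssripgx import qc
from ssripgx.synthio import MISSING, GenotypeMatrix, SimulationConfig, \
    VariantInfo, simulate_genotypes


def hwe_enumeration(a, h, b):
    """Exact-rational enumeration oracle for the conditional HWE test."""
    n = a + h + b
    rare = min(2 * a + h, 2 * b + h)
    probs = {}
    for x in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - x) // 2
        probs[x] = Fraction(comb(n, x) * comb(n - x, hom_rare) * 2 ** x)
    total = sum(probs.values())
    obs = probs[h]
    return float(sum(v for v in probs.values() if v <= obs) / total)


def test_hwe_monomorphic_and_symmetry():
    assert qc.hwe_exact_p(25, 0, 0) == 1.0
    assert qc.hwe_exact_p(0, 0, 25) == 1.0
    assert qc.hwe_exact_p(12, 7, 3) == pytest.approx(qc.hwe_exact_p(3, 7, 12))
    with pytest.raises(ValueError):
        qc.hwe_exact_p(-1, 2, 3)
    with pytest.raises(ValueError):
        qc.hwe_exact_p(0, 0, 0)


def test_hwe_matches_enumeration_sampled():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 51))
        a = int(rng.integers(0, n + 1))
        h = int(rng.integers(0, n - a + 1))
        b = n - a - h
        assert qc.hwe_exact_p(a, h, b) == pytest.approx(
            hwe_enumeration(a, h, b), abs=1e-12)


def _matrix(calls, positions=None):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    positions = positions or range(1, m + 1)
    variants = [VariantInfo(f"v{j}", "1", p, "A", "G")
                for j, p in enumerate(positions)]
    return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], variants, calls)


def test_variant_stats_arithmetic():
    g = _matrix([[1, 0], [1, 0], [1, 1], [1, 2]])
    st = qc.variant_stats(g)
    assert st.loc[0, "maf"] == pytest.approx(0.5)  # all het
    assert st.loc[1, "maf"] == pytest.approx(0.375)  # 3 alt alleles / 8
    g2 = _matrix([[MISSING, 1], [0, 1], [2, 1], [0, 1]])
    st2 = qc.variant_stats(g2)
    assert st2.loc[0, "missing_rate"] == pytest.approx(0.25)


def test_variant_stats_all_missing_flagged():
    g = _matrix([[MISSING, 1], [MISSING, 0]])
    st = qc.variant_stats(g)
    assert bool(st.loc[0, "all_missing"])
    retained, log = qc.filter_variants(st)
    assert "v0" not in retained
    assert "all_missing" in log.set_index("variant_id").loc["v0", "reason"]


def test_variant_stats_maf_matches_counting_oracle():
    cfg = SimulationConfig(n_subjects={"A": 500}, n_variants=100, seed=8)
    g = simulate_genotypes(cfg)
    st = qc.variant_stats(g)
    for j in range(g.n_variants):
        col = g.calls[:, j]
        af = col.sum() / (2 * len(col))
        assert st.loc[j, "maf"] == pytest.approx(min(af, 1 - af))


def test_filter_variants_boundaries_and_idempotence():
    report = pd.DataFrame([
        {"variant_id": "maf_low", "maf": 0.049, "missing_rate": 0.0,
         "hwe_p": 0.5, "all_missing": False},
        {"variant_id": "miss_edge", "maf": 0.2, "missing_rate": 0.05,
         "hwe_p": 0.5, "all_missing": False},
        {"variant_id": "hwe_edge", "maf": 0.2, "missing_rate": 0.0,
         "hwe_p": 1e-4, "all_missing": False},
        {"variant_id": "ok", "maf": 0.05, "missing_rate": 0.01,
         "hwe_p": 0.2, "all_missing": False},
    ])
    retained, log = qc.filter_variants(report)
    assert retained == ["miss_edge", "ok"]  # missing-rate 5% inclusive
    reasons = log.set_index("variant_id")["reason"]
    assert reasons["maf_low"] == "maf"
    assert reasons["hwe_edge"] == "hwe"  # threshold is strict >
    again, _ = qc.filter_variants(report[report["variant_id"].isin(retained)])
    assert again == retained


def test_filter_variants_constructed_failures():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(6):
        rows.append({"variant_id": f"good{i}", "maf": 0.3, "missing_rate": 0.01,
                     "hwe_p": 0.4, "all_missing": False})
    for i, bad in enumerate(
            [{"maf": 0.01}, {"missing_rate": 0.2}, {"hwe_p": 1e-6},
             {"maf": 0.02, "hwe_p": 1e-9}]):
        row = {"variant_id": f"bad{i}", "maf": 0.3, "missing_rate": 0.01,
               "hwe_p": 0.4, "all_missing": False}
        row.update(bad)
        rows.append(row)
    retained, log = qc.filter_variants(pd.DataFrame(rows))
    assert len(retained) == 6 and len(log) == 4


def test_sample_call_rate_strict_boundary():
    calls = np.zeros((3, 100), dtype=np.int8)
    calls[1, :3] = MISSING   # rate 0.97 exactly -> excluded
    calls[2, :2] = MISSING   # rate 0.98 -> retained
    g = _matrix(calls)
    rates = qc.sample_call_rate(g)
    assert rates["s0"] == 1.0
    kept = qc.filter_samples(rates)
    assert kept == ["s0", "s2"]


def test_ibs_distance_extremes_and_symmetry():
    calls = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [2, 2, 2, 2], [1, 1, 0, 2]],
                     dtype=np.int8)
    g = _matrix(calls)
    d = qc.ibs_distance(g)
    assert d.iloc[0, 1] == 0.0  # duplicated sample
    assert d.iloc[0, 2] == 1.0  # opposite homozygotes everywhere
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def test_ibs_invariant_to_allele_relabeling():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
    g1 = _matrix(calls)
    flipped = calls.copy()
    flipped[:, ::2] = 2 - flipped[:, ::2]
    g2 = _matrix(flipped)
    assert np.allclose(qc.ibs_distance(g1), qc.ibs_distance(g2))


def test_inbreeding_near_zero_for_unrelated():
    cfg = SimulationConfig(n_subjects={"A": 300}, n_variants=2000, block_size=1,
                           block_rho=0.0, seed=9)
    g = simulate_genotypes(cfg)
    f = qc.inbreeding_coeff(g)
    se = f.std(ddof=1) / np.sqrt(len(f))
    assert abs(f.mean()) < 3 * se + 0.01


def test_mds_colinear_points_exact_1d():
    d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    coords = qc.mds_embed(d, k=1)
    rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
    assert np.allclose(rec, d, atol=1e-8)


def test_mds_duplicate_rows_identical_coords():
    d = np.array([
        [0.0, 0.0, 2.0, 2.0],
        [0.0, 0.0, 2.0, 2.0],
        [2.0, 2.0, 0.0, 1.0],
        [2.0, 2.0, 1.0, 0.0]])
    coords = qc.mds_embed(d, k=2)
    assert np.allclose(coords[0], coords[1], atol=1e-8)


def test_mds_separates_two_populations():
    rng = np.random.default_rng(10)
    n, m = 60, 400
    f1 = rng.uniform(0.1, 0.5, m)
    shift = np.clip(f1 + rng.choice([-0.25, 0.25], m), 0.05, 0.95)
    calls = np.vstack([rng.binomial(2, f1, (n // 2, m)),
                       rng.binomial(2, shift, (n // 2, m))]).astype(np.int8)
    g = _matrix(calls)
    coords = qc.mds_embed(qc.ibs_distance(g), k=2)
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    r = np.corrcoef(coords[:, 0], labels)[0, 1]
    assert abs(r) > 0.9


def test_flag_outliers_mad_rule():
    coords = np.zeros((20, 2))
    coords[:, 0] = np.concatenate([np.random.default_rng(1).normal(0, 1, 19), [50]])
    flags = qc.flag_outliers(coords, n_mads=6)
    assert flags[-1] and flags[:-1].sum() == 0


def test_kinship_drops_lower_call_rate_member():
    calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], dtype=np.int8)
    calls = np.tile(calls, (1, 10))
    g = _matrix(calls)
    d = qc.ibs_distance(g)
    rates = pd.Series([0.99, 0.95, 1.0], index=g.subjects)
    res = qc.kinship_exclusions(d, rates, max_ibs_distance=0.1)
    assert res.drop == ["s1"]
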
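"""Generator and file-format tests for the synthetic-data module."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssripgx.synthio import (ITEM_MAX, MISSING, GenotypeMatrix, SimulationConfig,
                             VariantInfo, allocate_items, inject_missingness,
                             read_hrsd, read_plink, simulate_genotypes,
                             simulate_subjects, simulate_trial, write_hrsd,
                             write_plink)


def test_variant_info_invariants():
    with pytest.raises(ValueError):
        VariantInfo("v", "13", 0, "A", "G")
    with pytest.raises(ValueError):
        VariantInfo("v", "13", 10, "A", "A")


def test_genotype_matrix_rejects_bad_calls():
    v = [VariantInfo("v1", "1", 1, "A", "G")]
    with pytest.raises(ValueError):
        GenotypeMatrix(["s1"], v, np.array([[3]]))
    with pytest.raises(ValueError):
        GenotypeMatrix(["s1", "s2"], v, np.array([[1]]))


def test_simulation_is_deterministic(small_config):
    g1 = simulate_genotypes(small_config)
    g2 = simulate_genotypes(small_config)
    assert g1 == g2
    s1, p1 = simulate_trial(g1, small_config)
    s2, p2 = simulate_trial(g2, small_config)
    assert s1.equals(s2) and p1 == p2
    assert inject_missingness(p1, small_config) == inject_missingness(p2, small_config)


def test_perfect_block_correlation_forces_identical_variants():
    cfg = SimulationConfig(n_subjects={"A": 80}, n_variants=12, block_size=4,
                           block_rho=1.0, maf_range=(0.3, 0.3), seed=2)
    g = simulate_genotypes(cfg)
    for start in range(0, 12, 4):
        block = g.calls[:, start:start + 4]
        # identical up to minor-allele orientation
        oriented = np.where(block.mean(axis=0) / 2 > 0.5, 2 - block, block)
        assert (oriented == oriented[:, [0]]).all()


def test_realized_maf_matches_binomial_sampling():
    target = 0.30
    n = 1000
    cfg = SimulationConfig(n_subjects={"A": n}, n_variants=50, block_size=1,
                           block_rho=0.0, maf_range=(target, target), seed=3)
    g = simulate_genotypes(cfg)
    se = np.sqrt(target * (1 - target) / (2 * n))  # binomial se of one variant's AF
    assert abs(g.alt_freq().mean() - target) < 3 * se
    assert (np.abs(g.alt_freq() - target) < 4 * se).mean() > 0.9


def test_minor_allele_orientation(small_genotypes):
    af = small_genotypes.alt_freq()
    assert (af > 0).all() and (af <= 0.5 + 1e-12).all()


def test_degenerate_dynamics_keep_baseline_constant():
    cfg = SimulationConfig(n_subjects={"A": 30}, n_variants=4, improve_mean=0.0,
                           improve_sd=0.0, visit_noise_sd=0.0, seed=4)
    g = simulate_genotypes(cfg)
    _, panel = simulate_trial(g, cfg)
    totals = panel.totals()
    assert np.array_equal(totals, totals[:, [0]].repeat(4, axis=1))
    assert (totals[:, 0] >= 14).all()


def test_strong_causal_effect_orders_week8_means():
    cfg = SimulationConfig(n_subjects={"A": 600}, n_variants=4, block_size=1,
                           maf_range=(0.4, 0.4), causal_effects={"snp0002": 0.2},
                           seed=5)
    g = simulate_genotypes(cfg)
    _, panel = simulate_trial(g, cfg)
    week8 = panel.totals()[:, 3]
    dosage = g.calls[:, g.variant_index("snp0002")]
    means = [week8[dosage == d].mean() for d in (0, 1, 2)]
    assert means[0] > means[1] > means[2]


def test_missingness_patterns_and_baseline_protection(small_config, small_genotypes):
    cfg = dataclasses.replace(small_config, n_subjects={"A": 5000}, n_variants=4,
                              causal_effects={}, missing_probs=(0.92, 0.07, 0.01),
                              seed=6)
    g = simulate_genotypes(cfg)
    _, panel = simulate_trial(g, cfg)
    out = inject_missingness(panel, cfg)
    assert out.observed[:, 0].all()  # baseline never removed
    n_missing = (~out.observed[:, 1:]).sum(axis=1)
    frac_complete = (n_missing == 0).mean()
    se = np.sqrt(0.92 * 0.08 / 5000)
    assert abs(frac_complete - 0.92) < 3 * se
    assert abs((n_missing == 1).mean() - 0.07) < 3 * np.sqrt(0.07 * 0.93 / 5000)


def test_all_complete_probability_one_is_identity(small_trial, small_config):
    _, panel = small_trial
    cfg = dataclasses.replace(small_config, missing_probs=(1.0, 0.0, 0.0))
    assert inject_missingness(panel, cfg) == panel


def test_one_missing_forced_pattern(small_config, small_genotypes):
    cfg = dataclasses.replace(small_config, missing_probs=(0.0, 1.0, 0.0))
    _, panel = simulate_trial(small_genotypes, cfg)
    out = inject_missingness(panel, cfg)
    assert ((~out.observed[:, 1:]).sum(axis=1) == 1).all()


def test_missing_probs_must_sum_to_one(small_trial, small_config):
    _, panel = small_trial
    cfg = dataclasses.replace(small_config, missing_probs=(0.5, 0.1, 0.1))
    with pytest.raises(ValueError):
        inject_missingness(panel, cfg)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(total=st.integers(min_value=0, max_value=sum(ITEM_MAX)),
       w1=st.floats(min_value=0.5, max_value=20))
def test_item_allocation_preserves_total_and_maxima(total, w1):
    weights = np.array(ITEM_MAX, dtype=float)
    weights[0] = w1
    alloc = allocate_items(total, weights)
    assert alloc.sum() == total
    assert (alloc >= 0).all() and (alloc <= np.array(ITEM_MAX)).all()


def test_plink_roundtrip_with_missing(tmp_path):
    variants = [VariantInfo("v1", "13", 100, "A", "G"),
                VariantInfo("v2", "13", 200, "C", "T")]
    calls = np.array([[0, MISSING], [1, 2], [2, 0]], dtype=np.int8)
    g = GenotypeMatrix(["s1", "s2", "s3"], variants, calls)
    write_plink(g, tmp_path / "toy")
    back = read_plink(tmp_path / "toy")
    assert back == g


def test_plink_roundtrip_random_matrix(tmp_path):
    rng = np.random.default_rng(7)
    calls = rng.choice([0, 1, 2, MISSING], size=(50, 200), p=[0.4, 0.3, 0.25, 0.05])
    variants = [VariantInfo(f"v{j}", "1", j + 1, "A", "C") for j in range(200)]
    g = GenotypeMatrix([f"s{i}" for i in range(50)], variants, calls.astype(np.int8))
    write_plink(g, tmp_path / "rand")
    assert read_plink(tmp_path / "rand") == g


def test_plink_bad_magic_rejected(tmp_path):
    g = GenotypeMatrix(["s1"], [VariantInfo("v1", "1", 1, "A", "G")],
                       np.array([[1]], dtype=np.int8))
    write_plink(g, tmp_path / "bad")
    raw = (tmp_path / "bad.bed").read_bytes()
    (tmp_path / "bad.bed").write_bytes(b"\x00\x00\x00" + raw[3:])
    with pytest.raises(ValueError, match="magic"):
        read_plink(tmp_path / "bad")


def test_plink_payload_dimension_mismatch(tmp_path):
    g = GenotypeMatrix(["s1", "s2"], [VariantInfo("v1", "1", 1, "A", "G")],
                       np.array([[1], [2]], dtype=np.int8))
    write_plink(g, tmp_path / "trunc")
    raw = (tmp_path / "trunc.bed").read_bytes()
    (tmp_path / "trunc.bed").write_bytes(raw + b"\x00")
    with pytest.raises(ValueError, match="inconsistent"):
        read_plink(tmp_path / "trunc")


def test_hrsd_tsv_roundtrip(tmp_path, small_trial):
    subjects, panel = small_trial
    write_hrsd(panel, subjects, tmp_path / "hrsd.tsv")
    subj_back, panel_back = read_hrsd(tmp_path / "hrsd.tsv")
    assert panel_back == panel
    assert list(subj_back["subject_id"]) == list(subjects["subject_id"])
    assert (subj_back["sex"].to_numpy() == subjects["sex"].to_numpy()).all()


def test_hrsd_tsv_rejects_unknown_column(tmp_path, small_trial):
    subjects, panel = small_trial
    write_hrsd(panel, subjects, tmp_path / "h.tsv")
    text = (tmp_path / "h.tsv").read_text().splitlines()
    text[0] += "\tbogus"
    text[1] += "\t1"
    (tmp_path / "h.tsv").write_text("\n".join(text))
    with pytest.raises(ValueError, match="unknown col"):
        read_hrsd(tmp_path / "h.tsv")


def test_subject_table_mixes(small_config):
    subj = simulate_subjects(small_config)
    assert set(subj["cohort"]) == {"A", "B"}
    assert subj["age"].min() >= 18
    assert set(subj["sex"]) <= {1, 2}
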
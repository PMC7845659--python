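"""Cross-cohort combination: Fisher / inverse-gamma meta-analysis, pooled
mega-analysis, effective-number-of-tests correction, and significance tiers.

Meta-analysis combines per-cohort p-values with the inverse-gamma model: each
p is transformed to the upper-tail Gamma(alpha, 1) quantile, the transforms
are summed, and the combined p is the upper tail of Gamma(k * alpha, 1) at
the sum.  With shape alpha = 1 this is exactly Fisher's method (-2 ln p terms
against chi-square with 2k degrees of freedom).  Fisher combination is
direction-blind: opposite-direction cohort effects can combine into a small
p, so inspect per-cohort effect signs before interpreting a combined hit.

Mega-analysis pools the cohorts' genotypes (allele-aligned) and reruns the
single-marker machinery on the combined sample.  Multiple-testing correction
across correlated markers uses the Li-Ji effective number of tests from the
eigenvalues of the dosage correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import MISSING, GenotypeMatrix

#: strand-ambiguous allele pairs (indistinguishable under strand flip)
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ThresholdScheme:
    """Strict-inequality significance tiers for markers and genes."""

    snp_significant: float = 5e-4
    snp_suggestive: float = 5e-3
    snp_weak: float = 1e-2
    gene_significant: float = 1e-2
    gene_suggestive: float = 5e-2

    def __post_init__(self) -> None:
        if not self.snp_significant < self.snp_suggestive < self.snp_weak:
            raise ValueError("SNP tiers must be increasing")
        if not self.gene_significant < self.gene_suggestive:
            raise ValueError("gene tiers must be increasing")

    def snp_tier(self, p: float) -> str:
        if not np.isfinite(p):
            return "none"
        for tier, cut in (("significant", self.snp_significant),
                          ("suggestive", self.snp_suggestive),
                          ("weak", self.snp_weak)):
            if p < cut:
                return tier
        return "none"

    def gene_tier(self, p: float) -> str:
        if not np.isfinite(p):
            return "none"
        if p < self.gene_significant:
            return "significant"
        if p < self.gene_suggestive:
            return "suggestive"
        return "none"


def inverse_gamma_combine(p_values, alpha: float = 1.0) -> float:
    """Combine k p-values with the inverse-gamma model (alpha = 1 is Fisher).

    Each p_i maps to t_i solving P(Gamma(alpha, 1) >= t_i) = p_i; the
    combined p is P(Gamma(k * alpha, 1) >= sum t_i).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D list of p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    t = stats.gamma.isf(p, a=alpha)
    return float(stats.gamma.sf(t.sum(), a=alpha * len(p)))


def merge_cohorts(geno_a: GenotypeMatrix, geno_b: GenotypeMatrix,
                  ambiguous_maf_max: float = 0.4
                  ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Pool two cohorts over their shared, allele-reconcilable variants.

    Variants are matched by id.  Matching ref/alt passes through; swapped
    ref/alt flips cohort-B dosages 0<->2; a strand flip (complemented alleles)
    is accepted, with the swap rule applied after complementing.
    Strand-ambiguous variants (A/T, C/G) with MAF above ``ambiguous_maf_max``
    in either cohort are dropped, as are irreconcilable allele pairs; every
    drop is logged.  Returns (pooled matrix, log DataFrame).
    """
    ids_b = {v.id: j for j, v in enumerate(geno_b.variants)}
    overlap = set(geno_b.subjects) & set(geno_a.subjects)
    if overlap:
        raise ValueError(f"cohorts share subject ids: {sorted(overlap)[:3]} ...")
    keep_a, cols_b, log = [], [], []
    for ja, va in enumerate(geno_a.variants):
        if va.id not in ids_b:
            log.append({"variant_id": va.id, "action": "dropped",
                        "reason": "absent_in_b"})
            continue
        jb = ids_b[va.id]
        vb = geno_b.variants[jb]
        pair_a = (va.allele_ref, va.allele_alt)
        pair_b = (vb.allele_ref, vb.allele_alt)
        if frozenset(pair_a) in _AMBIGUOUS:
            af_a = geno_a.alt_freq()[ja]
            af_b = geno_b.alt_freq()[jb]
            mafs = [min(f, 1 - f) for f in (af_a, af_b) if np.isfinite(f)]
            if mafs and max(mafs) > ambiguous_maf_max:
                log.append({"variant_id": va.id, "action": "dropped",
                            "reason": "strand_ambiguous_high_maf"})
                continue
        col_b = geno_b.calls[:, jb].copy()
        if pair_b == pair_a:
            flip = False
        elif pair_b == (pair_a[1], pair_a[0]):
            flip = True
        else:
            comp_b = (_COMPLEMENT.get(pair_b[0], "?"), _COMPLEMENT.get(pair_b[1], "?"))
            if comp_b == pair_a:
                flip = False
            elif comp_b == (pair_a[1], pair_a[0]):
                flip = True
            else:
                log.append({"variant_id": va.id, "action": "dropped",
                            "reason": f"allele_mismatch {pair_a} vs {pair_b}"})
                continue
        if flip:
            nonmiss = col_b != MISSING
            col_b[nonmiss] = 2 - col_b[nonmiss]
            log.append({"variant_id": va.id, "action": "flipped",
                        "reason": "swapped_ref_alt"})
        keep_a.append(ja)
        cols_b.append(col_b)
    ids_a = set(v.id for v in geno_a.variants)
    for vb in geno_b.variants:
        if vb.id not in ids_a:
            log.append({"variant_id": vb.id, "action": "dropped",
                        "reason": "absent_in_a"})
    log_df = pd.DataFrame(log, columns=["variant_id", "action", "reason"])
    if not keep_a:
        import warnings
        warnings.warn("no shared variants between cohorts; empty merge")
        return GenotypeMatrix(geno_a.subjects + geno_b.subjects, [],
                              np.zeros((geno_a.n_subjects + geno_b.n_subjects, 0),
                                       dtype=np.int8)), log_df
    calls = np.vstack([geno_a.calls[:, keep_a],
                       np.column_stack(cols_b)]).astype(np.int8)
    variants = [geno_a.variants[j] for j in keep_a]
    return GenotypeMatrix(geno_a.subjects + geno_b.subjects, variants, calls), log_df


def mega_scan(pooled: GenotypeMatrix, pooled_table: pd.DataFrame, phenotype: str,
              covariates: tuple[str, ...] = ("age", "sex"),
              family: str | None = None,
              include_cohort: bool = False) -> pd.DataFrame:
    """Single-marker scan on the pooled sample (identical machinery to
    :func:`ssripgx.assoc.scan`).  ``include_cohort=True`` adds a cohort
    indicator covariate; the default adjusts for age and sex only.
    """
    from . import assoc

    table = pooled_table
    cov = tuple(covariates)
    if include_cohort:
        table = pooled_table.copy()
        codes = pd.Categorical(table["cohort"]).codes
        table["cohort_indicator"] = codes.astype(float)
        cov = cov + ("cohort_indicator",)
    return assoc.scan(pooled, table, phenotype, covariates=cov, family=family)


def meff_li_ji(correlation: np.ndarray) -> float:
    """Li-Ji effective number of independent tests.

    From the eigenvalues lambda_i of the absolute correlation matrix:
    Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ].
    Meff <= M with equality iff the correlation is the identity.
    """
    c = np.asarray(correlation, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    lam = np.linalg.eigvalsh(np.abs(c))
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def dosage_correlation(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pearson correlation matrix of mean-imputed dosages (for Meff)."""
    from .genetest import _dosage_block

    g = _dosage_block(genotypes, list(range(genotypes.n_variants)))
    keep = np.ptp(g, axis=0) > 0
    return np.corrcoef(g[:, keep], rowvar=False)


def classify_hits(results: pd.DataFrame, scheme: ThresholdScheme | None = None,
                  unit: str = "snp", meta_col: str = "meta_p",
                  mega_col: str = "mega_p") -> pd.DataFrame:
    """Assign a significance tier per unit for the meta and mega columns."""
    scheme = scheme or ThresholdScheme()
    for col in (meta_col, mega_col):
        if col not in results.columns:
            raise KeyError(f"missing column {col!r}")
    tier = scheme.snp_tier if unit == "snp" else scheme.gene_tier
    out = results.copy()
    out["meta_tier"] = [tier(p) for p in out[meta_col]]
    out["mega_tier"] = [tier(p) for p in out[mega_col]]
    return out


def count_suggestive(results: pd.DataFrame, threshold: float = 5e-3,
                     meta_col: str = "meta_p", mega_col: str = "mega_p") -> int:
    """Count units with p below ``threshold`` in BOTH meta and mega columns."""
    if results.empty:
        return 0
    both = (results[meta_col] < threshold) & (results[mega_col] < threshold)
    return int(both.sum())
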
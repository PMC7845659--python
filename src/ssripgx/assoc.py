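"""Covariate-adjusted additive single-marker association and difference tests.

Each variant is tested under the additive model (0/1/2 copies of the minor
allele, one degree of freedom) with age and sex as covariates, by
least-squares linear regression for continuous phenotypes and
maximum-likelihood logistic regression for binary ones; p-values are
two-sided Wald tests.  Binary phenotype codes {1, 2} are mapped so that the
clinically favourable outcome (remitted, response) is the event, hence an
odds ratio above 1 means the minor allele favours a good outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthio import MISSING, GenotypeMatrix

DEFAULT_COVARIATES = ("age", "sex")

#: binary phenotype code -> 0/1 event indicator
EVENT_CODE = {"remitted_code": 2.0, "response_code": 1.0, "stem_code": 1.0}

#: regression family per derived phenotype
PHENOTYPE_FAMILY = {"remitted_code": "logistic", "response_code": "logistic",
                    "stem_code": "logistic", "pct_change": "linear"}


@dataclass
class AssocResult:
    """Single-variant association fit."""

    variant_id: str
    family: str
    beta: float
    se: float
    wald_z: float
    p_value: float
    n_used: int
    maf: float
    covariates: tuple[str, ...]
    status: str = "ok"  # ok | not_converged | monomorphic | too_few

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise ValueError("odds ratio only defined for the logistic family")
        return float(np.exp(self.beta))


def binary_outcome(table: pd.DataFrame, phenotype: str) -> pd.Series:
    """Map a {1,2}-coded phenotype column to a 0/1 event indicator."""
    if phenotype not in EVENT_CODE:
        raise KeyError(f"{phenotype!r} is not a coded binary phenotype")
    col = table[phenotype]
    return (col == EVENT_CODE[phenotype]).astype(float).where(col.notna())


def additive_dosage(genotypes: GenotypeMatrix, variant_id: str,
                    subjects: list[str] | None = None) -> tuple[np.ndarray, float, bool]:
    """Minor-allele dosage for one variant on the analysis sample.

    Returns ``(dosage, maf, flipped)`` where dosage is float with nan for
    missing calls; if the alt-allele frequency on the analysis sample exceeds
    0.5 the dosage is flipped to count the other (minor) allele.
    """
    geno = genotypes if subjects is None else genotypes.subset_subjects(subjects)
    j = geno.variant_index(variant_id)
    col = geno.calls[:, j].astype(float)
    col[geno.calls[:, j] == MISSING] = np.nan
    af = np.nanmean(col) / 2.0 if np.isfinite(col).any() else np.nan
    flipped = bool(af > 0.5)
    if flipped:
        col = 2.0 - col
        af = 1.0 - af
    return col, float(af), flipped


def _nan_result(variant_id, family, n, maf, covariates, status) -> AssocResult:
    return AssocResult(variant_id=variant_id, family=family, beta=np.nan,
                       se=np.nan, wald_z=np.nan, p_value=np.nan, n_used=n,
                       maf=maf, covariates=tuple(covariates), status=status)


def single_marker_test(dosage: np.ndarray, phenotype: np.ndarray,
                       covariates: pd.DataFrame | None, family: str,
                       variant_id: str = "", min_cases: int = 10) -> AssocResult:
    """Fit one additive single-marker regression (complete-case).

    ``family`` is "linear" (OLS) or "logistic" (0/1 outcome, MLE); the
    reported test is the two-sided Wald test of the dosage coefficient.
    Monomorphic dosage and non-convergence / perfect separation are flagged
    in ``status`` with nan statistics rather than raised.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    X = np.column_stack([g] + ([covariates.to_numpy(float)] if cov_names else []))
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    n = int(keep.sum())
    maf = float(np.nanmean(X[:, 0]) / 2.0) if n else np.nan
    maf = min(maf, 1.0 - maf) if np.isfinite(maf) else np.nan
    if n < min_cases:
        return _nan_result(variant_id, family, n, maf, cov_names, "too_few")
    if np.ptp(X[:, 0]) == 0:
        return _nan_result(variant_id, family, n, maf, cov_names, "monomorphic")
    if family == "logistic" and len(np.unique(y)) < 2:
        return _nan_result(variant_id, family, n, maf, cov_names, "monomorphic")
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "linear":
                fit = sm.OLS(y, Xc).fit()
                converged = True
            else:
                fit = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
                converged = bool(fit.mle_retvals.get("converged", False))
                if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
                    converged = False
    except Exception:
        return _nan_result(variant_id, family, n, maf, cov_names, "not_converged")
    if not converged:
        return _nan_result(variant_id, family, n, maf, cov_names, "not_converged")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    z = beta / se
    if family == "linear":
        p = float(2 * stats.t.sf(abs(z), fit.df_resid))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return AssocResult(variant_id=variant_id, family=family, beta=beta, se=se,
                       wald_z=z, p_value=p, n_used=n, maf=maf,
                       covariates=cov_names, status="ok")


def _phenotype_vector(table: pd.DataFrame, phenotype: str,
                      family: str) -> np.ndarray:
    if family == "logistic":
        return binary_outcome(table, phenotype).to_numpy(float)
    return table[phenotype].to_numpy(float)


def scan(genotypes: GenotypeMatrix, table: pd.DataFrame, phenotype: str,
         covariates: tuple[str, ...] = DEFAULT_COVARIATES,
         family: str | None = None,
         variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Single-marker scan of many variants against one phenotype.

    ``table`` must carry one row per subject aligned with ``subject_id``;
    results are ordered by position.  Returns a DataFrame with columns
    variant_id, chromosome, position, maf, beta, or (logistic only), se,
    p_value, n_used, status.
    """
    family = family or PHENOTYPE_FAMILY[phenotype]
    geno = genotypes.subset_subjects(list(table["subject_id"]))
    y = _phenotype_vector(table, phenotype, family)
    cov = table[list(covariates)] if covariates else None
    vids = variant_ids if variant_ids is not None else geno.variant_ids
    order = sorted(vids, key=lambda v: geno.variants[geno.variant_index(v)].position)
    rows = []
    for vid in order:
        j = geno.variant_index(vid)
        dosage, _, _ = additive_dosage(geno, vid)
        res = single_marker_test(dosage, y, cov, family, variant_id=vid)
        v = geno.variants[j]
        rows.append({
            "variant_id": vid, "chromosome": v.chromosome, "position": v.position,
            "maf": res.maf, "beta": res.beta,
            "or": np.exp(res.beta) if family == "logistic" else np.nan,
            "se": res.se, "p_value": res.p_value, "n_used": res.n_used,
            "status": res.status,
        })
    return pd.DataFrame(rows)


def case_control_scan(cases: GenotypeMatrix, controls: GenotypeMatrix,
                      case_cov: pd.DataFrame | None = None,
                      control_cov: pd.DataFrame | None = None,
                      covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Logistic regression of case status on dosage (plus covariates).

    Cases and controls must share the variant panel with matching alleles
    (use :func:`ssripgx.combine.merge_cohorts` first when they do not).
    """
    from .combine import merge_cohorts  # local import to avoid a cycle

    if cases.n_subjects == 0 or controls.n_subjects == 0:
        raise ValueError("both case and control samples are required")
    pooled, _log = merge_cohorts(cases, controls)
    status = np.array([1.0] * cases.n_subjects + [0.0] * controls.n_subjects)
    table = pd.DataFrame({"subject_id": pooled.subjects, "status_code": status})
    if covariates:
        cov = pd.concat([case_cov[list(covariates)], control_cov[list(covariates)]],
                        ignore_index=True)
        table = pd.concat([table, cov], axis=1)
    y = status
    covdf = table[list(covariates)] if covariates else None
    rows = []
    for v in sorted(pooled.variants, key=lambda v: v.position):
        dosage, _, _ = additive_dosage(pooled, v.id)
        res = single_marker_test(dosage, y, covdf, "logistic", variant_id=v.id)
        rows.append({"variant_id": v.id, "chromosome": v.chromosome,
                     "position": v.position, "maf": res.maf, "beta": res.beta,
                     "or": np.exp(res.beta), "se": res.se, "p_value": res.p_value,
                     "n_used": res.n_used, "status": res.status})
    return pd.DataFrame(rows)


def difference_test(group_a, group_b, kind: str = "continuous") -> float:
    """Two-group difference test p-value.

    ``kind="continuous"``: pooled-variance two-sample Student t-test.
    ``kind="categorical"``: Pearson chi-square without continuity correction;
    the two arguments are label sequences, cross-tabulated internally.
    """
    if kind == "continuous":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs at least two observations per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            return 1.0
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if kind == "categorical":
        labels = pd.Series(list(group_a) + list(group_b))
        grp = pd.Series(["a"] * len(group_a) + ["b"] * len(group_b))
        ct = pd.crosstab(grp, labels)
        chi2, p, _, _ = stats.chi2_contingency(ct, correction=False)
        return float(p)
    raise ValueError(f"unknown kind {kind!r}")
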
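"""Marker and sample quality control.

Marker QC: Hardy-Weinberg exact test, genotype missing rate and minor allele
frequency, with the filter thresholds HWE p > 1e-4, missing rate <= 5% and
MAF >= 0.05.  Sample QC: per-sample call rate (retain > 97%), inbreeding
coefficient, pairwise identity-by-state (IBS) distance for kinship screening,
and classical multidimensional scaling of the IBS distance matrix for
population-stratification outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .synthio import MISSING, GenotypeMatrix

DEFAULT_VARIANT_THRESHOLDS = {"hwe_p_min": 1e-4, "missing_max": 0.05, "maf_min": 0.05}
DEFAULT_SAMPLE_MIN_CALL_RATE = 0.97


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value.

    Conditional on the observed allele counts, heterozygote counts of the same
    parity as the observed one are enumerated; the p-value is the summed
    probability of all configurations no more probable than the observed one
    (ties included).  Monomorphic variants return 1.
    """
    a, h, b = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(a, h, b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = a + h + b
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_alt = h + 2 * b  # copies of one allele; symmetric in ref/alt
    n_ref = h + 2 * a
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0
    # log P(het = x | allele counts) up to a shared constant
    xs = np.arange(rare % 2, rare + 1, 2)
    n_hom_rare = (rare - xs) // 2
    n_hom_common = n - xs - n_hom_rare
    logp = (xs * np.log(2.0)
            - gammaln(xs + 1) - gammaln(n_hom_rare + 1) - gammaln(n_hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.nonzero(xs == h)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def variant_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, missing rate and HWE exact p.

    MAF is computed on non-missing calls with minor-allele orientation; a
    variant with zero non-missing calls gets nan stats and ``all_missing``
    True.  Columns: variant_id, chromosome, position, n_called, maf,
    missing_rate, hwe_p, all_missing.
    """
    if genotypes.n_variants == 0 or genotypes.n_subjects == 0:
        raise ValueError("empty genotype matrix")
    calls = genotypes.calls
    miss = calls == MISSING
    n_called = (~miss).sum(axis=0)
    rows = []
    for j, v in enumerate(genotypes.variants):
        col = calls[~miss[:, j], j]
        if col.size == 0:
            rows.append({"variant_id": v.id, "chromosome": v.chromosome,
                         "position": v.position, "n_called": 0, "maf": np.nan,
                         "missing_rate": 1.0, "hwe_p": np.nan, "all_missing": True})
            continue
        af = col.mean() / 2.0
        maf = min(af, 1.0 - af)
        hom_ref = int((col == 0).sum())
        het = int((col == 1).sum())
        hom_alt = int((col == 2).sum())
        rows.append({"variant_id": v.id, "chromosome": v.chromosome,
                     "position": v.position, "n_called": int(n_called[j]),
                     "maf": float(maf),
                     "missing_rate": float(miss[:, j].mean()),
                     "hwe_p": hwe_exact_p(hom_ref, het, hom_alt),
                     "all_missing": False})
    return pd.DataFrame(rows)


def filter_variants(report: pd.DataFrame,
                    thresholds: dict | None = None) -> tuple[list[str], pd.DataFrame]:
    """Apply the marker filters; returns (retained ids, exclusion log).

    A variant is retained iff HWE p > ``hwe_p_min`` (strict), missing rate
    <= ``missing_max`` (inclusive) and MAF >= ``maf_min`` (inclusive).  The
    exclusion log has one row per removed variant with comma-joined reasons.
    Idempotent: filtering an already-filtered report changes nothing.
    """
    th = dict(DEFAULT_VARIANT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    retained, excluded = [], []
    for r in report.itertuples(index=False):
        reasons = []
        if r.all_missing:
            reasons.append("all_missing")
        else:
            if not r.hwe_p > th["hwe_p_min"]:
                reasons.append("hwe")
            if not r.missing_rate <= th["missing_max"]:
                reasons.append("missing")
            if not r.maf >= th["maf_min"]:
                reasons.append("maf")
        if reasons:
            excluded.append({"variant_id": r.variant_id, "reason": ",".join(reasons)})
        else:
            retained.append(r.variant_id)
    return retained, pd.DataFrame(excluded, columns=["variant_id", "reason"])


def sample_call_rate(genotypes: GenotypeMatrix) -> pd.Series:
    """Fraction of non-missing calls per sample, indexed by subject id."""
    if genotypes.n_variants == 0:
        raise ValueError("no variants")
    rate = (genotypes.calls != MISSING).mean(axis=1)
    return pd.Series(rate, index=genotypes.subjects, name="call_rate")


def filter_samples(rates: pd.Series,
                   min_rate: float = DEFAULT_SAMPLE_MIN_CALL_RATE) -> list[str]:
    """Retain samples with call rate strictly greater than ``min_rate``."""
    return list(rates.index[rates > min_rate])


def ibs_distance(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance matrix.

    distance(i, j) = 1 - mean over shared non-missing variants of the allele
    sharing score (identical genotypes 1, one allele shared 0.5, opposite
    homozygotes 0); equivalently 1 - (sum shared alleles) / (2 * #variants).
    Pairs with no shared non-missing variant get nan.
    """
    if genotypes.n_subjects < 2:
        raise ValueError("need at least two samples")
    calls = genotypes.calls.astype(float)
    calls[genotypes.calls == MISSING] = np.nan
    n = genotypes.n_subjects
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(calls[i] - calls[i:])  # (n-i, m)
        shared = ~np.isnan(diff)
        cnt = shared.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            d = np.nansum(diff, axis=1) / (2.0 * cnt)
        d[cnt == 0] = np.nan
        dist[i, i:] = d
        dist[i:, i] = d
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=genotypes.subjects, columns=genotypes.subjects)


def inbreeding_coeff(genotypes: GenotypeMatrix) -> pd.Series:
    """Per-sample inbreeding coefficient F = 1 - observed het / expected het.

    Expected heterozygosity sums 2 p_j (1 - p_j) over the variants called in
    that sample, with p_j the sample-wide alt-allele frequency.
    """
    calls = genotypes.calls
    miss = calls == MISSING
    af = genotypes.alt_freq()
    exp_het_var = 2.0 * af * (1.0 - af)
    obs_het = ((calls == 1) & ~miss).sum(axis=1).astype(float)
    exp_het = np.where(~miss, exp_het_var[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - obs_het / exp_het
    return pd.Series(f, index=genotypes.subjects, name="inbreeding_f")


def mds_embed(distance: pd.DataFrame | np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigen-decomposes, and returns the
    first k coordinate columns (eigenvalue-scaled); non-positive eigenvalue
    directions are truncated (with fewer than k columns if the rank is low).
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return coords[:, :k]


def flag_outliers(coords: np.ndarray, n_mads: float = 6.0) -> np.ndarray:
    """Flag points beyond ``n_mads`` median absolute deviations on any axis."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    med = np.median(coords, axis=0)
    mad = np.median(np.abs(coords - med), axis=0)
    mad = np.where(mad == 0, np.finfo(float).tiny, mad)
    return (np.abs(coords - med) / mad > n_mads).any(axis=1)


@dataclass
class KinshipResult:
    """Samples to drop for kinship plus the offending pairs."""

    drop: list[str]
    pairs: pd.DataFrame


def kinship_exclusions(distance: pd.DataFrame, call_rates: pd.Series,
                       max_ibs_distance: float = 0.1) -> KinshipResult:
    """Greedy kinship screen on the IBS distance matrix.

    For each pair closer than ``max_ibs_distance``, the member with the lower
    call rate is dropped (ties: the later subject id).
    """
    drop: list[str] = []
    rows = []
    ids = list(distance.index)
    d = distance.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isnan(d[i, j]) or d[i, j] >= max_ibs_distance:
                continue
            a, b = ids[i], ids[j]
            if a in drop or b in drop:
                continue
            victim = a if (call_rates[a], b) < (call_rates[b], a) else b
            drop.append(victim)
            rows.append({"sample_a": a, "sample_b": b, "ibs_distance": d[i, j],
                         "dropped": victim})
    return KinshipResult(drop=drop, pairs=pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "ibs_distance", "dropped"]))
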
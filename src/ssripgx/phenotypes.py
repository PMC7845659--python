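"""Treatment-response phenotypes derived from HRSD-21 trajectories.

Four repeated phenotypes quantify antidepressant response:

* **remitted** — week-8 HRSD total; coded 1 if the total exceeds 7, 2
  (remitted) otherwise, so a total of exactly 7 counts as remission.
* **response** — percentage change of the HRSD total at week 4 relative to
  baseline; coded response when the reduction reaches 50% (pct_change
  <= -0.50), non-response otherwise.
* **pct_change** — the signed fractional change itself (negative =
  improvement), kept continuous.
* **stem-depressed** — HRSD item 1 ("depressed mood") at week 4; coded 1 when
  the item score is 3 or 4 (moderately severe / severe), 2 otherwise.

Codes follow the {1, 2} convention used in the source trial data; the
response code is stored as 1 = response, 2 = non-response.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import WEEKS, HRSDPanel

#: stem-depressed severity labels for item-1 scores 0..4
SEVERITY_LABELS = ("not depressed", "mild", "moderate", "moderately severe", "severe")


def hrsd_total(panel: HRSDPanel, subject: str, week: int) -> float:
    """Sum of the 21 item scores for one visit; nan if the visit is missing."""
    i = panel.subject_index(subject)
    wi = panel.week_index(week)
    if not panel.observed[i, wi]:
        return math.nan
    return float(panel.items[i, wi, :].sum())


def derive_remitted(week8_total: float) -> float:
    """Remission code from the week-8 total: 1 if > 7, else 2 (remitted)."""
    if week8_total is None or (isinstance(week8_total, float) and math.isnan(week8_total)):
        return math.nan
    return 1.0 if week8_total > 7 else 2.0


def derive_response(baseline_total: float, week4_total: float) -> tuple[float, float]:
    """Signed fractional HRSD change at week 4 and the response code.

    Returns ``(pct_change, code)`` with code 1 = response (reduction >= 50%,
    i.e. pct_change <= -0.50) and 2 = non-response.  A missing week-4 total
    propagates nan; a zero baseline is an error (undefined ratio).
    """
    if baseline_total is None or (isinstance(baseline_total, float) and math.isnan(baseline_total)):
        return math.nan, math.nan
    if baseline_total == 0:
        raise ValueError("baseline HRSD total of 0: percentage change undefined")
    if week4_total is None or (isinstance(week4_total, float) and math.isnan(week4_total)):
        return math.nan, math.nan
    pct = (week4_total - baseline_total) / baseline_total
    return pct, (1.0 if pct <= -0.50 else 2.0)


def derive_stem(item1_week4: float) -> float:
    """Stem-depressed code from week-4 item 1: 1 if score >= 3, else 2."""
    if item1_week4 is None or (isinstance(item1_week4, float) and math.isnan(item1_week4)):
        return math.nan
    if not 0 <= item1_week4 <= 4:
        raise ValueError(f"item-1 score must be in 0..4, got {item1_week4}")
    return 1.0 if item1_week4 >= 3 else 2.0


def build_phenotypes(panel: HRSDPanel, subjects: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with all four phenotypes plus covariates.

    Columns: subject_id, cohort, sex, age, baseline_total, week2_total,
    week4_total, week8_total, item1_week4, remitted_code, response_code,
    pct_change, stem_code.  Phenotypes are nan where the needed visit is
    missing; covariates come from ``subjects``.
    """
    if subjects["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in subject table")
    unknown = set(subjects["subject_id"]) - set(panel.subjects)
    if unknown:
        raise KeyError(f"subjects not in panel: {sorted(unknown)[:3]} ...")
    totals = panel.totals()
    item1 = panel.item_scores(1)
    idx = [panel.subject_index(s) for s in subjects["subject_id"]]
    rows = []
    for r, i in zip(subjects.itertuples(index=False), idx):
        base, w2, w4, w8 = (totals[i, WEEKS.index(w)] for w in WEEKS)
        pct, resp = derive_response(base, w4)
        rows.append({
            "subject_id": r.subject_id, "cohort": r.cohort, "sex": int(r.sex),
            "age": float(r.age),
            "baseline_total": base, "week2_total": w2, "week4_total": w4,
            "week8_total": w8, "item1_week4": item1[i, WEEKS.index(4)],
            "remitted_code": derive_remitted(w8),
            "response_code": resp, "pct_change": pct,
            "stem_code": derive_stem(item1[i, WEEKS.index(4)]),
        })
    return pd.DataFrame(rows)


def _rate(count: int, denom: int) -> dict:
    return {"count": int(count), "denom": int(denom),
            "percent": round(100.0 * count / denom, 2)}


def summarize_rates(table: pd.DataFrame) -> dict:
    """Response/remission rates and sex-difference tests for a phenotype table.

    Remission by week uses the total <= 7 rule at each post-baseline week over
    subjects observed at that week.  Each rate reports count, denominator and
    percent; sex differences use a two-sample t-test for continuous phenotypes
    and a Pearson chi-square (no continuity correction) for categorical ones.
    """
    if table.empty:
        raise ValueError("empty phenotype table")
    out: dict = {"n": len(table)}
    for week, col in ((2, "week2_total"), (4, "week4_total"), (8, "week8_total")):
        obs = table[col].dropna()
        if len(obs):
            out[f"remission_week{week}"] = _rate((obs <= 7).sum(), len(obs))
    resp = table["response_code"].dropna()
    if len(resp):
        out["response_week4"] = _rate((resp == 1).sum(), len(resp))
    w8 = table[["baseline_total", "week8_total"]].dropna()
    if len(w8):
        red8 = (w8["week8_total"] - w8["baseline_total"]) / w8["baseline_total"]
        out["response_week8"] = _rate((red8 <= -0.5).sum(), len(w8))
    stem = table["stem_code"].dropna()
    if len(stem):
        out["stem_mild_or_less"] = _rate((stem == 2).sum(), len(stem))
        out["stem_severe"] = _rate((stem == 1).sum(), len(stem))
        item1 = table["item1_week4"].dropna().astype(int)
        out["severity_crosstab"] = {SEVERITY_LABELS[k]: _rate((item1 == k).sum(), len(item1))
                                    for k in range(5)}
    out["sex_difference_p"] = {}
    male = table[table["sex"] == 1]
    female = table[table["sex"] == 2]
    if len(male) >= 2 and len(female) >= 2:
        for col in ("week8_total", "pct_change"):
            a, b = male[col].dropna(), female[col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                out["sex_difference_p"][col] = float(
                    stats.ttest_ind(a, b, equal_var=True).pvalue)
        for col in ("remitted_code", "response_code", "stem_code"):
            sub = table[["sex", col]].dropna()
            ct = pd.crosstab(sub["sex"], sub[col])
            if ct.shape == (2, 2) and (ct.to_numpy() > 0).all():
                out["sex_difference_p"][col] = float(
                    stats.chi2_contingency(ct, correction=False)[1])
    return out


def recode_from_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Re-derive the four phenotype codes from (possibly imputed) totals.

    Used after imputation so the coding rules stay single-sourced here.
    Continuous columns (item1 clipped to 0..4) are rounded before coding.
    """
    out = table.copy()
    w8 = out["week8_total"].round()
    out["remitted_code"] = np.where(w8.isna(), np.nan, np.where(w8 > 7, 1.0, 2.0))
    base = out["baseline_total"]
    w4 = out["week4_total"].round()
    pct = (w4 - base) / base
    out["pct_change"] = pct
    out["response_code"] = np.where(pct.isna(), np.nan, np.where(pct <= -0.5, 1.0, 2.0))
    item1 = out["item1_week4"].round().clip(0, 4)
    out["stem_code"] = np.where(item1.isna(), np.nan, np.where(item1 >= 3, 1.0, 2.0))
    return out
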
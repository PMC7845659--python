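"""Multiple imputation of incomplete phenotypes and Rubin-rules pooling.

Missing visit totals are filled by chained-equations normal linear
regression: each incomplete column is regressed on the remaining predictor
columns over its observed rows, missing entries are replaced by the
regression prediction plus a residual draw from N(0, sigma_hat^2) — the
random error guarantees that subjects with identical predictors receive
different imputed values and preserves the natural variability of the data —
and the sweep over incomplete columns is repeated for a fixed number of
cycles.  The whole procedure is repeated m times (default 30) to produce a
stack of completed tables; analyses run per completed table are then pooled
with Rubin's rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import phenotypes
from .synthio import read_table, write_table

#: columns imputed on the continuous scale; codes are re-derived afterwards
DEFAULT_IMPUTE_COLS = ("week2_total", "week4_total", "week8_total", "item1_week4")
DEFAULT_PREDICTORS = ("baseline_total", "age", "sex")


@dataclass
class ImputedStack:
    """m completed phenotype tables plus the settings that produced them."""

    tables: list[pd.DataFrame]
    m: int
    cycles: int
    seed: int
    predictors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m != len(self.tables):
            raise ValueError("m inconsistent with number of tables")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, tab in enumerate(self.tables):
            write_table(tab, directory / f"imputed_{k + 1:02d}.tsv")
        manifest = {"m": self.m, "cycles": self.cycles, "seed": self.seed,
                    "predictors": self.predictors}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ImputedStack":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        tables = [read_table(directory / f"imputed_{k + 1:02d}.tsv")
                  for k in range(manifest["m"])]
        return cls(tables=tables, **manifest)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-rules pooled estimate: T = W + (1 + 1/m) * B."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def _fit_impute_column(df: pd.DataFrame, col: str, predictors: list[str],
                       rng: np.random.Generator) -> None:
    """One chained-equations pass for one incomplete column (in place)."""
    miss = df[col].isna()
    if not miss.any():
        return
    x_cols = [c for c in predictors if c != col]
    X = df[x_cols].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), X])
    obs = ~miss
    y = df.loc[obs, col].to_numpy(float)
    Xo = X[obs.to_numpy()]
    beta, _, rank, _ = np.linalg.lstsq(Xo, y, rcond=None)
    resid = y - Xo @ beta
    dof = max(len(y) - rank, 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    pred = X[miss.to_numpy()] @ beta
    df.loc[miss, col] = pred + rng.normal(0.0, sigma, size=miss.sum())


def impute_stack(table: pd.DataFrame,
                 impute_cols: tuple[str, ...] = DEFAULT_IMPUTE_COLS,
                 predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
                 m: int = 30, cycles: int = 4, seed: int = 0,
                 recode: bool = True) -> ImputedStack:
    """Produce m completed copies of a phenotype table.

    Incomplete columns in ``impute_cols`` are imputed by chained normal
    regression on ``predictors`` plus the other (current-state) impute
    columns, sweeping ``cycles`` times.  Observed cells are never altered.
    With ``recode=True`` the {1,2} phenotype codes are re-derived from the
    completed totals via :func:`ssripgx.phenotypes.recode_from_totals`.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    impute_cols = [c for c in impute_cols if c in table.columns]
    fully_missing = [c for c in impute_cols if table[c].isna().all()]
    if fully_missing:
        raise ValueError(f"columns entirely missing, cannot impute: {fully_missing}")
    for c in predictors:
        if table[c].isna().any():
            raise ValueError(f"predictor column {c!r} has missing values")
    incomplete = [c for c in impute_cols if table[c].isna().any()]
    work_predictors = list(predictors) + list(impute_cols)
    tables = []
    for k in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17, k]))
        df = table.copy()
        # start from mean fill, then sweep column-by-column for `cycles` passes
        for c in incomplete:
            df[c] = df[c].fillna(table[c].mean())
        for _cycle in range(cycles):
            for c in incomplete:
                df.loc[table[c].isna(), c] = np.nan
                _fit_impute_column(df, c, work_predictors, rng)
        if recode:
            df = phenotypes.recode_from_totals(df)
        tables.append(df)
    return ImputedStack(tables=tables, m=m, cycles=cycles, seed=seed,
                        predictors=list(predictors))


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Pool m per-imputation (estimate, variance) pairs with Rubin's rules.

    Q = mean(estimates); W = mean(variances); B = sample variance of the
    estimates (0 when m = 1); T = W + (1 + 1/m) B.  Degrees of freedom follow
    the classical Rubin formula df = (m - 1) (1 + W / ((1 + 1/m) B))^2 and the
    p-value is two-sided from a t reference; when B = 0 the df are infinite
    and a normal reference is used.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D")
    m = len(q)
    if m == 0:
        raise ValueError("need at least one imputation")
    if (w < 0).any():
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    if b < 1e-14 * max(1.0, qbar * qbar):  # identical estimates up to rounding
        b = 0.0
    t = wbar + (1.0 + 1.0 / m) * b
    if b > 0 and m > 1:
        df = (m - 1) * (1.0 + wbar / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = np.inf
    if t > 0:
        stat = qbar / np.sqrt(t)
        p = float(2 * stats.t.sf(abs(stat), df)) if np.isfinite(df) \
            else float(2 * stats.norm.sf(abs(stat)))
    else:
        p = 1.0
    return PooledEstimate(estimate=qbar, within_var=wbar, between_var=b,
                          total_var=t, df=float(df), p_value=p, m=m)
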
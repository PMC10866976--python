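"""Clinical statistics: group t-tests and the Brain-PAD regression battery.

Three ordinary-least-squares model families relate Brain-PAD to clinical
outcomes in people with PD:

    motor     outcome ~ 1 + Brain-PAD + age + duration + education + sex
    non-motor outcome ~ ... + UPDRS-III
    mood      outcome ~ ... + UPDRS-III + MoCA

The battery fits each family's outcomes within each subgroup (all PD,
females, males, matched males), with listwise deletion per model and the
sex term dropped automatically in single-sex subgroups.  The overall
F-test p-values are adjusted for the false discovery rate
(Benjamini-Hochberg) within each family-by-subgroup table; coefficient
p-values are reported raw, mirroring how such batteries are tabulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthcohort import FAMILY_OUTCOMES, MODEL_FAMILIES

__all__ = [
    "FitTable",
    "fit_ols",
    "run_battery",
    "bh_fdr",
    "group_ttest",
]

log = logging.getLogger(__name__)


@dataclass
class FitTable:
    """One fitted model: per-predictor stats plus model-level summary."""

    outcome: str
    subgroup: str
    family: str
    coef: pd.DataFrame  # index: predictor; columns: b, t, p
    adj_r2: float
    fvalue: float
    f_pvalue: float
    n: int
    df_resid: int
    fdr_pvalue: float | None = None


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        kept: list[int] = []
        for j in range(arr.shape[1]):
            cand = arr[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def fit_ols(
    outcome: str,
    design_columns: list[str],
    data: pd.DataFrame,
    subgroup: str = "all",
    family: str = "custom",
) -> FitTable:
    """OLS of ``outcome`` on ``design_columns`` with listwise deletion.

    Classical homoskedastic standard errors, two-sided t p-values, and the
    overall F-test against the intercept-only model.
    """
    cols = [outcome] + design_columns
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    sub = data[cols].dropna()
    n = len(sub)
    n_coef = len(design_columns) + 1  # + intercept
    if n <= n_coef + 1:
        raise ValueError(
            f"insufficient n after listwise deletion for {outcome!r}: "
            f"n={n}, coefficients={n_coef}"
        )
    X = sm.add_constant(sub[design_columns].astype(float), has_constant="add")
    _check_rank(X)
    fit = sm.OLS(sub[outcome].astype(float), X).fit()
    coef = pd.DataFrame(
        {"b": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    return FitTable(
        outcome=outcome,
        subgroup=subgroup,
        family=family,
        coef=coef,
        adj_r2=float(fit.rsquared_adj),
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        n=n,
        df_resid=int(fit.df_resid),
    )


def _family_design(family: str, data: pd.DataFrame) -> list[str]:
    preds = [p for p in MODEL_FAMILIES[family] if p != "intercept"]
    # rename the generator's slot to the analysis column
    preds = ["brain_pad" if p == "brain_pad" else p for p in preds]
    # drop sex if constant within the subgroup (single-sex analyses)
    if "sex" in preds and data["sex"].nunique() <= 1:
        preds.remove("sex")
    return preds


def run_battery(
    data: pd.DataFrame,
    subgroups: dict[str, pd.Series],
    families: tuple[str, ...] = ("motor", "nonmotor", "mood"),
    alpha: float = 0.05,
) -> list[FitTable]:
    """Fit every (family x outcome x subgroup) model with FDR per table.

    ``data`` needs a ``brain_pad`` column, the clinical outcome columns and
    the demographic predictors; ``subgroups`` maps subgroup names to
    boolean masks over ``data`` rows.  A ``motor`` family outcome serving
    as a predictor elsewhere (UPDRS-III, MoCA) is taken from the data, not
    from fitted values.  Models whose outcome is entirely missing in a
    subgroup are skipped with a logged reason.
    """
    if "brain_pad" not in data.columns:
        raise KeyError("data must contain a 'brain_pad' column")
    results: list[FitTable] = []
    for name, mask in subgroups.items():
        sub = data.loc[mask].copy()
        if len(sub) == 0:
            raise ValueError(f"subgroup {name!r} is empty")
        if "sex" not in sub.columns:
            raise KeyError("data must contain a 'sex' column")
        sub = sub.assign(sex=(sub["sex"] == "M").astype(float))
        for fam in families:
            fam_tables: list[FitTable] = []
            preds = _family_design(fam, sub)
            for outcome in FAMILY_OUTCOMES[fam]:
                design = [p for p in preds if p != outcome]
                if outcome not in sub.columns or sub[outcome].notna().sum() == 0:
                    log.info("skipping %s/%s/%s: outcome entirely missing", name, fam, outcome)
                    continue
                try:
                    tab = fit_ols(outcome, design, sub, subgroup=name, family=fam)
                except ValueError as exc:
                    log.info("skipping %s/%s/%s: %s", name, fam, outcome, exc)
                    continue
                fam_tables.append(tab)
            if fam_tables:
                adj = bh_fdr(np.array([t.f_pvalue for t in fam_tables]))
                for t, q in zip(fam_tables, adj):
                    t.fdr_pvalue = float(q)
            results.extend(fam_tables)
    return results


def battery_frame(tables: list[FitTable]) -> pd.DataFrame:
    """Flatten battery results to one row per model, Brain-PAD stats inline."""
    rows = []
    for t in tables:
        row = {
            "subgroup": t.subgroup,
            "family": t.family,
            "outcome": t.outcome,
            "n": t.n,
            "df_resid": t.df_resid,
            "adj_r2": t.adj_r2,
            "F": t.fvalue,
            "F_p": t.f_pvalue,
            "F_p_fdr": t.fdr_pvalue,
        }
        if "brain_pad" in t.coef.index:
            row["brainpad_b"] = t.coef.loc["brain_pad", "b"]
            row["brainpad_t"] = t.coef.loc["brain_pad", "t"]
            row["brainpad_p"] = t.coef.loc["brain_pad", "p"]
        rows.append(row)
    return pd.DataFrame(rows)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def group_ttest(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided independent Student t-test with pooled variance.

    Returns (t, df, p) with df = n_a + n_b - 2.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)
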
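"""Propensity-score matching and covariate-balance diagnostics.

Used to select, from the larger male PD group, a subgroup matched to the
female PD group on disease-severity covariates, so that sex contrasts of
Brain-PAD are not confounded by severity.  Scores are fitted probabilities
from a logistic regression of group membership on the covariates; matching
is greedy nearest-neighbour without replacement on the linear predictor
(logit of the score), with the minority group processed in a seeded random
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._rng import rng_stream

__all__ = [
    "MatchSpec",
    "MatchResult",
    "propensity_scores",
    "match_groups",
    "balance_table",
    "match_minority_majority",
    "DEFAULT_MATCH_COVARIATES",
]

DEFAULT_MATCH_COVARIATES = (
    "age",
    "education",
    "diagnosis_age",
    "UPDRS3_total",
    "UPDRS3_rigidity",
    "UPDRS3_tremor",
    "MoCA",
    "REM",
    "ESS",
)


@dataclass
class MatchSpec:
    covariates: tuple[str, ...] = DEFAULT_MATCH_COVARIATES
    ratio: int = 1
    caliper: float | None = None  # max |logit difference|; None = no caliper
    seed: int = 0

    def validate(self) -> None:
        if len(self.covariates) == 0:
            raise ValueError("covariates must be non-empty")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass
class MatchResult:
    scores: pd.Series  # propensity score per subject (index = subject_id)
    pairs: list[tuple[str, str]]  # (minority_id, majority_id)
    unmatched_minority: list[str] = field(default_factory=list)

    @property
    def matched_majority(self) -> list[str]:
        return [m for _, m in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minority_id": [a for a, _ in self.pairs],
                "majority_id": [b for _, b in self.pairs],
                "score_minority": [self.scores[a] for a, _ in self.pairs],
                "score_majority": [self.scores[b] for _, b in self.pairs],
            }
        )


def propensity_scores(covariates: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Fitted probability of majority-group membership per subject.

    ``labels`` is boolean/0-1 with 1 = majority group.  Constant covariate
    columns are dropped with a warning; perfect separation raises with
    advice rather than returning degenerate scores.
    """
    labels = pd.Series(labels).astype(float)
    if set(np.unique(labels)) != {0.0, 1.0}:
        raise ValueError("labels must contain both groups (0 and 1)")
    X = covariates.astype(float).copy()
    if X.isna().any().any():
        raise ValueError(
            "covariates contain missing values; apply listwise deletion first"
        )
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant covariate column(s): {const}", stacklevel=2)
        X = X.drop(columns=const)
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter(
                "error", category=sm.tools.sm_exceptions.PerfectSeparationWarning
            )
            fit = sm.Logit(labels.to_numpy(), design.to_numpy()).fit(disp=0)
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
        np.linalg.LinAlgError,
        RuntimeWarning,
    ) as exc:
        raise ValueError(
            "logistic model did not converge (possible perfect separation); "
            "review the covariate list or use a caliper"
        ) from exc
    probs = fit.predict(design.to_numpy())
    return pd.Series(probs, index=covariates.index, name="propensity")


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def match_groups(scores: pd.Series, labels: pd.Series, spec: MatchSpec) -> MatchResult:
    """Greedy nearest-neighbour matching without replacement.

    Minority subjects (label 0) are processed in a seeded random order;
    each takes the ``ratio`` closest unused majority subjects by |logit
    difference|, subject to the optional caliper.  Without a caliper every
    minority subject is matched exactly ``ratio`` times (majority
    permitting).
    """
    spec.validate()
    labels = pd.Series(labels).astype(bool)
    minority = scores.index[~labels]
    majority = scores.index[labels]
    if len(minority) > len(majority):
        raise ValueError(
            f"minority group ({len(minority)}) larger than majority ({len(majority)})"
        )
    lp = pd.Series(_logit(scores.to_numpy(float)), index=scores.index)
    rng = rng_stream(spec.seed, "matching", "order")
    # sort ids before the seeded shuffle so the result is invariant to the
    # row order of the input
    minority = pd.Index(sorted(minority))
    order = rng.permutation(len(minority))
    # majority candidates sorted by id for order-invariance given the seed
    avail_ids = sorted(majority)
    avail_lp = np.array([lp[m] for m in avail_ids])
    used = np.zeros(len(avail_ids), dtype=bool)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for i in order:
        mid = minority[i]
        got = 0
        for _ in range(spec.ratio):
            dist = np.abs(avail_lp - lp[mid])
            dist[used] = np.inf
            j = int(np.argmin(dist))
            if not np.isfinite(dist[j]):
                break
            if spec.caliper is not None and dist[j] > spec.caliper:
                break
            used[j] = True
            pairs.append((mid, avail_ids[j]))
            got += 1
        if got < spec.ratio:
            unmatched.append(mid)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} minority subject(s) not fully matched "
            "(caliper or majority exhaustion)",
            stacklevel=2,
        )
    return MatchResult(scores=scores, pairs=pairs, unmatched_minority=unmatched)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def balance_table(
    pheno: pd.DataFrame,
    minority_ids: list[str],
    majority_ids: list[str],
    matched: MatchResult,
    variables: list[str],
) -> pd.DataFrame:
    """Pre- and post-match balance diagnostics per variable.

    Reports group means/SDs, the pooled-variance two-sided t-test, and the
    standardised mean difference, before (minority vs all majority) and
    after (minority vs matched majority) matching.
    """
    df = pheno.set_index("subject_id")
    matched_ids = matched.matched_majority
    rows = []
    for var in variables:
        a = df.loc[minority_ids, var].dropna().to_numpy(float)
        b_pre = df.loc[majority_ids, var].dropna().to_numpy(float)
        b_post = df.loc[matched_ids, var].dropna().to_numpy(float)
        rec: dict = {"variable": var}
        for tag, b in (("pre", b_pre), ("post", b_post)):
            if len(a) >= 2 and len(b) >= 2 and (a.var() + b.var()) > 0:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            else:
                t, p = float("nan"), float("nan")
            rec.update(
                {
                    f"mean_minority": a.mean() if len(a) else float("nan"),
                    f"sd_minority": a.std(ddof=1) if len(a) > 1 else float("nan"),
                    f"mean_majority_{tag}": b.mean() if len(b) else float("nan"),
                    f"sd_majority_{tag}": b.std(ddof=1) if len(b) > 1 else float("nan"),
                    f"t_{tag}": float(t),
                    f"p_{tag}": float(p),
                    f"smd_{tag}": _smd(a, b) if len(a) > 1 and len(b) > 1 else float("nan"),
                }
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def match_minority_majority(
    pheno: pd.DataFrame,
    minority_mask: pd.Series,
    majority_mask: pd.Series,
    spec: MatchSpec | None = None,
) -> tuple[MatchResult, pd.DataFrame]:
    """End-to-end matching of two subgroups of a phenotype table.

    Subjects with missing matching covariates are excluded (listwise
    deletion) before the logistic fit.  Returns the match result and the
    balance table over the matching covariates.
    """
    spec = spec or MatchSpec()
    spec.validate()
    missing_cols = [c for c in spec.covariates if c not in pheno.columns]
    if missing_cols:
        raise KeyError(f"matching covariates missing from table: {missing_cols}")
    sub = pheno.loc[minority_mask | majority_mask].set_index("subject_id")
    sub = sub.dropna(subset=list(spec.covariates))
    labels = pd.Series(
        majority_mask.set_axis(pheno["subject_id"]).loc[sub.index], index=sub.index
    )
    if labels.all() or not labels.any():
        raise ValueError("both groups must be non-empty after listwise deletion")
    scores = propensity_scores(sub[list(spec.covariates)], labels)
    result = match_groups(scores, labels, spec)
    minority_ids = list(labels.index[~labels])
    majority_ids = list(labels.index[labels])
    bal = balance_table(pheno, minority_ids, majority_ids, result, list(spec.covariates))
    return result, bal
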
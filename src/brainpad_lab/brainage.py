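"""Brain-age estimation: feature assembly, linear SVR, bias adjustment.

The predictor of chronological age is a support vector regression with a
linear kernel on the concatenated GM/WM/CSF in-mask voxel intensities plus
seven scalar covariates (total GM/WM/CSF volumes, TIV, sex, scanner
vendor, field strength).  Raw brain-age predictions suffer regression
dilution — young subjects are over-, old subjects under-estimated — so a
post-hoc bias adjustment is fit on the training set: the prediction offset
(predicted minus actual age) is regressed on actual age,

    offset = alpha * age + beta,

and the fitted trend is subtracted from every later prediction.  Brain-PAD
is the bias-adjusted predicted age minus actual age; positive values mean
an "older-looking" brain.  By ordinary-least-squares orthogonality the
training-set Brain-PAD has exactly zero mean and zero correlation with
age; the coefficients are frozen and reused for hold-out and patient sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from ._rng import rng_stream
from .morphometry import VoxelGrid, tissue_volumes

__all__ = [
    "FeatureMatrix",
    "AgeModel",
    "FitMetrics",
    "assemble_features",
    "split_train_holdout",
    "train_age_model",
    "crossval_metrics",
    "fit_bias_adjustment",
    "apply_bias_adjustment",
    "brainpad",
    "evaluate",
]

TISSUE_ORDER = ("GM", "WM", "CSF")


@dataclass
class FeatureMatrix:
    """Subjects-by-features design for the age model.

    Column order: GM voxels, WM voxels, CSF voxels, total GM/WM/CSF volume,
    TIV, sex (F=0, M=1), vendor indicator(s), field strength.
    """

    X: np.ndarray
    columns: list[str]
    subject_ids: list[str]
    n_voxels: int
    vendor_levels: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("feature matrix shape inconsistent with labels")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing entries")

    def subset(self, ids: list[str]) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in feature matrix: {missing[:5]}")
        rows = [index[s] for s in ids]
        return FeatureMatrix(
            X=self.X[rows],
            columns=self.columns,
            subject_ids=list(ids),
            n_voxels=self.n_voxels,
            vendor_levels=self.vendor_levels,
        )


def _vendor_columns(levels: list[str]) -> list[str]:
    # one-hot with the first level as reference; a single level keeps its
    # (constant) indicator so the schema always carries a vendor column
    if len(levels) == 1:
        return [f"vendor_{levels[0]}"]
    return [f"vendor_{v}" for v in levels[1:]]


def assemble_features(
    maps: dict[str, dict[str, VoxelGrid]],
    pheno: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> FeatureMatrix:
    """Build the feature matrix for the subjects in ``pheno`` (row order).

    Tissue totals and TIV are computed from the maps themselves; vendor is
    encoded as one-hot indicators against the first (sorted) level.
    """
    if len(pheno) == 0:
        raise ValueError("cannot assemble features for zero subjects")
    ids = pheno["subject_id"].tolist()
    for sid in ids:
        if sid not in maps:
            raise KeyError(f"subject {sid!r} has no tissue maps")
        have = set(maps[sid])
        if have != set(TISSUE_ORDER):
            raise KeyError(
                f"subject {sid!r} missing tissue maps: {sorted(set(TISSUE_ORDER) - have)}"
            )
    first = maps[ids[0]]["GM"]
    ref_mask = first.mask if mask is None else np.asarray(mask, dtype=bool)
    n_vox = int(ref_mask.sum())

    vendor_levels = sorted(pheno["vendor"].astype(str).unique())
    vcols = _vendor_columns(vendor_levels)
    columns = (
        [f"{t}_vox{i}" for t in TISSUE_ORDER for i in range(n_vox)]
        + ["gm_total", "wm_total", "csf_total", "tiv", "sex"]
        + vcols
        + ["field_strength"]
    )

    rows = np.empty((len(ids), len(columns)))
    for r, (sid, prow) in enumerate(zip(ids, pheno.itertuples(index=False))):
        sub = maps[sid]
        for g in sub.values():
            if g.mask.shape != ref_mask.shape or not np.array_equal(g.mask, ref_mask):
                raise ValueError(f"subject {sid!r} has an inconsistent mask")
        vox = np.concatenate([sub[t].values[ref_mask] for t in TISSUE_ORDER])
        vols = tissue_volumes(sub["GM"], sub["WM"], sub["CSF"])
        sex = 1.0 if prow.sex == "M" else 0.0
        vend = np.zeros(len(vcols))
        vname = f"vendor_{prow.vendor}"
        if vname in vcols:
            vend[vcols.index(vname)] = 1.0
        scalars = np.concatenate(
            [
                [vols.gm_ml, vols.wm_ml, vols.csf_ml, vols.tiv_ml, sex],
                vend,
                [float(prow.field_strength)],
            ]
        )
        rows[r] = np.concatenate([vox, scalars])
    return FeatureMatrix(
        X=rows,
        columns=columns,
        subject_ids=ids,
        n_voxels=n_vox,
        vendor_levels=vendor_levels,
    )


def split_train_holdout(
    pheno: pd.DataFrame, fraction: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Randomly split healthy-control subjects into train and hold-out ids.

    The split is disjoint and exhaustive over HC rows; the training size is
    ``round(n_hc * fraction)`` (1054 controls at 0.9 give 949/105).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    hc = pheno.loc[pheno["group"].astype(str).str.startswith("HC"), "subject_id"]
    ids = hc.tolist()
    if not ids:
        raise ValueError("no healthy-control subjects to split")
    rng = rng_stream(seed, "brainage", "split")
    order = rng.permutation(len(ids))
    n_train = int(round(len(ids) * fraction))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in order[:n_train])
    holdout = sorted(ids[i] for i in order[n_train:])
    return train, holdout


@dataclass
class AgeModel:
    """Trained linear SVR with z-scoring parameters and bias coefficients."""

    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    columns: list[str]
    bias_alpha: float = 0.0
    bias_beta: float = 0.0
    meta: dict = field(default_factory=dict)

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """Raw (not bias-adjusted) predicted age in years."""
        if features.columns != self.columns:
            raise ValueError("feature schema does not match the trained model")
        Z = (features.X - self.feature_means) / self.feature_scales
        return Z @ self.weights + self.intercept

    def predict_corrected(self, features: FeatureMatrix, actual: np.ndarray) -> np.ndarray:
        """Bias-adjusted predicted age using the stored (frozen) alpha/beta."""
        raw = self.predict(features)
        return apply_bias_adjustment(raw, np.asarray(actual, float), self.bias_alpha, self.bias_beta)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "columns": self.columns,
            "intercept": self.intercept,
            "bias_alpha": self.bias_alpha,
            "bias_beta": self.bias_beta,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        np.savez(
            path.with_suffix(".npz"),
            weights=self.weights,
            feature_means=self.feature_means,
            feature_scales=self.feature_scales,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AgeModel":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        return cls(
            weights=arrays["weights"],
            intercept=float(header["intercept"]),
            feature_means=arrays["feature_means"],
            feature_scales=arrays["feature_scales"],
            columns=list(header["columns"]),
            bias_alpha=float(header["bias_alpha"]),
            bias_beta=float(header["bias_beta"]),
            meta=dict(header["meta"]),
        )


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)  # constant columns pass through
    return means, scales


def train_age_model(
    features: FeatureMatrix,
    ages: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    seed: int = 0,
) -> AgeModel:
    """Fit the linear-kernel SVR age model on z-scored features.

    Standardisation statistics come from the training data only and are
    stored with the model.  The epsilon-insensitive loss and C follow the
    common defaults; the fit itself is deterministic.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 10:
        raise ValueError(f"need at least 10 training subjects, got {len(ages)}")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    if np.ptp(ages) == 0:
        raise ValueError("constant-age training set: degenerate target")
    means, scales = _standardize_params(features.X)
    Z = (features.X - means) / scales
    svr = SVR(kernel="linear", C=C, epsilon=epsilon)
    svr.fit(Z, ages)
    weights = np.asarray(svr.coef_).ravel()
    return AgeModel(
        weights=weights,
        intercept=float(svr.intercept_[0]),
        feature_means=means,
        feature_scales=scales,
        columns=list(features.columns),
        meta={"n": len(ages), "C": C, "epsilon": epsilon, "seed": seed},
    )


def crossval_predictions(
    features: FeatureMatrix,
    ages: np.ndarray,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> np.ndarray:
    """Out-of-fold predicted age for every subject (k-fold CV)."""
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects n={n}")
    fold_seed = int(rng_stream(seed, "brainage", "cv").integers(2**31))
    kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
    preds = np.full(n, np.nan)
    for train_idx, test_idx in kf.split(features.X):
        means, scales = _standardize_params(features.X[train_idx])
        Z_train = (features.X[train_idx] - means) / scales
        Z_test = (features.X[test_idx] - means) / scales
        svr = SVR(kernel="linear", C=C, epsilon=epsilon)
        svr.fit(Z_train, ages[train_idx])
        preds[test_idx] = svr.predict(Z_test)
    assert not np.isnan(preds).any()
    return preds


def crossval_metrics(
    features: FeatureMatrix,
    ages: np.ndarray,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> "FitMetrics":
    """Pooled out-of-fold metrics of the k-fold cross-validated model."""
    preds = crossval_predictions(features, ages, k=k, seed=seed, C=C, epsilon=epsilon)
    return evaluate(preds, np.asarray(ages, float))


def fit_bias_adjustment(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """OLS fit of the prediction offset on actual age.

    Returns (alpha, beta) such that predicted - actual ~= alpha*actual + beta.
    """
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if len(actual) < 3:
        raise ValueError("need at least 3 subjects to fit bias adjustment")
    if np.var(actual) == 0:
        raise ValueError("zero age variance: bias adjustment undefined")
    offset = predicted - actual
    alpha, beta = np.polyfit(actual, offset, deg=1)
    return float(alpha), float(beta)


def apply_bias_adjustment(
    predicted: np.ndarray, actual: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Subtract the fitted age-dependent offset from raw predictions."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same shape")
    return predicted - (alpha * actual + beta)


def brainpad(corrected_predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Brain-predicted age difference: corrected prediction minus actual age."""
    corrected_predicted = np.asarray(corrected_predicted, float)
    actual = np.asarray(actual, float)
    if corrected_predicted.shape != actual.shape:
        raise ValueError("inputs must have the same shape")
    return corrected_predicted - actual


@dataclass(frozen=True)
class FitMetrics:
    mae: float
    rmse: float
    r2: float
    mean_pad: float
    pad_ci95: tuple[float, float]
    n: int


def evaluate(predicted: np.ndarray, actual: np.ndarray) -> FitMetrics:
    """MAE, RMSE, R^2 and mean Brain-PAD with a normal-approximation 95% CI."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    n = len(actual)
    if n < 2:
        raise ValueError("need at least 2 subjects to evaluate (CI undefined)")
    err = predicted - actual
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((actual - actual.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    mean_pad = float(err.mean())
    se = float(err.std(ddof=1) / np.sqrt(n))
    ci = (mean_pad - 1.96 * se, mean_pad + 1.96 * se)
    return FitMetrics(mae=mae, rmse=rmse, r2=r2, mean_pad=mean_pad, pad_ci95=ci, n=n)
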
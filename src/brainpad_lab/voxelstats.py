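"""Mass-univariate voxelwise statistics with permutation FWE control.

Regresses tissue density at every in-mask voxel on Brain-PAD with age,
sex and TIV as nuisance covariates; a negative t means tissue volume
decreases as the brain looks older.  Family-wise error over voxels is
controlled by max-statistic permutation under the Freedman-Lane scheme:
the outcome is reduced to its residuals under the nuisance-only model,
those residuals are permuted, the nuisance fit is added back, and the
maximum |t| over voxels of each permuted dataset forms the null
distribution against which each observed voxel's |t| is ranked.  Peaks
are then summarised as connected clusters (26-connectivity) with a
minimum extent, peak world coordinates and peak-level corrected p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._rng import rng_stream
from .morphometry import VoxelGrid

__all__ = [
    "StatMap",
    "ClusterRecord",
    "stack_maps",
    "massuni_fit",
    "fwe_correct",
    "extract_clusters",
    "slope_contrast",
    "roi_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class StatMap:
    """Per-voxel t-statistics for one contrast (in-mask vector)."""

    t: np.ndarray  # (V,) t-values; NaN where undefined
    df: int
    contrast: str
    mask: np.ndarray  # 3-D boolean analysis mask
    affine: np.ndarray

    def volume(self) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.t
        return vol


@dataclass(frozen=True)
class ClusterRecord:
    cluster_id: int
    n_voxels: int
    size_ml: float
    peak_xyz_mm: tuple[float, float, float]
    peak_t: float
    peak_fwe_p: float
    hemisphere: str
    sign: str  # "positive" | "negative"


def stack_maps(
    maps: dict[str, dict[str, VoxelGrid]],
    subject_ids: list[str],
    tissue: str = "GM",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack one tissue's in-mask voxels into an (n_subjects, V) matrix.

    Returns (stack, mask, affine); all subjects must share the mask.
    """
    ref = maps[subject_ids[0]][tissue]
    mask = ref.mask
    rows = np.empty((len(subject_ids), int(mask.sum())))
    for i, sid in enumerate(subject_ids):
        g = maps[sid][tissue]
        if not np.array_equal(g.mask, mask):
            raise ValueError(f"subject {sid!r} mask differs from the reference")
        rows[i] = g.values[mask]
    return rows, mask, ref.affine


def _t_for_contrast(
    Y: np.ndarray, X: np.ndarray, c_idx: int
) -> tuple[np.ndarray, int]:
    """Vectorised per-voxel OLS t for one design column. Y is (n, V)."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"non-positive residual df: n={n}, p={p}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # (p, V)
    resid = Y - X @ beta
    sse = np.einsum("ij,ij->j", resid, resid)
    sigma2 = sse / df
    denom = np.sqrt(sigma2 * xtx_inv[c_idx, c_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[c_idx] / denom
    # constant voxels have variance at rounding level, not exactly zero
    colvar = Y.var(axis=0)
    undefined = (denom == 0) | (colvar <= 1e-12 * (1.0 + Y.mean(axis=0) ** 2))
    t[undefined] = np.nan
    return t, df


def _design_matrix(design: pd.DataFrame, contrast: str) -> tuple[np.ndarray, int, list[str]]:
    cols = list(design.columns)
    if contrast not in cols:
        raise KeyError(f"contrast column {contrast!r} not in design: {cols}")
    if "intercept" not in cols:
        design = design.copy()
        design.insert(0, "intercept", 1.0)
        cols = list(design.columns)
    X = design.to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank-deficient (columns: {cols})")
    return X, cols.index(contrast), cols


def massuni_fit(
    stack: np.ndarray,
    design: pd.DataFrame,
    contrast: str,
    mask: np.ndarray,
    affine: np.ndarray,
) -> StatMap:
    """Per-voxel OLS t-statistic for one design column.

    Voxels with zero residual variance get NaN t (count logged).
    """
    if stack.shape[0] < 10:
        raise ValueError("need at least 10 subjects for voxelwise regression")
    X, c_idx, _ = _design_matrix(design, contrast)
    if len(design) != stack.shape[0]:
        raise ValueError("design rows do not match map stack rows")
    t, df = _t_for_contrast(stack, X, c_idx)
    n_bad = int(np.isnan(t).sum())
    if n_bad:
        log.info("%d voxel(s) with undefined t (zero residual variance)", n_bad)
    return StatMap(t=t, df=df, contrast=contrast, mask=mask, affine=affine)


def fwe_correct(
    stack: np.ndarray,
    design: pd.DataFrame,
    contrast: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-level FWE-corrected p per voxel by max-|t| permutation.

    Freedman-Lane: residuals of the nuisance-only model are permuted and
    recombined with the nuisance fit before recomputing the contrast t.
    Corrected p for voxel v is ``(1 + #{max|t*| >= |t_v|}) / (n_perm + 1)``.
    Returns (corrected_p, observed_t).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    X, c_idx, cols = _design_matrix(design, contrast)
    t_obs, _ = _t_for_contrast(stack, X, c_idx)
    Z = np.delete(X, c_idx, axis=1)  # nuisance-only design
    hat = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    fitted = hat @ stack
    resid = stack - fitted
    rng = rng_stream(seed, "voxelstats", "fwe")
    n = stack.shape[0]
    abs_obs = np.abs(t_obs)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted + resid[perm]
        t_star, _ = _t_for_contrast(Y_star, X, c_idx)
        max_t = np.nanmax(np.abs(t_star))
        exceed += (max_t >= abs_obs).astype(float)
    p_corr = (1.0 + exceed) / (n_perm + 1.0)
    p_corr[np.isnan(abs_obs)] = np.nan
    return p_corr, t_obs


def extract_clusters(
    stat: StatMap,
    corrected_p: np.ndarray,
    alpha: float = 0.05,
    min_extent_voxels: int = 100,
) -> list[ClusterRecord]:
    """Connected suprathreshold clusters with peak-level statistics.

    Voxels with corrected p < alpha are grouped by 26-connectivity,
    separately for positive and negative t; components smaller than the
    extent threshold are dropped.  Sizes are reported in voxels and ml;
    the peak is the in-cluster voxel with max |t|, with its world (mm)
    coordinate and hemisphere from the sign of world x.
    """
    if alpha <= 0 or min_extent_voxels <= 0:
        raise ValueError("alpha and min_extent_voxels must be positive")
    voxel_ml = float(abs(np.linalg.det(stat.affine[:3, :3]))) / 1000.0
    t_vol = stat.volume()
    p_vol = np.full(stat.mask.shape, np.nan)
    p_vol[stat.mask] = corrected_p
    passing = (p_vol < alpha) & ~np.isnan(t_vol)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    records: list[ClusterRecord] = []
    cid = 0
    for sign, signed in (("positive", t_vol > 0), ("negative", t_vol < 0)):
        labeled, n_comp = ndimage.label(passing & signed, structure=structure)
        for comp in range(1, n_comp + 1):
            where = np.argwhere(labeled == comp)
            if len(where) < min_extent_voxels:
                continue
            ts = t_vol[tuple(where.T)]
            peak_local = where[np.argmax(np.abs(ts))]
            peak_t = float(t_vol[tuple(peak_local)])
            peak_p = float(p_vol[tuple(peak_local)])
            xyz = stat.affine @ np.append(peak_local.astype(float), 1.0)
            cid += 1
            records.append(
                ClusterRecord(
                    cluster_id=cid,
                    n_voxels=len(where),
                    size_ml=len(where) * voxel_ml,
                    peak_xyz_mm=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    peak_t=peak_t,
                    peak_fwe_p=peak_p,
                    hemisphere="L" if xyz[0] < 0 else "R",
                    sign=sign,
                )
            )
    records.sort(key=lambda r: -r.n_voxels)
    return records


def cluster_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_voxels": r.n_voxels,
                "size_ml": r.size_ml,
                "peak_x_mm": r.peak_xyz_mm[0],
                "peak_y_mm": r.peak_xyz_mm[1],
                "peak_z_mm": r.peak_xyz_mm[2],
                "peak_t": r.peak_t,
                "peak_fwe_p": r.peak_fwe_p,
                "hemisphere": r.hemisphere,
                "sign": r.sign,
            }
            for r in records
        ]
    )


def slope_contrast(
    stack: np.ndarray,
    design: pd.DataFrame,
    mask: np.ndarray,
    affine: np.ndarray,
    group_col: str = "group",
    pad_col: str = "brain_pad",
) -> StatMap:
    """t-map of the group difference in Brain-PAD slopes (interaction).

    ``design[group_col]`` must be 0/1; the interaction column
    ``group x Brain-PAD`` is added and tested.  Swapping group labels
    flips the map's sign.
    """
    d = design.copy()
    g = d[group_col].to_numpy(float)
    sizes = [int((g == v).sum()) for v in (0.0, 1.0)]
    if min(sizes) < 10:
        raise ValueError(f"both groups need >= 10 subjects, got {sizes}")
    inter = f"{group_col}_x_{pad_col}"
    d[inter] = g * d[pad_col].to_numpy(float)
    return massuni_fit(stack, d, inter, mask, affine)


def roi_correlation(
    cluster_mask: np.ndarray,
    maps: dict[str, dict[str, VoxelGrid]],
    pad: pd.Series,
    groups: pd.Series,
    tissue: str = "GM",
) -> dict[str, tuple[float, float]]:
    """Pearson r between mean in-cluster tissue density and Brain-PAD, per group."""
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    out: dict[str, tuple[float, float]] = {}
    for grp in pd.unique(groups):
        ids = list(pad.index[groups == grp])
        if len(ids) < 3:
            raise ValueError(f"group {grp!r} has fewer than 3 subjects")
        means = np.array([maps[s][tissue].values[cluster_mask].mean() for s in ids])
        pads = pad.loc[ids].to_numpy(float)
        if np.ptp(pads) == 0 or np.ptp(means) == 0:
            raise ValueError(f"group {grp!r} has constant values: correlation undefined")
        r, p = stats.pearsonr(means, pads)
        out[str(grp)] = (float(r), float(p))
    return out
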
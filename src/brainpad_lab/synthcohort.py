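"""Synthetic cohorts for testing the brain-age pipeline end to end.

Real brain-age studies of Parkinson's disease rest on access-gated MRI
archives, so this module generates stand-in cohorts whose tissue maps and
clinical scores embed, with known ground truth, exactly the statistical
structure the downstream analysis assumes:

* smooth spatial GM/WM/CSF templates with a linear age-related GM/WM
  decline absorbed by CSF (total intracranial volume is age-invariant);
* additive sex and scanner offsets and spatially smooth scanner noise;
* a disease-specific "accelerated aging" gap: people with PD (PwP) carry a
  latent ``true_gap`` (years) drawn per sex, and their maps look like those
  of a healthy brain aged ``age + true_gap`` — which makes the injected
  Brain-PAD a well-defined recovery target for the estimator;
* clinical outcome scores generated from the same linear model families
  the analysis later fits, with ``true_gap`` standing in the Brain-PAD
  slot and recorded generating coefficients.

All draws come from named sub-streams of the spec seed, so regeneration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import rng_stream
from .morphometry import FWHM_TO_SIGMA, VoxelGrid

__all__ = [
    "CohortSpec",
    "OutcomeEffect",
    "ClinicalEffectSpec",
    "ellipsoid_mask",
    "fullscale_mask",
    "tissue_templates",
    "generate_phenotypes",
    "generate_tissue_maps",
    "generate_clinical_scores",
    "default_effect_spec",
    "MODEL_FAMILIES",
    "FAMILY_OUTCOMES",
]

GROUPS = ("HC_train", "HC_holdout", "PD")

#: predictor lists of the three clinical regression-model families.
#: ``brain_pad`` is the slot the generator fills with the latent true_gap
#: and the analysis fills with the estimated Brain-PAD.
MODEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "motor": ("intercept", "brain_pad", "age", "disease_duration", "education", "sex"),
    "nonmotor": (
        "intercept",
        "brain_pad",
        "age",
        "disease_duration",
        "education",
        "sex",
        "UPDRS3_total",
    ),
    "mood": (
        "intercept",
        "brain_pad",
        "age",
        "disease_duration",
        "education",
        "sex",
        "UPDRS3_total",
        "MoCA",
    ),
}

FAMILY_OUTCOMES: dict[str, tuple[str, ...]] = {
    "motor": ("UPDRS3_total", "UPDRS3_rigidity", "UPDRS3_tremor"),
    "nonmotor": (
        "MoCA",
        "ESS",
        "LNS",
        "REM",
        "BJLO",
        "HVLT_recall",
        "HVLT_recognition",
        "olfactory",
        "SDM",
    ),
    "mood": ("anxiety", "GDS"),
}

CLINICAL_COLUMNS = tuple(c for outs in FAMILY_OUTCOMES.values() for c in outs)


@dataclass(frozen=True)
class ScannerLevel:
    vendor: str
    field_strength: float  # tesla
    offset: float  # additive GM probability offset
    noise_scale: float  # multiplies the cohort noise_sd


@dataclass
class CohortSpec:
    """Generative parameters of one synthetic cohort.

    Group sizes and female fractions default to the composition of the
    study cohorts this bench emulates (~1054 healthy controls, 53% female;
    373 PwP, 34% female) scaled down; the sex-specific accelerated-aging
    gaps default to 3.5 y (males) and 1.8 y (females) with a 2-y spread.
    Ages are uniform over the stated ranges (healthy 18-94, PD 33-85).
    """

    n_hc_train: int = 270
    n_hc_holdout: int = 30
    n_pd: int = 373
    female_fraction_hc: float = 0.53
    female_fraction_pd: float = 0.34
    age_range: tuple[float, float] = (18.0, 94.0)
    pd_age_range: tuple[float, float] = (33.0, 85.0)
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_spacing: float = 8.0  # mm, isotropic
    atrophy_rate: float = -0.002  # GM probability units / year, uniform
    atrophy_rate_map: np.ndarray | None = None  # overrides atrophy_rate per voxel
    wm_rate_factor: float = 0.5  # WM declines at this fraction of the GM rate
    sex_offset: float = -0.01  # additive GM offset for males (F is reference)
    sex_offset_map: np.ndarray | None = None
    scanner_levels: tuple[ScannerLevel, ...] = (
        ScannerLevel("Siemens", 3.0, 0.0, 1.0),
        ScannerLevel("GE", 1.5, 0.01, 1.2),
    )
    pad_gap_mean_f: float = 1.8  # years
    pad_gap_mean_m: float = 3.5  # years
    pad_gap_sd: float = 2.0  # years
    noise_fwhm: float = 8.0  # mm
    noise_sd: float = 0.02  # probability units, per tissue
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_hc_train <= 0:
            bad.append("n_hc_train must be > 0")
        if self.n_hc_holdout <= 0:
            bad.append("n_hc_holdout must be > 0")
        if self.n_pd < 0:
            bad.append("n_pd must be >= 0")
        for name in ("female_fraction_hc", "female_fraction_pd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name} must be in [0, 1]")
        for name in ("age_range", "pd_age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                bad.append(f"{name} must have min < max")
        if self.pad_gap_sd < 0:
            bad.append("pad_gap_sd must be >= 0")
        if self.noise_sd < 0:
            bad.append("noise_sd must be >= 0")
        if self.noise_fwhm < 0:
            bad.append("noise_fwhm must be >= 0")
        if self.voxel_spacing <= 0:
            bad.append("voxel_spacing must be > 0")
        if len(self.scanner_levels) == 0:
            bad.append("scanner_levels must be non-empty")
        if any(n <= 0 for n in self.grid_shape):
            bad.append("grid_shape entries must be > 0")
        if bad:
            raise ValueError("invalid CohortSpec: " + "; ".join(bad))


def ellipsoid_mask(shape: tuple[int, int, int], semi_frac: float = 0.49) -> np.ndarray:
    """Boolean ellipsoidal brain mask centred on the grid.

    With the default 16^3 grid this yields roughly 2000 in-mask voxels.
    """
    r2 = _norm_radius2(shape, semi_frac)
    return r2 <= 1.0


def fullscale_mask(shape: tuple[int, int, int] = (20, 20, 20)) -> np.ndarray:
    """A mask with exactly 3747 in-mask voxels, matching the per-tissue
    voxel count of the full-resolution 8-mm template this bench emulates.

    The 3747 voxels closest (in normalised ellipsoid radius, ties broken by
    flat index) to the grid centre are kept.
    """
    n_target = 3747
    if int(np.prod(shape)) < n_target:
        raise ValueError(f"grid {shape} has fewer than {n_target} voxels")
    r2 = _norm_radius2(shape, semi_frac=0.5)
    order = np.argsort(r2.ravel(), kind="stable")
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    mask[order[:n_target]] = True
    return mask.reshape(shape)


def _norm_radius2(shape: tuple[int, int, int], semi_frac: float) -> np.ndarray:
    axes = [np.arange(n, dtype=float) - (n - 1) / 2.0 for n in shape]
    semis = [max(semi_frac * n, 0.5) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (
        (xx / semis[0]) ** 2 + (yy / semis[1]) ** 2 + (zz / semis[2]) ** 2
    )


def tissue_templates(
    shape: tuple[int, int, int], mask: np.ndarray
) -> dict[str, np.ndarray]:
    """Smooth radial GM/WM/CSF probability templates.

    GM density rises toward the surface (cortical ribbon), WM toward the
    centre, CSF with the square of the radius; the three sum to < 1
    everywhere, leaving headroom for offsets and noise.
    """
    r = np.sqrt(np.clip(_norm_radius2(shape, semi_frac=0.49), 0.0, None))
    r = np.clip(r, 0.0, 1.0)
    gm = (0.38 + 0.20 * r) * mask
    wm = (0.12 + 0.35 * (1.0 - r)) * mask
    csf = (0.04 + 0.08 * r**2) * mask
    return {"GM": gm, "WM": wm, "CSF": csf}


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject phenotype table for a cohort spec.

    Sex is Bernoulli per subject at the group's female fraction; ages are
    uniform over the group's age range; PwP receive a latent accelerated-
    aging gap ``true_gap ~ N(gap_mean_sex, pad_gap_sd)`` and a diagnosis
    age such that disease duration (months) is scan age minus diagnosis
    age times twelve, rounded to whole months.  Healthy rows have
    ``true_gap = 0`` and missing disease columns.
    """
    spec.validate()
    rng = rng_stream(spec.seed, "synthcohort", "phenotypes")
    rows: list[dict] = []
    counts = {
        "HC_train": (spec.n_hc_train, spec.female_fraction_hc, spec.age_range),
        "HC_holdout": (spec.n_hc_holdout, spec.female_fraction_hc, spec.age_range),
        "PD": (spec.n_pd, spec.female_fraction_pd, spec.pd_age_range),
    }
    idx = 0
    for group, (n, f_frac, age_rng) in counts.items():
        for _ in range(n):
            sex = "F" if rng.random() < f_frac else "M"
            age = float(rng.uniform(*age_rng))
            level = spec.scanner_levels[rng.integers(len(spec.scanner_levels))]
            row = {
                "subject_id": f"S{idx:04d}",
                "group": group,
                "sex": sex,
                "age": age,
                "education": int(rng.integers(8, 21)),
                "vendor": level.vendor,
                "field_strength": level.field_strength,
                "diagnosis_age": np.nan,
                "disease_duration": np.nan,
                "true_gap": 0.0,
            }
            if group == "PD":
                gap_mean = spec.pad_gap_mean_f if sex == "F" else spec.pad_gap_mean_m
                row["true_gap"] = float(rng.normal(gap_mean, spec.pad_gap_sd))
                years_since_dx = float(rng.uniform(0.25, 8.0))
                dx_age = max(age - years_since_dx, age_rng[0] - 8.0)
                row["diagnosis_age"] = dx_age
                row["disease_duration"] = float(round((age - dx_age) * 12.0))
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def _smooth_noise_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    mask: np.ndarray,
    fwhm_mm: float,
    spacing: float,
    sd: float,
) -> np.ndarray:
    white = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma = fwhm_mm * FWHM_TO_SIGMA / spacing
        smoothed = ndimage.gaussian_filter(white, sigma=sigma, mode="constant")
    else:
        smoothed = white
    in_sd = smoothed[mask].std()
    if in_sd > 0:
        smoothed = smoothed / in_sd
    return smoothed * sd


def generate_tissue_maps(
    pheno: pd.DataFrame,
    spec: CohortSpec,
    mask: np.ndarray | None = None,
) -> dict[str, dict[str, VoxelGrid]]:
    """Generate GM/WM/CSF maps for every subject in the phenotype table.

    Per voxel, GM = template + atrophy_rate * (age + true_gap) + sex offset
    (males) + scanner offset + smooth noise; WM declines analogously at
    ``wm_rate_factor`` times the GM rate; CSF absorbs the GM and WM loss so
    TIV is age-invariant.  Values are clipped to [0, 1], and on the rare
    voxels where noise pushes the three tissues above unit sum they are
    rescaled to sum to one.
    """
    spec.validate()
    if mask is None:
        mask = ellipsoid_mask(spec.grid_shape)
    templates = tissue_templates(spec.grid_shape, mask)
    rate_gm = (
        np.asarray(spec.atrophy_rate_map, dtype=float)
        if spec.atrophy_rate_map is not None
        else np.full(spec.grid_shape, spec.atrophy_rate)
    ) * mask
    rate_wm = rate_gm * spec.wm_rate_factor
    sex_off = (
        np.asarray(spec.sex_offset_map, dtype=float)
        if spec.sex_offset_map is not None
        else np.full(spec.grid_shape, spec.sex_offset)
    ) * mask
    levels = {lv.vendor: lv for lv in spec.scanner_levels}
    spacing = (spec.voxel_spacing,) * 3
    rng = rng_stream(spec.seed, "synthcohort", "maps")

    out: dict[str, dict[str, VoxelGrid]] = {}
    for row in pheno.itertuples(index=False):
        if row.vendor not in levels:
            raise ValueError(
                f"unknown vendor {row.vendor!r} for subject {row.subject_id}; "
                f"known: {sorted(levels)}"
            )
        level = levels[row.vendor]
        eff_age = float(row.age) + float(row.true_gap)
        gm = templates["GM"] + rate_gm * eff_age + level.offset * mask
        if row.sex == "M":
            gm = gm + sex_off
        wm = templates["WM"] + rate_wm * eff_age
        csf = templates["CSF"] - (rate_gm + rate_wm) * eff_age
        tissues = {"GM": gm, "WM": wm, "CSF": csf}
        if spec.noise_sd > 0:
            for name in tissues:
                noise = _smooth_noise_field(
                    rng,
                    spec.grid_shape,
                    mask,
                    spec.noise_fwhm,
                    spec.voxel_spacing,
                    spec.noise_sd * level.noise_scale,
                )
                tissues[name] = tissues[name] + noise * mask
        stack = np.stack([np.clip(tissues[t] * mask, 0.0, 1.0) for t in ("GM", "WM", "CSF")])
        total = stack.sum(axis=0)
        over = total > 1.0
        if over.any():
            stack[:, over] /= total[over]
        out[row.subject_id] = {
            t: VoxelGrid(values=stack[i], spacing=spacing, mask=mask, tissue=t)
            for i, t in enumerate(("GM", "WM", "CSF"))
        }
    return out


@dataclass(frozen=True)
class OutcomeEffect:
    """Generating model of one clinical outcome.

    ``coefs`` maps predictor names (a subset of the outcome's family
    predictors) to coefficients; absent predictors contribute zero.
    """

    name: str
    family: str
    coefs: dict[str, float]
    residual_sd: float = 0.0
    missing_prob: float = 0.0

    def validate(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"outcome {self.name!r}: unknown family {self.family!r}; "
                f"known: {sorted(MODEL_FAMILIES)}"
            )
        if self.name not in FAMILY_OUTCOMES[self.family]:
            raise ValueError(
                f"outcome {self.name!r} is not in family {self.family!r} "
                f"(known outcomes: {FAMILY_OUTCOMES[self.family]})"
            )
        extra = set(self.coefs) - set(MODEL_FAMILIES[self.family])
        if extra:
            raise ValueError(
                f"outcome {self.name!r}: coefficients for predictors outside "
                f"the {self.family} family: {sorted(extra)}"
            )
        if self.residual_sd < 0:
            raise ValueError(f"outcome {self.name!r}: residual_sd must be >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError(f"outcome {self.name!r}: missing_prob must be in [0, 1]")


@dataclass
class ClinicalEffectSpec:
    outcomes: list[OutcomeEffect] = field(default_factory=list)

    def validate(self) -> None:
        for o in self.outcomes:
            o.validate()


def default_effect_spec(
    pad_coefs: dict[str, float] | None = None,
    residual_scale: float = 1.0,
    missing_prob: float = 0.02,
) -> ClinicalEffectSpec:
    """Plausible generating coefficients for all clinical outcomes.

    Magnitudes are chosen to land outcome means and spreads near published
    PD cohort summaries (UPDRS-III ~ 21 +/- 9, MoCA ~ 27 +/- 2, ...).
    ``pad_coefs`` overrides the Brain-PAD coefficient per outcome (default
    includes modest effects on motor severity, cognition and RBD).
    """
    base: dict[str, tuple[str, dict[str, float], float]] = {
        # name: (family, coefs, residual_sd)
        "UPDRS3_total": ("motor", {"intercept": 8.0, "brain_pad": 0.30, "age": 0.12, "disease_duration": 0.05, "education": -0.10, "sex": 1.5}, 7.0),
        "UPDRS3_rigidity": ("motor", {"intercept": 2.0, "brain_pad": 0.08, "age": 0.02, "disease_duration": 0.01, "sex": 0.5}, 2.0),
        "UPDRS3_tremor": ("motor", {"intercept": 3.0, "brain_pad": 0.04, "age": 0.01, "disease_duration": 0.01}, 2.5),
        "MoCA": ("nonmotor", {"intercept": 28.0, "brain_pad": -0.08, "age": -0.02, "education": 0.08, "UPDRS3_total": -0.02}, 2.0),
        "ESS": ("nonmotor", {"intercept": 5.0, "brain_pad": 0.05, "age": 0.01, "UPDRS3_total": 0.05}, 3.0),
        "LNS": ("nonmotor", {"intercept": 12.0, "brain_pad": -0.05, "age": -0.04, "education": 0.15}, 2.5),
        "REM": ("nonmotor", {"intercept": 3.0, "brain_pad": 0.10, "UPDRS3_total": 0.03}, 2.5),
        "BJLO": ("nonmotor", {"intercept": 13.0, "brain_pad": -0.06, "age": -0.02, "education": 0.05}, 2.0),
        "HVLT_recall": ("nonmotor", {"intercept": 9.0, "brain_pad": -0.05, "age": -0.03, "education": 0.06}, 2.2),
        "HVLT_recognition": ("nonmotor", {"intercept": 11.0, "brain_pad": -0.03, "age": -0.01}, 1.2),
        "olfactory": ("nonmotor", {"intercept": 24.0, "brain_pad": -0.10, "age": -0.08, "sex": -1.5}, 6.0),
        "SDM": ("nonmotor", {"intercept": 55.0, "brain_pad": -0.20, "age": -0.30, "education": 0.60}, 8.0),
        "anxiety": ("mood", {"intercept": 40.0, "brain_pad": 0.15, "UPDRS3_total": 0.15, "MoCA": -0.40}, 9.0),
        "GDS": ("mood", {"intercept": 3.0, "brain_pad": 0.05, "UPDRS3_total": 0.05, "MoCA": -0.08}, 2.2),
    }
    outcomes = []
    for name, (family, coefs, sd) in base.items():
        coefs = dict(coefs)
        if pad_coefs is not None and name in pad_coefs:
            coefs["brain_pad"] = pad_coefs[name]
        outcomes.append(
            OutcomeEffect(
                name=name,
                family=family,
                coefs=coefs,
                residual_sd=sd * residual_scale,
                missing_prob=missing_prob,
            )
        )
    return ClinicalEffectSpec(outcomes=outcomes)


def generate_clinical_scores(
    pheno: pd.DataFrame,
    eff: ClinicalEffectSpec,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Fill clinical outcome columns for PD rows from their linear models.

    Each outcome is its family's linear combination — with ``true_gap``
    standing in the Brain-PAD slot — plus Gaussian noise; families are
    generated in dependency order (motor, then non-motor which may load on
    UPDRS-III, then mood which may also load on MoCA).  Missing values are
    injected per outcome at its ``missing_prob``.  Returns the augmented
    table and the ground-truth generating coefficients.
    """
    eff.validate()
    rng = rng_stream(seed, "synthcohort", "clinical")
    out = pheno.copy()
    pd_mask = out["group"] == "PD"
    n_pd = int(pd_mask.sum())
    for col in CLINICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan

    sex_code = (out.loc[pd_mask, "sex"] == "M").astype(float)
    predictors = {
        "intercept": np.ones(n_pd),
        "brain_pad": out.loc[pd_mask, "true_gap"].to_numpy(float),
        "age": out.loc[pd_mask, "age"].to_numpy(float),
        "disease_duration": out.loc[pd_mask, "disease_duration"].to_numpy(float),
        "education": out.loc[pd_mask, "education"].to_numpy(float),
        "sex": sex_code.to_numpy(float),
    }

    truth: dict = {"outcomes": {}}
    ordered = sorted(
        eff.outcomes, key=lambda o: ("motor", "nonmotor", "mood").index(o.family)
    )
    for o in ordered:
        y = np.zeros(n_pd)
        for pred, coef in o.coefs.items():
            if pred not in predictors:
                raise ValueError(
                    f"outcome {o.name!r} requires predictor {pred!r} which has "
                    "not been generated yet"
                )
            y = y + coef * predictors[pred]
        if o.residual_sd > 0:
            y = y + rng.normal(0.0, o.residual_sd, size=n_pd)
        recorded = y
        if o.missing_prob > 0:
            miss = rng.random(n_pd) < o.missing_prob
            recorded = np.where(miss, np.nan, y)
        out.loc[pd_mask, o.name] = recorded
        # later families load on the underlying score, not its (possibly
        # unrecorded) measurement — missingness must not cascade
        predictors[o.name] = y
        truth["outcomes"][o.name] = {
            "family": o.family,
            "coefs": dict(o.coefs),
            "residual_sd": o.residual_sd,
            "missing_prob": o.missing_prob,
        }
    return out, truth


def spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    for key in ("atrophy_rate_map", "sex_offset_map"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["scanner_levels"] = [list(dataclasses.astuple(lv)) for lv in spec.scanner_levels]
    return d
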
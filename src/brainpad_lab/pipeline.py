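"""End-to-end orchestration of the synthetic brain-aging study.

``run_all`` sequences the stages — simulate cohort, smooth/resample maps,
assemble features, cross-validate and train the age model, bias-adjust,
compute Brain-PAD per set, propensity-match males to females, run the
clinical regression battery, and (optionally) the voxelwise analysis —
and returns a report bundle whose tables mirror how such studies are
summarised: per-set accuracy metrics with mean Brain-PAD and 95% CI,
battery CSVs, cluster tables, plus a ground-truth recovery summary that
only a synthetic cohort can provide.  Identical config and seed give a
bit-identical bundle; every table carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brainage, clinstats, matching, morphometry, voxelstats
from .synthcohort import (
    CohortSpec,
    ScannerLevel,
    default_effect_spec,
    generate_clinical_scores,
    generate_phenotypes,
    generate_tissue_maps,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_all", "load_config", "validate_config", "default_config"]


@dataclass
class MorphometryConfig:
    fwhm_mm: float = 4.0
    target_spacing_mm: float = 8.0


@dataclass
class ModelConfig:
    C: float = 1.0
    epsilon: float = 0.1
    folds: int = 10


@dataclass
class MatchingConfig:
    covariates: tuple[str, ...] = matching.DEFAULT_MATCH_COVARIATES
    ratio: int = 1
    caliper: float | None = None


@dataclass
class BatteryConfig:
    families: tuple[str, ...] = ("motor", "nonmotor", "mood")
    alpha: float = 0.05


@dataclass
class VoxelwiseConfig:
    enabled: bool = True
    n_perm: int = 300
    alpha: float = 0.05
    min_extent_voxels: int = 10


@dataclass
class EffectConfig:
    residual_scale: float = 1.0
    missing_prob: float = 0.02


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: EffectConfig = field(default_factory=EffectConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    voxelwise: VoxelwiseConfig = field(default_factory=VoxelwiseConfig)
    seed: int = 0

    def content_hash(self) -> str:
        blob = json.dumps(_to_plain(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


_SECTION_TYPES = {
    "cohort": CohortSpec,
    "effects": EffectConfig,
    "morphometry": MorphometryConfig,
    "model": ModelConfig,
    "matching": MatchingConfig,
    "battery": BatteryConfig,
    "voxelwise": VoxelwiseConfig,
}

_TUPLE_FIELDS = {"age_range", "pd_age_range", "grid_shape", "covariates", "families"}


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key == "scanner_levels":
            val = tuple(
                ScannerLevel(**v) if isinstance(v, dict) else ScannerLevel(*v)
                for v in val
            )
        elif key in _TUPLE_FIELDS and isinstance(val, (list, tuple)):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys anywhere are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config key(s) at root: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            sec = raw[name]
            if not isinstance(sec, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, sec, name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    cfg = RunConfig(**kwargs)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def default_config() -> RunConfig:
    return RunConfig()


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of human-readable problems; empty means valid."""
    problems: list[str] = []
    try:
        cfg.cohort.validate()
    except ValueError as exc:
        problems.append(str(exc))
    if cfg.model.folds < 2:
        problems.append("model.folds must be >= 2")
    if cfg.model.C <= 0:
        problems.append("model.C must be > 0")
    if cfg.morphometry.fwhm_mm < 0:
        problems.append("morphometry.fwhm_mm must be >= 0")
    if cfg.morphometry.target_spacing_mm < cfg.cohort.voxel_spacing:
        problems.append("morphometry.target_spacing_mm must be >= cohort voxel spacing")
    if cfg.voxelwise.enabled and cfg.voxelwise.n_perm < 100:
        problems.append("voxelwise.n_perm must be >= 100")
    if not 0 < cfg.battery.alpha < 1:
        problems.append("battery.alpha must be in (0, 1)")
    return problems


@dataclass
class ReportBundle:
    table2: pd.DataFrame  # per-set accuracy + mean Brain-PAD metrics
    pad_table: pd.DataFrame  # per-subject Brain-PAD
    battery: pd.DataFrame
    balance: pd.DataFrame
    clusters: pd.DataFrame
    ttests: dict
    recovery: dict
    config_hash: str
    seed: int
    timings: dict[str, float] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("table2", self.table2),
            ("brainpad", self.pad_table),
            ("battery", self.battery),
            ("balance", self.balance),
            ("clusters", self.clusters),
        ):
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "ttests": self.ttests,
                    "recovery": self.recovery,
                    "timings": self.timings,
                },
                indent=1,
            )
        )
        return out


def _metrics_row(set_name: str, group: str, metrics: brainage.FitMetrics) -> dict:
    return {
        "set": set_name,
        "group": group,
        "n": metrics.n,
        "mae_y": metrics.mae,
        "rmse_y": metrics.rmse,
        "r2": metrics.r2,
        "mean_brainpad_y": metrics.mean_pad,
        "ci95_low_y": metrics.pad_ci95[0],
        "ci95_high_y": metrics.pad_ci95[1],
    }


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the full synthetic study; see the module docstring.

    A failure in any stage aborts the run with the stage name and cause;
    when an output directory was given, a ``FAILED`` marker is left there
    next to whatever partial outputs exist.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    tracker: dict[str, str] = {"stage": "init"}
    try:
        bundle = _run_stages(config, tracker)
    except Exception as exc:
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text(f"stage {tracker['stage']} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {tracker['stage']!r} failed: {exc}") from exc
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


def _run_stages(config: RunConfig, tracker: dict[str, str]) -> ReportBundle:
    timings: dict[str, float] = {}
    seed = config.seed
    spec = dataclasses.replace(config.cohort, seed=seed)

    def _stage(name):
        tracker["stage"] = name
        timings[name] = time.perf_counter()
        log.info("stage %s", name)

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]

    _stage("simulate")
    pheno = generate_phenotypes(spec)
    eff = default_effect_spec(
        residual_scale=config.effects.residual_scale,
        missing_prob=config.effects.missing_prob,
    )
    pheno, truth = generate_clinical_scores(pheno, eff, seed=seed)
    maps = generate_tissue_maps(pheno, spec)
    log.info("simulated %d subjects (%d PD)", len(pheno), (pheno.group == "PD").sum())
    _done("simulate")

    _stage("morphometry")
    for sid, tissues in maps.items():
        for t, g in tissues.items():
            g2 = morphometry.smooth(g, config.morphometry.fwhm_mm)
            g2 = morphometry.resample(g2, config.morphometry.target_spacing_mm)
            maps[sid][t] = g2
    _done("morphometry")

    _stage("features")
    features = brainage.assemble_features(maps, pheno)
    ages = pheno.set_index("subject_id")["age"]
    train_ids = pheno.loc[pheno.group == "HC_train", "subject_id"].tolist()
    holdout_ids = pheno.loc[pheno.group == "HC_holdout", "subject_id"].tolist()
    pd_ids = pheno.loc[pheno.group == "PD", "subject_id"].tolist()
    _done("features")

    _stage("train")
    f_train = features.subset(train_ids)
    y_train = ages.loc[train_ids].to_numpy()
    cv = brainage.crossval_metrics(
        f_train, y_train, k=config.model.folds, seed=seed,
        C=config.model.C, epsilon=config.model.epsilon,
    )
    model = brainage.train_age_model(
        f_train, y_train, C=config.model.C, epsilon=config.model.epsilon, seed=seed
    )
    raw_train = model.predict(f_train)
    model.bias_alpha, model.bias_beta = brainage.fit_bias_adjustment(raw_train, y_train)
    _done("train")

    _stage("pad")
    rows = [_metrics_row("training_cv", "HC", cv)]
    pads: dict[str, float] = {}
    for set_name, ids in (
        ("training", train_ids),
        ("holdout", holdout_ids),
        ("pd", pd_ids),
    ):
        if not ids:
            continue
        f = features.subset(ids)
        y = ages.loc[ids].to_numpy()
        corrected = model.predict_corrected(f, y)
        pad = brainage.brainpad(corrected, y)
        pads.update(dict(zip(ids, pad)))
        rows.append(_metrics_row(set_name, "HC" if set_name != "pd" else "PD", brainage.evaluate(corrected, y)))
    pad_table = pd.DataFrame(
        {"subject_id": list(pads), "brain_pad": list(pads.values())}
    )
    data = pheno.merge(pad_table, on="subject_id", how="left")
    is_pd = data.group == "PD"
    for sex, name in (("F", "pd_female"), ("M", "pd_male")):
        sel = data.loc[is_pd & (data.sex == sex)]
        if len(sel) >= 2:
            ids = sel.subject_id.tolist()
            corrected = model.predict_corrected(features.subset(ids), ages.loc[ids].to_numpy())
            rows.append(_metrics_row(name, f"PD-{sex}", brainage.evaluate(corrected, ages.loc[ids].to_numpy())))
    _done("pad")

    _stage("match")
    mspec = matching.MatchSpec(
        covariates=tuple(config.matching.covariates),
        ratio=config.matching.ratio,
        caliper=config.matching.caliper,
        seed=seed,
    )
    match_result, balance = matching.match_minority_majority(
        data, is_pd & (data.sex == "F"), is_pd & (data.sex == "M"), mspec
    )
    matched_ids = set(match_result.matched_majority)
    sel = data.loc[data.subject_id.isin(matched_ids)]
    if len(sel) >= 2:
        ids = sel.subject_id.tolist()
        corrected = model.predict_corrected(features.subset(ids), ages.loc[ids].to_numpy())
        rows.append(_metrics_row("pd_male_matched", "PD-M*", brainage.evaluate(corrected, ages.loc[ids].to_numpy())))
    table2 = pd.DataFrame(rows)

    ttests = {}
    pad_f = data.loc[is_pd & (data.sex == "F"), "brain_pad"].to_numpy()
    pad_m = data.loc[is_pd & (data.sex == "M"), "brain_pad"].to_numpy()
    pad_mstar = data.loc[data.subject_id.isin(matched_ids), "brain_pad"].to_numpy()
    for name, a, b in (
        ("pd_m_vs_pd_f", pad_m, pad_f),
        ("pd_mstar_vs_pd_f", pad_mstar, pad_f),
    ):
        if len(a) >= 2 and len(b) >= 2:
            t, df, p = clinstats.group_ttest(a, b)
            ttests[name] = {"t": t, "df": df, "p": p}
    _done("match")

    _stage("battery")
    subgroups = {
        "PD": is_pd,
        "PD-F": is_pd & (data.sex == "F"),
        "PD-M": is_pd & (data.sex == "M"),
        "PD-M*": data.subject_id.isin(matched_ids),
    }
    tables = clinstats.run_battery(
        data, subgroups, families=tuple(config.battery.families), alpha=config.battery.alpha
    )
    battery = clinstats.battery_frame(tables)
    _done("battery")

    clusters = pd.DataFrame()
    if config.voxelwise.enabled:
        _stage("voxelwise")
        design = (
            data.set_index("subject_id")
            .loc[pd_ids, ["brain_pad", "age", "sex"]]
            .assign(sex=lambda d: (d.sex == "M").astype(float))
        )
        stack, mask, affine = voxelstats.stack_maps(maps, pd_ids, tissue="GM")
        vols = [morphometry.tissue_volumes(maps[s]["GM"], maps[s]["WM"], maps[s]["CSF"]).tiv_ml for s in pd_ids]
        design["tiv"] = vols
        stat = voxelstats.massuni_fit(stack, design, "brain_pad", mask, affine)
        p_corr, _ = voxelstats.fwe_correct(
            stack, design, "brain_pad", n_perm=config.voxelwise.n_perm, seed=seed
        )
        records = voxelstats.extract_clusters(
            stat, p_corr, alpha=config.voxelwise.alpha,
            min_extent_voxels=config.voxelwise.min_extent_voxels,
        )
        clusters = voxelstats.cluster_frame(records)
        _done("voxelwise")

    true_f = pheno.loc[is_pd & (pheno.sex == "F"), "true_gap"]
    true_m = pheno.loc[is_pd & (pheno.sex == "M"), "true_gap"]
    recovery = {
        "true_gap_mean_f": float(true_f.mean()) if len(true_f) else None,
        "true_gap_mean_m": float(true_m.mean()) if len(true_m) else None,
        "estimated_pad_mean_f": float(np.mean(pad_f)) if len(pad_f) else None,
        "estimated_pad_mean_m": float(np.mean(pad_m)) if len(pad_m) else None,
        "spec_gap_mean_f": spec.pad_gap_mean_f,
        "spec_gap_mean_m": spec.pad_gap_mean_m,
    }

    return ReportBundle(
        table2=table2,
        pad_table=pad_table,
        battery=battery,
        balance=balance,
        clusters=clusters,
        ttests=ttests,
        recovery=recovery,
        config_hash=config.content_hash(),
        seed=seed,
        timings={k: round(v, 3) for k, v in timings.items()},
    )
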
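"""Configuration-driven orchestration of the full design loop.

Stages: ``calibrate`` (porosity law) -> ``mesh`` (canonical construct)
-> ``sweep`` (factorial FE corpus, plus the uncertainty-augmented grid)
-> ``train`` (canonical and augmented surrogates, residual models) ->
``risk`` (Monte-Carlo reliability of the canonical design) ->
``optimize`` (risk-constrained GA, fresh-seed audit of the archive) ->
``report``.  Each stage writes machine-readable artefacts (CSV/JSON/VTK)
into the run directory and later stages declare their upstream files.

A single global seed deterministically derives one sub-seed per stage
(numpy ``SeedSequence(global_seed, spawn_key=(stage_index,))``), so any
stage can be rerun in isolation and a full rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__ as _code_version
from .doe import FEDataset, full_factorial, qc_filter, run_sweep
from .geometry import ConstructSpec, build_construct_mesh, write_vtk
from .materials import (LATTICE_COUPONS, TI6AL4V, CalibrationPoint,
                        calibrate_porosity_law, PorosityLaw,
                        read_calibration_csv, write_calibration_csv)
from .optimize import (GAConfig, construct_effective_modulus,
                       efficiency_index, objectives, run_ga,
                       surrogate_evaluator)
from .risk import (Thresholds, UncertaintyNode, UncertaintySpec, propagate,
                   sample_joint)
from .surrogate import (MLPSurrogate, evaluate, fit_residual_model,
                        split_stratified, ResidualModel)

__all__ = ["RunConfig", "ConfigError", "DependencyError", "STAGES",
           "validate_config", "run_stage", "run_all", "stage_seed"]

log = logging.getLogger("latticeplate")

STAGES = ("calibrate", "mesh", "sweep", "train", "risk", "optimize", "report")

#: Load levels of the canonical factorial (paper grid) are taken from
#: doe.PAPER_LEVELS; the augmented risk grid extends the load axis so the
#: +/-30% bite scatter around 600 N stays inside the training hull.
AUGMENTED_P_LEVELS = (300.0, 450.0, 600.0, 780.0)
AUGMENTED_BONE_LEVELS = (0.8, 1.0, 1.2)


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Normalised run configuration; defaults reproduce the canonical run."""

    geometry: ConstructSpec = field(default_factory=ConstructSpec)
    calibration_table: str | None = None  # CSV path; built-in coupons if None
    doe_levels: dict = field(default_factory=dict)  # {} = paper grid
    augmented_P: tuple = AUGMENTED_P_LEVELS
    bone_levels: tuple = AUGMENTED_BONE_LEVELS
    train: dict = field(default_factory=dict)  # MLPSurrogate overrides
    train_augmented: dict = field(default_factory=lambda: {"max_epochs": 400})
    split_fractions: tuple = (0.70, 0.15, 0.15)
    strata: tuple = ("P", "t_plate", "t_lat")
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    thresholds: Thresholds = field(default_factory=Thresholds)
    ga: GAConfig = field(default_factory=GAConfig)
    n_mc_search: int = 2000
    n_mc_audit: int = 10000
    verify_k: int = 3
    seed: int = 2025
    outdir: str = "runs/canonical"

    def config_hash(self) -> str:
        payload = json.dumps(_config_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


_KNOWN_KEYS = {"geometry", "calibration_table", "doe_levels", "augmented_P",
               "bone_levels", "train", "train_augmented", "split_fractions",
               "strata", "uncertainty", "thresholds", "ga", "n_mc_search",
               "n_mc_audit", "verify_k", "seed", "outdir"}


def validate_config(path_or_dict) -> RunConfig:
    """Normalise a YAML config file (or dict) into a RunConfig.

    All defaults are filled in; violations are gathered and raised
    together, each naming key, value and rule.  Unknown top-level keys
    warn (forward compatibility) rather than error.
    """
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    errors: list[str] = []
    for key in sorted(set(raw) - _KNOWN_KEYS):
        log.warning("unknown config key '%s' ignored", key)
        raw.pop(key)

    kwargs: dict[str, Any] = {}
    geo = raw.get("geometry", {})
    try:
        spec = ConstructSpec(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in geo.items()})
        spec.validate()
        kwargs["geometry"] = spec
    except (TypeError, ValueError) as err:
        errors.append(f"geometry: {geo!r}: {err}")

    if "uncertainty" in raw:
        try:
            nodes = tuple(UncertaintyNode(**nd) for nd in raw["uncertainty"])
            kwargs["uncertainty"] = UncertaintySpec(nodes=nodes)
        except (TypeError, ValueError) as err:
            errors.append(f"uncertainty: {raw['uncertainty']!r}: {err}")
    if "thresholds" in raw:
        try:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        except TypeError as err:
            errors.append(f"thresholds: {raw['thresholds']!r}: {err}")
    if "ga" in raw:
        try:
            kwargs["ga"] = GAConfig(**raw["ga"])
        except (TypeError, ValueError) as err:
            errors.append(f"ga: {raw['ga']!r}: {err}")

    for key in ("calibration_table", "doe_levels", "train", "train_augmented",
                "n_mc_search", "n_mc_audit", "verify_k", "seed", "outdir"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("augmented_P", "bone_levels", "split_fractions", "strata"):
        if key in raw:
            kwargs[key] = tuple(raw[key])

    for key in ("n_mc_search", "n_mc_audit", "seed"):
        if key in kwargs and (not isinstance(kwargs[key], int)
                              or kwargs[key] < (1 if key != "seed" else 0)):
            errors.append(f"{key}: {kwargs[key]!r}: must be a positive integer")
    if errors:
        raise ConfigError("invalid configuration:\n" +
                          "\n".join(f"  - {e}" for e in errors))
    return RunConfig(**kwargs)


def stage_seed(cfg: RunConfig, stage: str) -> int:
    """Per-stage sub-seed derived from the global seed (documented scheme)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _write_json(path: Path, payload: dict) -> None:
    _write_atomic(path, json.dumps(payload, indent=2, sort_keys=True))


def _require(outdir: Path, stage: str, *files: str) -> None:
    for f in files:
        if not (outdir / f).exists():
            raise DependencyError(
                f"stage '{stage}' needs '{f}'; run the stage that produces "
                "it first")


def _load_law(outdir: Path) -> PorosityLaw:
    d = json.loads((outdir / "porosity_law.json").read_text())
    return PorosityLaw(E_solid=d["E_solid"], C=d["C"], n=d["n"],
                       calibration=tuple(CalibrationPoint(*pt)
                                         for pt in d["calibration"]),
                       fit_r2=d["fit_r2"])


# -- stages ---------------------------------------------------------------


def _stage_calibrate(cfg: RunConfig, outdir: Path) -> dict:
    points = (read_calibration_csv(cfg.calibration_table)
              if cfg.calibration_table else LATTICE_COUPONS)
    law = calibrate_porosity_law(points, TI6AL4V.E)
    _write_json(outdir / "porosity_law.json",
                {"E_solid": law.E_solid, "C": law.C, "n": law.n,
                 "fit_r2": law.fit_r2,
                 "calibration": [[p.porosity, p.E_eff] for p in law.calibration]})
    write_calibration_csv(law.calibration, outdir / "calibration.csv")
    log.info("calibrated porosity law: C=%.4f n=%.4f r2=%.5f",
             law.C, law.n, law.fit_r2)
    return {"C": law.C, "n": law.n, "fit_r2": law.fit_r2}


def _stage_mesh(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "mesh", "porosity_law.json")
    law = _load_law(outdir)
    mesh = build_construct_mesh(cfg.geometry)
    write_vtk(mesh, outdir / "construct.vtk")
    summary = {"n_nodes": mesh.n_nodes, "n_elements": mesh.n_elements,
               "element_size": mesh.element_size,
               "porosity": cfg.geometry.porosity(),
               "mesh_divisions": list(cfg.geometry.mesh_divisions)}
    _write_json(outdir / "mesh_summary.json", summary)
    log.info("meshed canonical construct: %d elements", mesh.n_elements)
    return summary


def _stage_sweep(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "sweep", "porosity_law.json")
    law = _load_law(outdir)
    seed = stage_seed(cfg, "sweep")
    levels = dict(cfg.doe_levels) or None
    # augmented grid: same geometric levels, extended load axis
    from .doe import PAPER_LEVELS
    base = dict(levels or PAPER_LEVELS)
    base["P"] = tuple(cfg.augmented_P)
    aug_points = full_factorial(base)
    ds = run_sweep(aug_points, cfg.geometry, law,
                   bone_levels=cfg.bone_levels, seed=seed)
    clean = qc_filter(ds)
    clean.to_csv(outdir / "dataset_augmented.csv")
    canonical_P = set(dict(levels or PAPER_LEVELS)["P"])
    sub = clean.df[(clean.df.bone_scale == 1.0) &
                   clean.df.P.isin(canonical_P)].drop(columns="bone_scale")
    sub = sub.reset_index(drop=True)
    canonical = FEDataset(df=sub, provenance={**clean.provenance,
                                              "slice": "bone=1.0, paper P"})
    canonical.to_csv(outdir / "dataset.csv")
    log.info("sweep: %d augmented rows retained (%d dropped); canonical %d",
             len(clean), len(clean.exclusions), len(sub))
    return {"n_augmented": len(clean), "n_canonical": len(sub),
            "n_dropped": len(clean.exclusions)}


def _stage_train(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "train", "dataset.csv", "dataset_augmented.csv")
    seed = stage_seed(cfg, "train")
    ds = FEDataset.from_csv(outdir / "dataset.csv")
    train_df, val_df, test_df = split_stratified(
        ds.df, cfg.split_fractions, seed=seed, strata=cfg.strata)
    cols = ["d", "a", "t_lat", "t_plate", "P"]
    tcols = ["sigma_vm_max", "delta_max", "sigma_screw_max"]
    net = MLPSurrogate(random_state=seed, **cfg.train)
    net.fit(train_df[cols].to_numpy(), train_df[tcols].to_numpy(),
            X_val=val_df[cols].to_numpy(), y_val=val_df[tcols].to_numpy())
    report = evaluate(net, test_df[cols].to_numpy(), test_df[tcols].to_numpy())
    residual = fit_residual_model(net, test_df[cols].to_numpy(),
                                  test_df[tcols].to_numpy())
    net.save(outdir / "surrogate.json")
    net.history_.to_csv(outdir / "history.csv", index=False)

    aug = FEDataset.from_csv(outdir / "dataset_augmented.csv")
    acols = cols + ["bone_scale"]
    atr, aval, ate = split_stratified(aug.df, cfg.split_fractions,
                                      seed=seed + 1,
                                      strata=tuple(cfg.strata) + ("bone_scale",))
    net_aug = MLPSurrogate(random_state=seed + 1,
                           **{**cfg.train, **cfg.train_augmented})
    net_aug.fit(atr[acols].to_numpy(), atr[tcols].to_numpy(),
                X_val=aval[acols].to_numpy(), y_val=aval[tcols].to_numpy())
    report_aug = evaluate(net_aug, ate[acols].to_numpy(), ate[tcols].to_numpy())
    residual_aug = fit_residual_model(net_aug, ate[acols].to_numpy(),
                                      ate[tcols].to_numpy())
    net_aug.save(outdir / "surrogate_aug.json")

    hull = np.vstack([aug.df[acols].min().to_numpy(),
                      aug.df[acols].max().to_numpy()])
    payload = {"canonical": report.as_dict(),
               "augmented": report_aug.as_dict(),
               "split_sizes": {"train": len(train_df), "val": len(val_df),
                               "test": len(test_df)},
               "best_epoch": net.best_epoch_,
               "best_epoch_aug": net_aug.best_epoch_}
    _write_json(outdir / "eval.json", payload)
    _write_json(outdir / "residuals.json",
                {"canonical": residual.sigma.tolist(),
                 "augmented": residual_aug.sigma.tolist(),
                 "training_hull": hull.tolist()})
    log.info("surrogate: test R2 %s, MAE%% %s",
             np.round(report.r2, 4).tolist(),
             np.round(report.mae_pct, 2).tolist())
    return payload


def _load_aug_model(outdir: Path):
    net_aug = MLPSurrogate.load(outdir / "surrogate_aug.json")
    res = json.loads((outdir / "residuals.json").read_text())
    residual_aug = ResidualModel(sigma=np.array(res["augmented"]))
    hull = np.array(res["training_hull"])
    return net_aug, residual_aug, hull


def _stage_risk(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "risk", "surrogate_aug.json", "residuals.json")
    seed = stage_seed(cfg, "risk")
    law = _load_law(outdir)
    net_aug, residual_aug, hull = _load_aug_model(outdir)
    from .doe import DesignPoint
    g = cfg.geometry
    design = DesignPoint(d=g.d, a=g.a, t_lat=g.t_lat, t_plate=g.t_plate,
                         P=600.0)
    samples = sample_joint(cfg.uncertainty, cfg.n_mc_audit, seed)
    rep = propagate(design, samples, net_aug, residual_aug, cfg.thresholds,
                    seed=seed + 1, training_hull=hull)
    payload = {"design": design.as_dict(), **rep.as_dict()}
    if cfg.verify_k > 0:
        from .risk import verify_against_fem
        ver = verify_against_fem(design, cfg.verify_k, samples, cfg.geometry,
                                 law, net_aug)
        payload["fem_verification_max_rel_err"] = \
            ver.drop(columns="sample").max().to_dict()
    _write_json(outdir / "risk_canonical.json", payload)
    log.info("canonical design risk: stress %.4f, disp %.4f",
             rep.pr_stress_allow, rep.pr_disp)
    return payload


def _stage_optimize(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "optimize", "surrogate.json", "surrogate_aug.json",
             "residuals.json")
    seed = stage_seed(cfg, "optimize")
    net = MLPSurrogate.load(outdir / "surrogate.json")
    net_aug, residual_aug, hull = _load_aug_model(outdir)
    samples = sample_joint(cfg.uncertainty, cfg.n_mc_search, seed)

    def risk_fn(design):
        # one-sided 95% upper confidence bound on the worst exceedance
        # probability, so finite-sample search noise cannot admit a
        # design whose true risk sits above the cap
        rep = propagate(design, samples, net_aug, residual_aug,
                        cfg.thresholds, seed=seed + 1)
        return max(rep.pr_stress_allow + 1.645 * rep.se_stress_allow,
                   rep.pr_yield90 + 1.645 * rep.se_yield90,
                   rep.pr_disp + 1.645 * rep.se_disp)

    evaluator = surrogate_evaluator(net)
    ga = dataclasses.replace(cfg.ga, seed=seed,
                             risk_threshold=cfg.thresholds.risk_cap)
    pareto = run_ga(ga, None,
                    lambda d: objectives(d, evaluator, cfg.geometry),
                    risk_fn)

    # fresh-seed audit of every archive member at the full sample count
    audit_seed = stage_seed(cfg, "optimize") + 7919
    audit_samples = sample_joint(cfg.uncertainty, cfg.n_mc_audit, audit_seed)
    audits = []
    for e in pareto.entries:
        rep = propagate(e["design"], audit_samples, net_aug, residual_aug,
                        cfg.thresholds, seed=audit_seed + 1,
                        training_hull=hull)
        audits.append({"design": e["design"].as_dict(), **rep.as_dict()})

    front = pareto.to_frame()
    if len(front):
        deltas = np.array([evaluator(e["design"])[1]
                           for e in pareto.entries])
        front["E_construct"] = [construct_effective_modulus(dl, 600.0,
                                                            cfg.geometry)
                                for dl in deltas]
        front["p"] = [e["design"].porosity() for e in pareto.entries]
        if len(front) >= 2:
            scores, binned = efficiency_index(front)
            front["efficiency"] = scores
            binned.to_csv(outdir / "efficiency_bins.csv", index=False)
    front.to_csv(outdir / "pareto.csv", index=False, float_format="%.10g")
    pareto.generation_log.to_csv(outdir / "ga_log.csv", index=False)
    _write_json(outdir / "pareto_audit.json",
                {"status": pareto.status, "n_members": len(pareto),
                 "audits": audits,
                 "max_audited_probability": max(
                     (a_rep["pr_stress_allow"] for a_rep in audits),
                     default=0.0),
                 "max_audited_any": max(
                     (max(a["pr_stress_allow"], a["pr_yield90"], a["pr_disp"])
                      for a in audits), default=0.0)})
    log.info("GA archive: %d members (%s)", len(pareto), pareto.status)
    return {"n_members": len(pareto), "status": pareto.status}


def _stage_report(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir, "report", "eval.json", "pareto_audit.json",
             "risk_canonical.json", "mesh_summary.json")
    report = {"config_hash": cfg.config_hash(),
              "code_version": _code_version,
              "seed": cfg.seed,
              "stage_seeds": {s: stage_seed(cfg, s) for s in STAGES},
              "mesh": json.loads((outdir / "mesh_summary.json").read_text()),
              "surrogate": json.loads((outdir / "eval.json").read_text()),
              "risk_canonical": json.loads(
                  (outdir / "risk_canonical.json").read_text()),
              "pareto": json.loads((outdir / "pareto_audit.json").read_text()),
              "config": _config_to_dict(cfg)}
    _write_json(outdir / "run_report.json", report)
    return {"written": "run_report.json"}


_STAGE_FNS = {"calibrate": _stage_calibrate, "mesh": _stage_mesh,
              "sweep": _stage_sweep, "train": _stage_train,
              "risk": _stage_risk, "optimize": _stage_optimize,
              "report": _stage_report}


def run_stage(name: str, cfg: RunConfig) -> dict:
    if name not in _STAGE_FNS:
        raise ValueError(f"unknown stage '{name}'; choose from {STAGES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("stage %s starting (config %s, seed %d)", name,
             cfg.config_hash(), cfg.seed)
    out = _STAGE_FNS[name](cfg, outdir)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)
    return out


def run_all(cfg: RunConfig) -> dict[str, dict]:
    return {name: run_stage(name, cfg) for name in STAGES}
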
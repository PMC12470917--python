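"""Design-of-experiments generation, FE sweep execution and QC filtering.

The canonical training corpus is a full-factorial sweep over four
geometric factors (strut diameter d, unit-cell size a, lattice-core
thickness t_lat, face-plate thickness t_plate) and the two bite-load
levels, solved with the built-in FE chain on the converged canonical
mesh.  A Latin-hypercube generator is provided as an alternative for
continuous exploration.  Quality control drops non-converged solves and
geometrically infeasible strut combinations (d/a above the merge cap),
recording the exclusion reason per dropped row.

The sweep exploits the structure of the problem: designs sharing
(t_lat, t_plate) share a mesh, the lattice and bone moduli scale their
region stiffness matrices linearly, and the load level enters linearly,
so one factorisation serves every load (and the solve is exact, not
approximated, for each point).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import __version__ as _code_version
from .fem import LoadCase, ReusableSolver, assemble_stiffness, construct_material_map
from .geometry import ConstructSpec, build_construct_mesh
from .materials import (CORTICAL_BONE, InfeasibleStrutError, LatticeCell,
                        PorosityLaw, effective_modulus, struts_to_porosity)

__all__ = ["DesignPoint", "FEDataset", "PAPER_LEVELS", "full_factorial",
           "latin_hypercube", "qc_filter", "run_sweep",
           "DATASET_COLUMNS"]

#: Printed factorial levels of the training corpus (mm, mm, mm, mm, N).
PAPER_LEVELS: dict[str, tuple[float, ...]] = {
    "d": (0.40, 0.55, 0.70, 0.85, 1.00, 1.15),
    "a": (2.0, 2.5, 3.0, 3.5, 4.0),
    "t_lat": (1.5, 2.5, 3.5, 4.5),
    "t_plate": (1.0, 1.5),
    "P": (300.0, 600.0),
}

DATASET_COLUMNS = ["d", "a", "t_lat", "t_plate", "P", "p", "sigma_vm_max",
                   "delta_max", "sigma_screw_max", "converged"]

_VARS = ("d", "a", "t_lat", "t_plate", "P")


@dataclass(frozen=True)
class DesignPoint:
    d: float  # strut diameter, mm
    a: float  # unit-cell size, mm
    t_lat: float  # lattice-core thickness, mm
    t_plate: float  # face-plate thickness, mm
    P: float  # bite force, N
    extras: tuple[tuple[str, float], ...] = ()

    def porosity(self, cell: LatticeCell = LatticeCell()) -> float:
        return struts_to_porosity(self.d, self.a, cell)

    def as_dict(self) -> dict[str, float]:
        out = {k: getattr(self, k) for k in _VARS}
        out.update(dict(self.extras))
        return out


@dataclass
class FEDataset:
    """Retained design rows with their FE response targets.

    ``exclusions`` keeps the QC-dropped rows with a per-row reason;
    ``provenance`` records how the dataset was produced.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.df)

    def inputs(self, columns: Sequence[str] = _VARS[:5]) -> np.ndarray:
        return self.df.loc[:, list(columns)].to_numpy(float)

    def targets(self) -> np.ndarray:
        return self.df.loc[:, ["sigma_vm_max", "delta_max",
                               "sigma_screw_max"]].to_numpy(float)

    def to_csv(self, path) -> None:
        path = Path(path)
        out = self.df.copy()
        float_cols = out.columns.difference(["converged"])
        out[float_cols] = out[float_cols].astype(float)
        out.to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path) -> "FEDataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df=df, provenance=prov)


def full_factorial(levels: Mapping[str, Sequence[float]] | None = None
                   ) -> list[DesignPoint]:
    """Cartesian product of the per-variable levels, lexicographic order."""
    levels = dict(PAPER_LEVELS if levels is None else levels)
    for name, vals in levels.items():
        if len(vals) < 1:
            raise ValueError(f"variable '{name}' has no levels")
    base = {k: levels.pop(k) for k in _VARS if k in levels}
    if levels:
        raise ValueError(f"unknown factorial variables: {sorted(levels)}")
    grids = np.meshgrid(*[base[k] for k in _VARS if k in base], indexing="ij")
    names = [k for k in _VARS if k in base]
    flat = [g.ravel() for g in grids]
    defaults = {"d": 1.0, "a": 2.5, "t_lat": 3.5, "t_plate": 1.5, "P": 600.0}
    points = []
    for row in zip(*flat):
        kw = dict(defaults)
        kw.update(dict(zip(names, map(float, row))))
        points.append(DesignPoint(**kw))
    return points


def latin_hypercube(n: int, bounds: Mapping[str, tuple[float, float]],
                    seed: int) -> list[DesignPoint]:
    """Stratified LHS: each variable has one sample per of n equal strata.

    Variables beyond the five canonical ones are carried in
    ``DesignPoint.extras`` (e.g. screw-layout parameters).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], float)
    hi = np.array([bounds[k][1] for k in names], float)
    if np.any(hi <= lo):
        bad = names[int(np.argmax(hi <= lo))]
        raise ValueError(f"degenerate bounds for '{bad}'")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    vals = qmc.scale(unit, lo, hi)
    defaults = {"d": 1.0, "a": 2.5, "t_lat": 3.5, "t_plate": 1.5, "P": 600.0}
    points = []
    for row in vals:
        kw = dict(defaults)
        extras = []
        for name, v in zip(names, row):
            if name in _VARS:
                kw[name] = float(v)
            else:
                extras.append((name, float(v)))
        points.append(DesignPoint(**kw, extras=tuple(extras)))
    return points


def _solve_rows(points: Sequence[DesignPoint], template: ConstructSpec,
                law: PorosityLaw, cell: LatticeCell,
                bone_levels: Sequence[float]) -> pd.DataFrame:
    rows = []
    indexed = list(enumerate(points))
    by_geom: dict[tuple[float, float], list[tuple[int, DesignPoint]]] = {}
    for i, pt in indexed:
        by_geom.setdefault((pt.t_lat, pt.t_plate), []).append((i, pt))

    for (t_lat, t_plate), group in by_geom.items():
        spec = dataclasses.replace(template, t_lat=t_lat, t_plate=t_plate)
        mesh = build_construct_mesh(spec)
        base_map = construct_material_map(spec, law, cell=cell)
        nu_ti = base_map["plate"][1]
        K_ti = assemble_stiffness(mesh, base_map, regions=("plate", "screw"))
        K_lat1 = assemble_stiffness(mesh, {"lattice": (1.0, nu_ti)},
                                    regions=("lattice",))
        K_bone1 = assemble_stiffness(mesh, {"bone": (1.0, CORTICAL_BONE.nu)},
                                     regions=("bone",))
        solver = ReusableSolver(mesh)

        by_lattice: dict[tuple[float, float], list[tuple[int, DesignPoint]]] = {}
        for i, pt in group:
            by_lattice.setdefault((pt.d, pt.a), []).append((i, pt))
        for (d, a), sub in by_lattice.items():
            design = dataclasses.replace(spec, d=d, a=a)
            try:
                p = struts_to_porosity(d, a, cell)
            except InfeasibleStrutError as err:
                for i, pt in sub:
                    for s in bone_levels:
                        rows.append({"_ord": i, **pt.as_dict(), "bone_scale": s,
                                     "p": np.nan, "sigma_vm_max": np.nan,
                                     "delta_max": np.nan,
                                     "sigma_screw_max": np.nan,
                                     "converged": False,
                                     "feasible": False, "reason": str(err)})
                continue
            E_lat = effective_modulus(law, p) * 1e3
            for s in bone_levels:
                mat = construct_material_map(design, law, cell=cell,
                                             bone_scale=s)
                K = K_ti + E_lat * K_lat1 + (CORTICAL_BONE.E_mpa * s) * K_bone1
                ok = solver.factorize(K.tocsr())
                for i, pt in sub:
                    res = solver.solve(LoadCase(pt.P), mat) if ok else None
                    converged = bool(ok and res is not None and res.converged)
                    rows.append({"_ord": i, **pt.as_dict(), "bone_scale": s,
                                 "p": p,
                                 "sigma_vm_max": res.sigma_vm_max_plate if converged else np.nan,
                                 "delta_max": res.delta_max if converged else np.nan,
                                 "sigma_screw_max": res.sigma_screw_max if converged else np.nan,
                                 "converged": converged, "feasible": True,
                                 "reason": "" if converged else "non-converged"})
    df = pd.DataFrame(rows)
    df = df.sort_values(["bone_scale", "_ord"], kind="stable").drop(columns="_ord")
    return df.reset_index(drop=True)


def run_sweep(points: Sequence[DesignPoint], template: ConstructSpec,
              law: PorosityLaw, cell: LatticeCell = LatticeCell(),
              bone_levels: Sequence[float] = (1.0,),
              seed: int | None = None) -> FEDataset:
    """One FE solve per (point, bone level) on the converged mesh settings.

    Per-point solver failures are recorded as non-converged rows, not
    raised.  ``bone_levels`` multiplies the cortical-bone modulus (used
    to train the uncertainty-augmented surrogate); the canonical sweep
    uses the single level 1.0.
    """
    df = _solve_rows(points, template, law, cell, bone_levels)
    if list(bone_levels) == [1.0]:
        df = df.drop(columns="bone_scale")
    prov = {"generator": "run_sweep", "seed": seed,
            "n_points": len(points), "bone_levels": list(bone_levels),
            "mesh_divisions": list(template.mesh_divisions),
            "band_divisions": list(template.band_divisions or []),
            "porosity_law": {"C": law.C, "n": law.n, "E_solid": law.E_solid},
            "code_version": _code_version}
    return FEDataset(df=df, provenance=prov)


def qc_filter(dataset: FEDataset | pd.DataFrame) -> FEDataset:
    """Drop non-converged and geometrically infeasible rows.

    Exclusion reasons are recorded per dropped row in ``exclusions``.
    """
    if isinstance(dataset, FEDataset):
        df, prov = dataset.df, dict(dataset.provenance)
    else:
        df, prov = dataset, {}
    feasible = df["feasible"] if "feasible" in df else pd.Series(True, index=df.index)
    converged = df["converged"].astype(bool)
    keep = feasible.astype(bool) & converged
    dropped = df.loc[~keep].copy()
    if "reason" not in dropped:
        dropped["reason"] = np.where(~feasible[~keep], "infeasible", "non-converged")
    else:
        dropped.loc[~feasible[~keep].astype(bool), "reason"] = \
            dropped.loc[~feasible[~keep].astype(bool), "reason"].replace("", "infeasible")
    retained = df.loc[keep].drop(columns=[c for c in ("feasible", "reason")
                                          if c in df]).reset_index(drop=True)
    if retained[["sigma_vm_max", "delta_max", "sigma_screw_max"]].isna().any().any():
        raise ValueError("retained rows contain non-finite targets")
    prov.update({"qc_retained": int(keep.sum()), "qc_dropped": int((~keep).sum())})
    return FEDataset(df=retained, provenance=prov,
                     exclusions=dropped.reset_index(drop=True))
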
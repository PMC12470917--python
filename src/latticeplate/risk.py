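"""Monte-Carlo propagation of input scatter through the surrogate.

The uncertainty model is a factorised joint distribution over root
input nodes -- cortical-bone modulus scale (+/-20%), bite-force scale
(+/-30%) and build-porosity offset (+/-5 percentage points) -- whose
children are the three mechanical outputs; each output additionally
receives its zero-mean Gaussian surrogate residual.  Forward sampling
of the factorisation (the graph has no observed nodes to condition on)
yields exceedance probabilities against the allowable-stress,
0.9-sigma_y and 1 mm displacement limits, with binomial standard
errors.  These probabilities are the probabilistic design constraint of
the optimiser.

Bone-modulus scatter cannot flow through the five canonical surrogate
inputs, so risk propagation uses the augmented six-input surrogate
(bone-modulus multiplier appended); porosity scatter is folded into an
equivalent strut diameter through the lattice-cell density map, so the
perturbation travels through the net's own geometric inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .doe import DesignPoint
from .fem import LoadCase, solve_construct
from .geometry import ConstructSpec
from .materials import LatticeCell, PorosityLaw, struts_to_porosity
from .surrogate import ResidualModel

__all__ = ["UncertaintyNode", "UncertaintySpec", "Thresholds", "RiskReport",
           "sample_joint", "propagate", "exceedance_probability",
           "perturbed_inputs", "verify_against_fem"]


@dataclass(frozen=True)
class UncertaintyNode:
    """Root node of the factorised input-uncertainty graph.

    ``width`` is the +/- half-width x of the stated scatter: a
    ``uniform_scale`` node draws a multiplier on [1-x, 1+x]; a
    ``normal_scale`` node draws N(1, (x/1.96)^2) (x read as a 95%
    half-interval); ``uniform_offset`` / ``normal_offset`` draw an
    additive perturbation around 0.  Zero width collapses to a constant.
    """

    name: str
    family: str = "uniform_scale"
    width: float = 0.0
    parents: tuple[str, ...] = ()

    _FAMILIES = ("uniform_scale", "normal_scale", "uniform_offset",
                 "normal_offset")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown distribution family '{self.family}'")
        if self.width < 0:
            raise ValueError("scatter width must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        centre = 1.0 if self.family.endswith("scale") else 0.0
        if self.width == 0:
            return np.full(n, centre)
        if self.family.startswith("uniform"):
            return rng.uniform(centre - self.width, centre + self.width, n)
        return rng.normal(centre, self.width / 1.96, n)


def _default_nodes() -> tuple[UncertaintyNode, ...]:
    return (UncertaintyNode("bone_modulus_scale", "uniform_scale", 0.20),
            UncertaintyNode("bite_force_scale", "uniform_scale", 0.30),
            UncertaintyNode("porosity_offset", "uniform_offset", 0.05))


@dataclass(frozen=True)
class UncertaintySpec:
    """Input nodes plus the implicit output layer of the graph.

    Outputs (the three FE targets) have every input node as parent; the
    residual-noise node is realised by the surrogate's
    :class:`~latticeplate.surrogate.ResidualModel`.
    """

    nodes: tuple[UncertaintyNode, ...] = field(default_factory=_default_nodes)

    def node(self, name: str) -> UncertaintyNode:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(name)

    @property
    def output_parents(self) -> tuple[str, ...]:
        return tuple(nd.name for nd in self.nodes)


@dataclass(frozen=True)
class Thresholds:
    """Exceedance limits for the reliability check."""

    sigma_allow: float = 792.0  # MPa, default 0.9 * sigma_y
    sigma_y: float = 880.0  # MPa
    disp_limit: float = 1.0  # mm
    risk_cap: float = 0.03


@dataclass
class RiskReport:
    n_samples: int
    seed: int
    pr_stress_allow: float  # Pr(sigma_vm_max > sigma_allow)
    pr_yield90: float  # Pr(sigma_vm_max > 0.9 sigma_y)
    pr_disp: float  # Pr(delta_max > disp_limit)
    se_stress_allow: float
    se_yield90: float
    se_disp: float
    extrapolation_count: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def max_probability(self) -> float:
        return max(self.pr_stress_allow, self.pr_yield90, self.pr_disp)

    def as_dict(self) -> dict:
        return {"n_samples": self.n_samples, "seed": self.seed,
                "pr_stress_allow": self.pr_stress_allow,
                "pr_yield90": self.pr_yield90, "pr_disp": self.pr_disp,
                "se_stress_allow": self.se_stress_allow,
                "se_yield90": self.se_yield90, "se_disp": self.se_disp,
                "extrapolation_count": self.extrapolation_count,
                "thresholds": dataclasses.asdict(self.thresholds)}


def sample_joint(spec: UncertaintySpec, n: int, seed: int) -> pd.DataFrame:
    """n independent draws from the factorised joint of the root nodes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({nd.name: nd.sample(n, rng) for nd in spec.nodes})


def exceedance_probability(values: np.ndarray, threshold: float
                           ) -> tuple[float, float]:
    """Empirical Pr(value > threshold) with its binomial standard error."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("need at least one value")
    p = float(np.mean(values > threshold))
    se = float(np.sqrt(p * (1 - p) / values.size))
    return p, se


def perturbed_inputs(design: DesignPoint, samples: pd.DataFrame,
                     cell: LatticeCell = LatticeCell()) -> np.ndarray:
    """Surrogate input matrix [d_eff, a, t_lat, t_plate, P', bone_scale].

    The porosity offset is folded into an equivalent strut diameter by
    inverting the lattice-cell density map at the perturbed porosity, so
    porosity scatter travels through the net's own geometry inputs.
    """
    p_nom = struts_to_porosity(design.d, design.a, cell)
    p = np.clip(p_nom + samples["porosity_offset"].to_numpy(), 0.005, 0.995)
    d_eff = design.a * np.sqrt((1.0 - p) / cell.density_coefficient)
    n = len(samples)
    return np.column_stack([
        d_eff, np.full(n, design.a), np.full(n, design.t_lat),
        np.full(n, design.t_plate),
        design.P * samples["bite_force_scale"].to_numpy(),
        samples["bone_modulus_scale"].to_numpy()])


def propagate(design: DesignPoint, samples: pd.DataFrame, net,
              residual: ResidualModel, thresholds: Thresholds = Thresholds(),
              seed: int = 0, cell: LatticeCell = LatticeCell(),
              training_hull: np.ndarray | None = None) -> RiskReport:
    """Push the sampled scatter through the surrogate and count exceedances.

    Per sample: perturb the inputs, predict the three outputs with the
    augmented net, add Gaussian residual noise, compare to the limits.
    ``training_hull`` (2, n_inputs) lo/hi rows enables the
    out-of-hull extrapolation counter.
    """
    X = perturbed_inputs(design, samples, cell)
    rng = np.random.default_rng(seed)
    pred = np.asarray(net.predict(X), float) + residual.sample(len(X), rng)
    sigma, delta = pred[:, 0], pred[:, 1]
    p_sa, se_sa = exceedance_probability(sigma, thresholds.sigma_allow)
    p_y, se_y = exceedance_probability(sigma, 0.9 * thresholds.sigma_y)
    p_d, se_d = exceedance_probability(delta, thresholds.disp_limit)
    extrap = 0
    if training_hull is not None:
        lo, hi = training_hull
        extrap = int(np.sum(np.any((X < lo) | (X > hi), axis=1)))
    return RiskReport(n_samples=len(X), seed=seed,
                      pr_stress_allow=p_sa, pr_yield90=p_y, pr_disp=p_d,
                      se_stress_allow=se_sa, se_yield90=se_y, se_disp=se_d,
                      extrapolation_count=extrap, thresholds=thresholds)


def verify_against_fem(design: DesignPoint, k: int, samples: pd.DataFrame,
                       template: ConstructSpec, law: PorosityLaw, net,
                       cell: LatticeCell = LatticeCell()) -> pd.DataFrame:
    """Re-run the FE chain at k sampled perturbations; report the
    per-output relative discrepancy |surrogate - FEM| / FEM.

    Desk-scale spot check of surrogate fidelity inside the scattered
    input region; ``k = 0`` returns an empty report.
    """
    rows = []
    sub = samples.iloc[:k]
    X = perturbed_inputs(design, sub, cell) if k else None
    for i in range(len(sub)):
        s = sub.iloc[i]
        spec = dataclasses.replace(template, d=float(X[i, 0]), a=design.a,
                                   t_lat=design.t_lat, t_plate=design.t_plate)
        res = solve_construct(spec, law, LoadCase(float(X[i, 4])), cell=cell,
                              bone_scale=float(s["bone_modulus_scale"]))
        fem_out = np.array([res.sigma_vm_max_plate, res.delta_max,
                            res.sigma_screw_max])
        sur_out = np.asarray(net.predict(X[i]), float)
        rows.append({"sample": i,
                     **{f"rel_err_{name}": abs(sur_out[j] - fem_out[j]) / fem_out[j]
                        for j, name in enumerate(("sigma_vm_max", "delta_max",
                                                  "sigma_screw_max"))}})
    return pd.DataFrame(rows)
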
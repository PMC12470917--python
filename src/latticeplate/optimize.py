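"""Risk-constrained multi-objective genetic search over the design space.

Objectives: minimise implant mass, minimise peak plate von Mises
stress, maximise the fatigue margin 340 MPa / sigma_vM_max (340 MPa is
the endurance limit of hot-isostatically-pressed laser-powder-bed
Ti-6Al-4V).  The Monte-Carlo exceedance probability acts as a
probabilistic constraint: candidates whose risk exceeds the cap
(default 3%) are handled by constraint domination, so the returned
archive is both non-dominated and risk-feasible.

The GA is an NSGA-II-style loop -- binary tournament on
(constraint-dominated rank, crowding distance), simulated binary
crossover, polynomial mutation -- small enough to implement directly
and kept bit-reproducible under a fixed seed.  A brute-force pairwise
Pareto extractor doubles as the test oracle.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .doe import DesignPoint
from .fem import LoadCase, solve_construct
from .geometry import ConstructSpec, build_construct_mesh, region_volumes
from .materials import (TI6AL4V, LatticeCell, MaterialCard, PorosityLaw,
                        struts_to_porosity)

__all__ = ["FATIGUE_LIMIT_MPA", "ObjectiveVector", "GAConfig", "ParetoSet",
           "DEFAULT_BOUNDS", "implant_mass", "construct_effective_modulus",
           "objectives", "surrogate_evaluator", "fem_evaluator", "dominates",
           "pareto_front_bruteforce", "run_ga", "efficiency_index",
           "trend_regression"]

#: Fatigue endurance limit of HIPped L-PBF Ti-6Al-4V, MPa.
FATIGUE_LIMIT_MPA = 340.0

#: Continuous hull of the printed factorial levels; load fixed at the
#: 600 N worst case during optimisation.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "d": (0.40, 1.15), "a": (2.0, 4.0), "t_lat": (1.5, 4.5),
    "t_plate": (1.0, 1.5)}


@dataclass(frozen=True)
class ObjectiveVector:
    mass: float  # g, minimise
    sigma_vm_max: float  # MPa, minimise
    fatigue_margin: float  # = 340 / sigma_vm_max, maximise

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        if not self.fatigue_margin > 0:
            raise ValueError("fatigue margin must be positive")

    def minimised(self) -> np.ndarray:
        """Sign-normalised array where every entry is to be minimised."""
        return np.array([self.mass, self.sigma_vm_max, -self.fatigue_margin])


@dataclass(frozen=True)
class GAConfig:
    population: int = 48
    generations: int = 40
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1 / n_variables
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    seed: int = 0
    risk_threshold: float = 0.03

    def __post_init__(self) -> None:
        if self.population < 4 or self.population % 2:
            raise ValueError("population must be even and >= 4")
        for p in (self.crossover_prob, self.mutation_prob):
            if p is not None and not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class ParetoSet:
    """Risk-feasible non-dominated archive with its generation log."""

    entries: list[dict]  # each: design, objectives, risk
    generation_log: pd.DataFrame
    status: str = "ok"

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            d: DesignPoint = e["design"]
            o: ObjectiveVector = e["objectives"]
            rows.append({"d": d.d, "a": d.a, "t_lat": d.t_lat,
                         "t_plate": d.t_plate, "P": d.P,
                         "mass_g": o.mass, "sigma_vm_max": o.sigma_vm_max,
                         "fatigue_margin": o.fatigue_margin,
                         "risk": e["risk"]})
        return pd.DataFrame(rows)


def implant_mass(design: DesignPoint, template: ConstructSpec,
                 cell: LatticeCell = LatticeCell(),
                 ti: MaterialCard = TI6AL4V,
                 porosity: float | None = None) -> float:
    """Implant mass (g): plate + screws + lattice scaled by (1 - p).

    Region volumes come from the meshed construct; ``porosity=0.0``
    gives the solid-plate baseline of the same envelope.
    """
    spec = dataclasses.replace(template, d=design.d, a=design.a,
                               t_lat=design.t_lat, t_plate=design.t_plate)
    vols = region_volumes(build_construct_mesh(spec))
    p = struts_to_porosity(design.d, design.a, cell) if porosity is None \
        else porosity
    v_ti = vols["plate"] + vols["screw"] + vols["lattice"] * (1.0 - p)
    return v_ti * ti.rho / 1000.0  # mm^3 * g/cm^3 -> g


def construct_effective_modulus(delta_max: float, P: float,
                                template: ConstructSpec) -> float:
    """Uniaxial-equivalent construct stiffness (GPa) from load-point
    compliance: E = (P * span) / (W * H * delta).

    A proxy that maps the construct's global compliance onto the scale
    of a material modulus so it can be compared with cortical bone for
    stiffness matching.
    """
    A = template.section_width * template.section_height
    return P * template.defect_span / (A * delta_max) / 1e3


def surrogate_evaluator(net) -> Callable[[DesignPoint], np.ndarray]:
    """Evaluator mapping a design to (sigma, delta, sigma_screw) via the
    five-input surrogate."""
    def _eval(design: DesignPoint) -> np.ndarray:
        x = np.array([design.d, design.a, design.t_lat, design.t_plate,
                      design.P])
        return np.asarray(net.predict(x), float)
    return _eval


def fem_evaluator(template: ConstructSpec, law: PorosityLaw,
                  cell: LatticeCell = LatticeCell()
                  ) -> Callable[[DesignPoint], np.ndarray]:
    """Evaluator running the full FE chain (slow; verification use)."""
    def _eval(design: DesignPoint) -> np.ndarray:
        spec = dataclasses.replace(template, d=design.d, a=design.a,
                                   t_lat=design.t_lat, t_plate=design.t_plate)
        res = solve_construct(spec, law, LoadCase(design.P), cell=cell)
        return np.array([res.sigma_vm_max_plate, res.delta_max,
                         res.sigma_screw_max])
    return _eval


def objectives(design: DesignPoint, evaluator: Callable[[DesignPoint], np.ndarray],
               template: ConstructSpec, cell: LatticeCell = LatticeCell(),
               ti: MaterialCard = TI6AL4V) -> ObjectiveVector:
    sigma = float(evaluator(design)[0])
    return ObjectiveVector(mass=implant_mass(design, template, cell, ti),
                           sigma_vm_max=sigma,
                           fatigue_margin=FATIGUE_LIMIT_MPA / sigma)


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """Pareto dominance: a no worse everywhere, strictly better somewhere."""
    av, bv = a.minimised(), b.minimised()
    return bool(np.all(av <= bv) and np.any(av < bv))


def pareto_front_bruteforce(entries: Sequence[ObjectiveVector]) -> list[int]:
    """Exact non-dominated indices by pairwise comparison (test oracle)."""
    keep = []
    for i, a in enumerate(entries):
        if not any(dominates(b, a) for j, b in enumerate(entries) if j != i):
            keep.append(i)
    return keep


# -- NSGA-II machinery ----------------------------------------------------


def _constrained_dominates(oa, ca, ob, cb) -> bool:
    """Deb constraint domination: feasible beats infeasible; two
    infeasible compare by violation; two feasible by Pareto dominance."""
    if ca == 0 and cb > 0:
        return True
    if ca > 0 and cb > 0:
        return ca < cb
    if ca > 0:
        return False
    return bool(np.all(oa <= ob) and np.any(oa < ob))


def _nd_sort(objs: np.ndarray, cons: np.ndarray) -> list[np.ndarray]:
    n = len(objs)
    S = [[] for _ in range(n)]
    counts = np.zeros(n, int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if _constrained_dominates(objs[i], cons[i], objs[j], cons[j]):
                S[i].append(j)
            elif _constrained_dominates(objs[j], cons[j], objs[i], cons[i]):
                counts[i] += 1
    fronts = []
    current = np.flatnonzero(counts == 0)
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in S[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), int)
    return fronts


def _crowding(objs: np.ndarray) -> np.ndarray:
    n, k = objs.shape
    dist = np.zeros(n)
    for m in range(k):
        order = np.argsort(objs[:, m], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = objs[order[-1], m] - objs[order[0], m]
        if span > 0 and n > 2:
            dist[order[1:-1]] += (objs[order[2:], m] -
                                  objs[order[:-2], m]) / span
    return dist


def _sbx(p1, p2, lo, hi, eta, prob, rng):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() < prob:
        for i in range(len(p1)):
            if rng.random() < 0.5 and abs(p1[i] - p2[i]) > 1e-12:
                u = rng.random()
                beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1))
                c1[i] = 0.5 * ((1 + beta) * p1[i] + (1 - beta) * p2[i])
                c2[i] = 0.5 * ((1 - beta) * p1[i] + (1 + beta) * p2[i])
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(x, lo, hi, eta, prob, rng):
    y = x.copy()
    for i in range(len(x)):
        if rng.random() < prob:
            u = rng.random()
            delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 else \
                1 - (2 * (1 - u)) ** (1 / (eta + 1))
            y[i] = np.clip(x[i] + delta * (hi[i] - lo[i]), lo[i], hi[i])
    return y


def run_ga(config: GAConfig,
           bounds: Mapping[str, tuple[float, float]] | None,
           evaluate_fn: Callable[[DesignPoint], ObjectiveVector],
           risk_fn: Callable[[DesignPoint], float],
           P: float = 600.0,
           cell: LatticeCell = LatticeCell()) -> ParetoSet:
    """Search the continuous design hull for risk-feasible Pareto designs.

    ``risk_fn`` returns the candidate's maximum exceedance probability;
    candidates above ``config.risk_threshold`` (and geometrically
    infeasible strut ratios) are pushed behind every feasible candidate
    by constraint domination.  The returned archive is the non-dominated
    subset of every feasible candidate evaluated across the whole run,
    so a larger generation budget can only grow its quality.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    rng = np.random.default_rng(config.seed)
    mut_prob = config.mutation_prob if config.mutation_prob is not None \
        else 1.0 / len(names)

    cache: dict[tuple, tuple] = {}

    def make_design(x: np.ndarray) -> DesignPoint:
        kw = {"d": 1.0, "a": 2.5, "t_lat": 3.5, "t_plate": 1.5, "P": P}
        kw.update(zip(names, map(float, x)))
        return DesignPoint(**kw)

    def evaluate(x: np.ndarray) -> tuple:
        key = tuple(np.round(x, 12))
        if key in cache:
            return cache[key]
        design = make_design(x)
        ratio = design.d / design.a
        if ratio > cell.feasibility_cap:
            # large finite penalty keeps crowding distances well-defined
            out = (np.full(3, 1e12), ratio - cell.feasibility_cap, None, None)
        else:
            obj = evaluate_fn(design)
            risk = float(risk_fn(design))
            violation = max(0.0, risk - config.risk_threshold)
            out = (obj.minimised(), violation, obj, risk)
        cache[key] = out
        return out

    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    pop = qmc.scale(sampler.random(config.population), lo, hi)
    evals = [evaluate(x) for x in pop]

    archive: dict[tuple, dict] = {}

    def archive_add(x, ev):
        objs_min, cv, obj, risk = ev
        if cv == 0 and obj is not None:
            archive[tuple(np.round(x, 12))] = {
                "design": make_design(x), "objectives": obj, "risk": risk}

    for x, ev in zip(pop, evals):
        archive_add(x, ev)

    log = []
    for gen in range(config.generations):
        objs = np.array([e[0] for e in evals])
        cons = np.array([e[1] for e in evals])
        fronts = _nd_sort(objs, cons)
        rank = np.empty(len(pop), int)
        crowd = np.empty(len(pop))
        for r, fr in enumerate(fronts):
            rank[fr] = r
            crowd[fr] = _crowding(objs[fr])

        def tournament():
            i, j = rng.integers(0, len(pop), 2)
            if rank[i] != rank[j]:
                return pop[i] if rank[i] < rank[j] else pop[j]
            return pop[i] if crowd[i] >= crowd[j] else pop[j]

        children = []
        while len(children) < config.population:
            c1, c2 = _sbx(tournament(), tournament(), lo, hi,
                          config.eta_crossover, config.crossover_prob, rng)
            children.append(_poly_mutation(c1, lo, hi, config.eta_mutation,
                                           mut_prob, rng))
            children.append(_poly_mutation(c2, lo, hi, config.eta_mutation,
                                           mut_prob, rng))
        children = np.array(children[:config.population])
        child_evals = [evaluate(x) for x in children]
        for x, ev in zip(children, child_evals):
            archive_add(x, ev)

        allpop = np.vstack([pop, children])
        allev = evals + child_evals
        objs = np.array([e[0] for e in allev])
        cons = np.array([e[1] for e in allev])
        fronts = _nd_sort(objs, cons)
        sel = []
        for fr in fronts:
            if len(sel) + len(fr) <= config.population:
                sel.extend(fr.tolist())
            else:
                cd = _crowding(objs[fr])
                order = fr[np.argsort(-cd, kind="stable")]
                sel.extend(order[:config.population - len(sel)].tolist())
                break
        pop = allpop[sel]
        evals = [allev[i] for i in sel]
        n_feasible = int(sum(1 for e in evals if e[1] == 0))
        log.append({"generation": gen, "n_feasible": n_feasible,
                    "archive_size": len(archive)})

    entries = list(archive.values())
    keep = pareto_front_bruteforce([e["objectives"] for e in entries])
    entries = [entries[i] for i in keep]
    status = "ok" if entries else "no feasible design"
    return ParetoSet(entries=entries, generation_log=pd.DataFrame(log),
                     status=status)


def efficiency_index(df: pd.DataFrame, weights: tuple[float, float] = (0.5, 0.5),
                     bone_modulus: float = 13.0,
                     baseline_mass: float | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Joint normalised gain in mass saving and bone-stiffness matching.

    ``df`` needs columns ``mass_g``, ``E_construct`` (GPa) and ``p``.
    Per design: score = w_mass * minmax(mass saving vs the solid-plate
    baseline) + w_stiff * minmax(-|E_construct - E_bone|); min-max
    normalisation over the evaluated set, so the best design scores
    exactly 1 and the worst 0.  Returns the scores and a porosity-decade
    binned mean-score table.
    """
    if len(df) < 2:
        raise ValueError("need at least 2 designs to normalise")
    w_mass, w_stiff = weights
    base = baseline_mass if baseline_mass is not None else df["mass_g"].max()
    saving = base - df["mass_g"].to_numpy(float)
    match = -np.abs(df["E_construct"].to_numpy(float) - bone_modulus)

    def minmax(v):
        span = v.max() - v.min()
        if span == 0:
            warnings.warn("degenerate normalisation range; scores set to 0.5",
                          stacklevel=2)
            return np.full(len(v), 0.5)
        return (v - v.min()) / span

    scores = w_mass * minmax(saving) + w_stiff * minmax(match)
    scores = minmax(scores) if scores.max() > scores.min() else scores
    bins = np.arange(0.0, 1.01, 0.10)
    binned = pd.DataFrame({
        "porosity_bin": pd.cut(df["p"].to_numpy(float), bins, right=False),
        "score": scores}).groupby("porosity_bin", observed=True)["score"] \
        .mean().reset_index()
    return scores, binned


def trend_regression(x: np.ndarray, y: np.ndarray
                     ) -> tuple[float, float, float, float]:
    """OLS line fit: (slope, intercept, R^2, two-tailed p of the slope)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))
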
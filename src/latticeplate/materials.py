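"""Material constants and the porosity -> effective-stiffness calibration.

Dense-alloy and cortical-bone property cards, plus the Gibson--Ashby
power law ``E_eff = C * E_s * (1 - p)**n`` that homogenises an open-cell
lattice into a continuum modulus.  The law is calibrated against coupon
measurements of (porosity, effective modulus) by least squares in log
space, where the power law is a straight line.

Units: moduli are GPa at this API boundary (the FE layer converts to MPa
internally), strengths MPa, densities g/cm^3, lengths mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MaterialCard",
    "CalibrationPoint",
    "PorosityLaw",
    "LatticeCell",
    "TI6AL4V",
    "CORTICAL_BONE",
    "LATTICE_COUPONS",
    "InfeasibleStrutError",
    "calibrate_porosity_law",
    "default_porosity_law",
    "effective_modulus",
    "struts_to_porosity",
    "elastic_strain_at_reference",
    "read_calibration_csv",
    "write_calibration_csv",
]


class CalibrationError(ValueError):
    """Raised when a porosity-law calibration is ill-posed."""


class InfeasibleStrutError(ValueError):
    """Strut diameter / cell size ratio above the manufacturability cap.

    Carries the offending ratio so DOE quality control can log it.
    """

    def __init__(self, d: float, a: float, cap: float):
        self.ratio = d / a
        self.cap = cap
        super().__init__(
            f"d/a = {self.ratio:.3f} exceeds the feasibility cap {cap:.3f} "
            "(struts would merge)"
        )


@dataclass(frozen=True)
class MaterialCard:
    """Isotropic linear-elastic material with static strength values."""

    name: str
    E: float  # Young's modulus, GPa
    nu: float  # Poisson ratio
    rho: float  # density, g/cm^3
    sigma_y: float  # 0.2% proof strength, MPa
    sigma_u: float  # ultimate tensile strength, MPa

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"nu must lie in (0, 0.5), got {self.nu}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not 0 < self.sigma_y <= self.sigma_u:
            raise ValueError(
                f"need 0 < sigma_y <= sigma_u, got {self.sigma_y}, {self.sigma_u}"
            )

    @property
    def E_mpa(self) -> float:
        return self.E * 1e3


#: Hot isostatically pressed Ti-6Al-4V (ELI) static properties.
TI6AL4V = MaterialCard("Ti-6Al-4V (ELI)", E=110.0, nu=0.33, rho=4.43,
                       sigma_y=880.0, sigma_u=950.0)

#: Cortical bone: stiffness per the FE setup; strengths are nominal
#: textbook values (used only to satisfy the card contract, never as limits).
CORTICAL_BONE = MaterialCard("cortical bone", E=13.0, nu=0.30, rho=1.85,
                             sigma_y=115.0, sigma_u=130.0)


@dataclass(frozen=True)
class CalibrationPoint:
    porosity: float  # void fraction in [0, 1)
    E_eff: float  # effective Young's modulus, GPa

    def __post_init__(self) -> None:
        if not 0 <= self.porosity < 1:
            raise ValueError(f"porosity must lie in [0, 1), got {self.porosity}")
        if not self.E_eff > 0:
            raise ValueError(f"E_eff must be positive, got {self.E_eff}")


#: Effective moduli of four mechanically tested lattice coupons.
LATTICE_COUPONS = (
    CalibrationPoint(0.371, 35.0),
    CalibrationPoint(0.300, 43.0),
    CalibrationPoint(0.164, 65.0),
    CalibrationPoint(0.041, 89.0),
)


@dataclass(frozen=True)
class LatticeCell:
    """Strut-lattice unit cell reduced to a relative-density map.

    ``rho_rel = density_coefficient * (d/a)**2`` is the standard
    small-(d/a) scaling of strut lattices; the default coefficient
    3*pi/4 corresponds to a simple-cubic strut cell.  Other topologies
    are swapped in by changing the coefficient.
    """

    topology: str = "simple-cubic-strut"
    density_coefficient: float = 3.0 * math.pi / 4.0
    feasibility_cap: float = 0.5  # max d/a before struts merge

    def relative_density(self, d: float, a: float) -> float:
        return min(1.0, self.density_coefficient * (d / a) ** 2)


@dataclass(frozen=True)
class PorosityLaw:
    """Calibrated power-law map from porosity to effective modulus (GPa)."""

    E_solid: float
    C: float
    n: float
    calibration: tuple[CalibrationPoint, ...] = ()
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.n >= 1:
            raise CalibrationError(
                f"exponent n = {self.n:.3f} < 1: data are inconsistent with an "
                "open-cell stiffness law"
            )

    def __call__(self, p: float) -> float:
        return effective_modulus(self, p)


def calibrate_porosity_law(points: Iterable[CalibrationPoint] | Iterable[tuple],
                           E_solid: float) -> PorosityLaw:
    """Fit ``E_eff = C * E_solid * (1-p)**n`` by log-space least squares.

    Minimises the squared error of ``log(E_eff/E_solid)`` against
    ``n*log(1-p) + log(C)``; ``fit_r2`` is reported on that log scale.
    ``C`` is left unconstrained (not forced through (0, E_solid)); the
    prediction is clipped at ``E_solid``.
    """
    pts = tuple(p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p)
                for p in points)
    if len(pts) < 2:
        raise CalibrationError("need at least 2 calibration points")
    poro = np.array([p.porosity for p in pts])
    if len(np.unique(poro)) != len(poro):
        raise CalibrationError("calibration porosities must be distinct")
    E = np.array([p.E_eff for p in pts])
    if np.any(E > E_solid):
        raise ValueError("calibration E_eff exceeds the solid modulus")

    x = np.log1p(-poro)
    y = np.log(E / E_solid)
    n, logC = np.polyfit(x, y, 1)
    yhat = n * x + logC
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PorosityLaw(E_solid=float(E_solid), C=float(np.exp(logC)),
                       n=float(n), calibration=pts, fit_r2=r2)


def default_porosity_law() -> PorosityLaw:
    """Law calibrated on the built-in coupon table with the dense-alloy modulus."""
    return calibrate_porosity_law(LATTICE_COUPONS, TI6AL4V.E)


def effective_modulus(law: PorosityLaw, p: float) -> float:
    """Effective modulus (GPa) at porosity ``p``; clipped at ``E_solid``."""
    if not 0 <= p < 1:
        raise ValueError(f"porosity must lie in [0, 1), got {p}")
    return min(law.E_solid, law.C * law.E_solid * (1.0 - p) ** law.n)


def struts_to_porosity(d: float, a: float,
                       cell: LatticeCell = LatticeCell()) -> float:
    """Porosity of a strut lattice with diameter ``d`` and cell size ``a`` (mm).

    Raises :class:`InfeasibleStrutError` above the d/a cap; DOE quality
    control consumes that as an infeasibility flag.
    """
    if d <= 0 or a <= 0:
        raise ValueError("d and a must be positive")
    if d / a > cell.feasibility_cap:
        raise InfeasibleStrutError(d, a, cell.feasibility_cap)
    return 1.0 - cell.relative_density(d, a)


def elastic_strain_at_reference(law: PorosityLaw, p: float,
                                sigma_ref: float = 50.0) -> float:
    """Macroscopic elastic strain (%) under a reference stress (MPa)."""
    if sigma_ref < 0:
        raise ValueError("reference stress must be non-negative")
    E_mpa = effective_modulus(law, p) * 1e3
    return 100.0 * sigma_ref / E_mpa


def read_calibration_csv(path) -> tuple[CalibrationPoint, ...]:
    df = pd.read_csv(path)
    expected = ["porosity", "E_eff_GPa"]
    if list(df.columns) != expected:
        raise ValueError(f"calibration CSV must have columns {expected}, "
                         f"got {list(df.columns)}")
    return tuple(CalibrationPoint(float(r.porosity), float(r.E_eff_GPa))
                 for r in df.itertuples())


def write_calibration_csv(points: Sequence[CalibrationPoint], path) -> None:
    pd.DataFrame({"porosity": [p.porosity for p in points],
                  "E_eff_GPa": [p.E_eff for p in points]}).to_csv(path, index=False)
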
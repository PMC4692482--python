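"""Forward models of equilibrium sedimentation.

At sedimentation equilibrium the radial absorbance profile of an ideal
species of molar mass M is exponential in r^2.  With the reduced buoyancy
factor

    A_p = (1 - vbar * rho) * omega^2 / (2 R T)      [mol g^-1 cm^-2, CGS]

the homogeneous n-mer model reads

    C(r) = Cb * exp[A_p * (n Mp) * (r^2 - rb^2)] + eps,

and the reversible monomer/n-mer model, with the association constant k on
the absorbance concentration scale,

    C(r) = Cb * exp[A_p Mp (r^2 - rb^2)]
         + Cb^n * exp[ln k + n A_p Mp (r^2 - rb^2)] + eps.

Both are referenced to the cell bottom rb, so the first exponential equals
Cb there.  Units are CGS throughout (R = 8.31446e7 erg mol^-1 K^-1, radii in
cm, masses in g/mol), which makes the exponent dimensionless with no hidden
conversion factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._tables import R_GAS_CGS

__all__ = [
    "RotorCondition",
    "BuoyancyContext",
    "HomogeneousModel",
    "ReversibleModel",
    "RadialScan",
    "reduced_buoyancy",
    "predict_homogeneous",
    "predict_reversible",
]

_EXP_CLIP = 700.0  # overflow guard for exp()


@dataclass(frozen=True)
class RotorCondition:
    """Rotor speed, temperature and radial window of one equilibrium run."""

    speed_rpm: float
    temperature_K: float
    meniscus_cm: float
    bottom_cm: float

    def __post_init__(self) -> None:
        if self.speed_rpm < 0:
            raise ValueError("rotor speed must be >= 0 rpm")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if not self.meniscus_cm < self.bottom_cm:
            raise ValueError("meniscus radius must be smaller than cell-bottom radius")

    @property
    def omega(self) -> float:
        """Angular velocity in rad/s."""
        return self.speed_rpm * 2.0 * math.pi / 60.0


@dataclass(frozen=True)
class BuoyancyContext:
    """Partial specific volume (cm^3/g) and solvent density (g/cm^3)."""

    vbar: float
    density: float

    def __post_init__(self) -> None:
        if not 0.0 < self.vbar * self.density < 2.0:
            raise ValueError("vbar * rho outside the physically sensible range (0, 2)")


@dataclass(frozen=True)
class HomogeneousModel:
    """Single ideal species of mass n * monomer_mass (absorbance units)."""

    monomer_mass: float
    n: int = 1
    bottom_conc: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError("monomer mass must be positive")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("stoichiometry n must be an integer >= 1")
        if self.bottom_conc < 0:
            raise ValueError("bottom concentration must be >= 0")


@dataclass(frozen=True)
class ReversibleModel:
    """Reversible monomer/n-mer equilibrium on the absorbance scale."""

    monomer_mass: float
    n: int
    bottom_conc: float = 0.0
    ln_k: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError("monomer mass must be positive")
        if self.n not in (2, 3):
            raise ValueError("reversible models support n in {2, 3}")
        if self.bottom_conc < 0:
            raise ValueError("monomer bottom concentration must be >= 0")


@dataclass(frozen=True)
class RadialScan:
    """One absorbance-versus-radius trace with its rotor/cell context."""

    radii_cm: np.ndarray
    absorbance: np.ndarray
    rotor: RotorCondition
    wavelength_nm: float = 280.0
    loading_uM: float | None = None
    sector: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_cm, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if r.ndim != 1 or r.shape != a.shape:
            raise ValueError("radii and absorbance must be equal-length 1-D sequences")
        if r.size and not np.all(np.diff(r) > 0):
            raise ValueError("radii must be strictly increasing")
        if r.size and (r[0] < self.rotor.meniscus_cm - 1e-9
                       or r[-1] > self.rotor.bottom_cm + 1e-9):
            raise ValueError("radii must lie within [meniscus, bottom]")
        object.__setattr__(self, "radii_cm", r)
        object.__setattr__(self, "absorbance", a)

    @property
    def n_points(self) -> int:
        return self.radii_cm.size


def reduced_buoyancy(ctx: BuoyancyContext, cond: RotorCondition) -> float:
    """Reduced buoyancy factor A_p = (1 - vbar rho) omega^2 / (2 R T).

    Returned in mol g^-1 cm^-2 so that A_p * M * (r^2 - rb^2) is
    dimensionless for M in g/mol and r in cm.
    """
    if cond.temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return (1.0 - ctx.vbar * ctx.density) * cond.omega**2 / (2.0 * R_GAS_CGS * cond.temperature_K)


def _safe_exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def predict_homogeneous(model: HomogeneousModel, ap: float,
                        radii_cm: Sequence[float], bottom_cm: float) -> np.ndarray:
    """Absorbance profile of the homogeneous n-mer model at the given radii."""
    r = np.asarray(radii_cm, dtype=float)
    x = ap * (model.n * model.monomer_mass) * (r**2 - bottom_cm**2)
    return model.bottom_conc * _safe_exp(x) + model.baseline


def predict_reversible(model: ReversibleModel, ap: float,
                       radii_cm: Sequence[float], bottom_cm: float) -> np.ndarray:
    """Absorbance profile of the reversible monomer/n-mer model."""
    r = np.asarray(radii_cm, dtype=float)
    x = ap * model.monomer_mass * (r**2 - bottom_cm**2)
    monomer = model.bottom_conc * _safe_exp(x)
    if model.bottom_conc > 0:
        nmer = _safe_exp(model.n * math.log(model.bottom_conc) + model.ln_k + model.n * x)
    else:
        nmer = np.zeros_like(r)
    return monomer + nmer + model.baseline
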
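"""Buffer density from component molarities and temperature.

The buoyancy term (1 - vbar * rho) of a sedimentation-equilibrium analysis
needs the solvent density.  For dilute aqueous buffers the density is, to
excellent accuracy, the density of pure water at the run temperature plus a
linear increment per solute,

    rho = rho_w(T) + sum_i c_i * (M_i - rho_w(T) * phi_i) / 1000,

where c_i is the formal molarity, M_i the molar mass (g/mol) and phi_i the
dilute-limit apparent molal volume (cm^3/mol) of component i.  Water density
follows the Kell (1975) polynomial.  Buffer salts are treated at their stated
formal molarity without pH speciation, which matches common sedimentation
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._tables import SOLUTE_COMPONENTS, SOLUTION_TEMP_RANGE_K

__all__ = ["SolutionRecipe", "water_density", "buffer_density"]


def water_density(temperature_K: float) -> float:
    """Density of air-free pure water in g/cm^3 (Kell 1975 polynomial)."""
    lo, hi = SOLUTION_TEMP_RANGE_K
    if not lo <= temperature_K <= hi:
        raise ValueError(f"temperature {temperature_K} K outside table range {lo}-{hi} K")
    t = temperature_K - 273.15
    num = (999.83952 + 16.945176 * t - 7.9870401e-3 * t**2
           - 46.170461e-6 * t**3 + 105.56302e-9 * t**4 - 280.54253e-12 * t**5)
    return num / (1.0 + 16.879850e-3 * t) / 1000.0


@dataclass(frozen=True)
class SolutionRecipe:
    """Buffer composition: (component, molarity) pairs at a temperature.

    Components must appear in the embedded increment table; pH is carried
    for bookkeeping only and does not enter the density.
    """

    components: Sequence[tuple[str, float]]
    temperature_K: float = 293.15
    pH: float | None = None

    def __post_init__(self) -> None:
        lo, hi = SOLUTION_TEMP_RANGE_K
        if not lo <= self.temperature_K <= hi:
            raise ValueError(f"temperature {self.temperature_K} K outside {lo}-{hi} K")
        clean = []
        for name, conc in self.components:
            if name not in SOLUTE_COMPONENTS:
                known = ", ".join(sorted(SOLUTE_COMPONENTS))
                raise ValueError(f"unknown buffer component {name!r} (known: {known})")
            if conc < 0:
                raise ValueError(f"negative concentration for {name}")
            clean.append((name, float(conc)))
        object.__setattr__(self, "components", tuple(clean))


def buffer_density(recipe: SolutionRecipe) -> float:
    """Solution density in g/cm^3 at the recipe temperature."""
    rho_w = water_density(recipe.temperature_K)
    rho = rho_w
    for name, conc in recipe.components:
        molar_mass, phi_v = SOLUTE_COMPONENTS[name]
        rho += conc * (molar_mass - rho_w * phi_v) / 1000.0
    return rho
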
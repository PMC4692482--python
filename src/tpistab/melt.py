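"""Two-state thermal-denaturation fitting of CD melt traces.

A melt followed at a single wavelength (theta at 222 nm for helical
proteins) is modelled as a two-state equilibrium N <-> U with a van't Hoff
temperature dependence and linear pre-/post-transition baselines:

    f(T)      = 1 / (1 + exp[-(dHvH / R) (1/T - 1/Td)])        (T in K)
    signal(T) = (b_f + m_f T) f(T) + (b_u + m_u T) (1 - f(T))

f is the folded fraction, Td the half-denaturation temperature (f(Td)=1/2)
and dHvH the apparent van't Hoff enthalpy controlling the transition
steepness.  dCp is fixed at zero, i.e. the fit reports an *apparent* Td.
Temperatures are handled in Kelvin internally and reported in degC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._tables import R_GAS_KJ

__all__ = ["MeltCurve", "TwoStateParams", "fraction_folded", "fit_two_state",
           "read_melt_table"]

logger = logging.getLogger(__name__)

_C_TO_K = 273.15


@dataclass(frozen=True)
class MeltCurve:
    """Signal vs temperature trace of a thermal melt."""

    temperature_C: np.ndarray
    signal: np.ndarray
    scan_rate_C_min: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("temperature and signal must be equal-length 1-D sequences")
        if t.size < 20:
            raise ValueError("a melt curve needs at least 20 points spanning the transition")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state van't Hoff parameters with linear baselines."""

    td_C: float
    dh_vh_kJ_mol: float
    folded_intercept: float
    folded_slope: float
    unfolded_intercept: float
    unfolded_slope: float

    def __post_init__(self) -> None:
        if self.dh_vh_kJ_mol <= 0:
            raise ValueError("van't Hoff enthalpy must be positive")


def fraction_folded(temperature_C, params: TwoStateParams) -> np.ndarray:
    """Folded fraction f(T) in [0, 1]; f(Td) = 1/2, monotone decreasing in T."""
    t_K = np.asarray(temperature_C, dtype=float) + _C_TO_K
    td_K = params.td_C + _C_TO_K
    x = -(params.dh_vh_kJ_mol / R_GAS_KJ) * (1.0 / t_K - 1.0 / td_K)
    return 1.0 / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


def predict_signal(temperature_C, params: TwoStateParams) -> np.ndarray:
    t = np.asarray(temperature_C, dtype=float)
    f = fraction_folded(t, params)
    folded = params.folded_intercept + params.folded_slope * t
    unfolded = params.unfolded_intercept + params.unfolded_slope * t
    return folded * f + unfolded * (1.0 - f)


def _initial_guess(curve: MeltCurve) -> TwoStateParams:
    t, s = curve.temperature_C, curve.signal
    k = max(3, t.size // 6)
    bf = np.polyfit(t[:k], s[:k], 1)        # folded baseline from the low-T edge
    bu = np.polyfit(t[-k:], s[-k:], 1)      # unfolded baseline from the high-T edge
    folded = np.polyval(bf, t)
    unfolded = np.polyval(bu, t)
    denom = folded - unfolded
    mid = np.abs(denom) > 1e-12
    # amplitude comparable to the signal spread distinguishes a real
    # transition from two fits to the same baseline
    spread = np.ptp(s)
    if not np.any(mid) or np.max(np.abs(denom)) < 0.1 * max(spread, 1e-12):
        raise ValueError(
            "transition midpoint is not bracketed by the temperature range; "
            "collect data further into the pre- and post-transition baselines")
    frac = np.clip((s[mid] - unfolded[mid]) / denom[mid], 0.0, 1.0)
    tm = t[mid]
    crossings = np.nonzero(np.diff(np.sign(frac - 0.5)))[0]
    if crossings.size == 0:
        raise ValueError(
            "transition midpoint is not bracketed by the temperature range; "
            "collect data further into the pre- and post-transition baselines")
    td0 = float(tm[crossings[0]])
    return TwoStateParams(td_C=td0, dh_vh_kJ_mol=400.0,
                          folded_intercept=float(bf[1]), folded_slope=float(bf[0]),
                          unfolded_intercept=float(bu[1]), unfolded_slope=float(bu[0]))


def fit_two_state(curve: MeltCurve, init: TwoStateParams | None = None,
                  dof_correction: bool = True) -> tuple[TwoStateParams, float]:
    """Least-squares two-state fit; returns the parameters and the residual RMS.

    Raises if the transition midpoint is not bracketed by pre- and
    post-transition data.
    """
    p0 = init or _initial_guess(curve)
    t, s = curve.temperature_C, curve.signal
    span = t[-1] - t[0]
    if not (t[0] + 0.05 * span < p0.td_C < t[-1] - 0.05 * span):
        raise ValueError(
            "transition midpoint is not bracketed by the temperature range; "
            "collect data further into the pre- and post-transition baselines")

    def residual_fn(x):
        params = TwoStateParams(td_C=x[0], dh_vh_kJ_mol=max(x[1], 1e-6),
                                folded_intercept=x[2], folded_slope=x[3],
                                unfolded_intercept=x[4], unfolded_slope=x[5])
        return predict_signal(t, params) - s

    x0 = [p0.td_C, p0.dh_vh_kJ_mol, p0.folded_intercept, p0.folded_slope,
          p0.unfolded_intercept, p0.unfolded_slope]
    lb = [t[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    ub = [t[-1], 1e5, np.inf, np.inf, np.inf, np.inf]
    sol = least_squares(residual_fn, x0, bounds=(lb, ub), method="trf",
                        x_scale=[1.0, 100.0, 1.0, 0.1, 1.0, 0.1])
    params = TwoStateParams(td_C=float(sol.x[0]), dh_vh_kJ_mol=float(sol.x[1]),
                            folded_intercept=float(sol.x[2]), folded_slope=float(sol.x[3]),
                            unfolded_intercept=float(sol.x[4]), unfolded_slope=float(sol.x[5]))
    denom = max(t.size - 6, 1) if dof_correction else t.size
    rms = float(np.sqrt(np.sum(sol.fun**2) / denom))
    return params, rms


def read_melt_table(path) -> MeltCurve:
    """Read a two-column (temperature degC, signal) delimited text file.

    Non-numeric header or comment lines are skipped with a log message.
    """
    temps, signals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                continue
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError:
                logger.info("skipping non-numeric line %d of %s: %r",
                            lineno, path, line.strip())
                continue
            temps.append(t)
            signals.append(s)
    return MeltCurve(np.asarray(temps), np.asarray(signals))
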
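"""Least-squares fitting of sedimentation-equilibrium models and model selection.

The oligomeric-state question is answered by fitting a family of candidate
models (homogeneous monomer/dimer/trimer/tetramer with the monomer mass fixed
from composition, optionally a free-mass variant, and reversible
monomer/n-mer associations) to one or more radial scans and comparing their
weighted sum-of-squares and root-mean-square errors, backed by a
runs test on the residual signs.  A homogeneous n-mer is accepted when it
gives the smallest RMS and random residuals, while reversible candidates
whose association constant collapses (large negative ln k) are flagged
degenerate, mirroring standard equilibrium-AUC practice.

Fits use damped least squares (scipy's trust-region reflective
Levenberg-Marquardt variant, which supports the non-negativity bound on
bottom concentrations).  Multi-scan fits share the model parameters
(monomer mass, ln k) and give every scan its own bottom concentration and
baseline.  Weighting is uniform by default; per-point weights can be
supplied.  The reported RMS uses a degrees-of-freedom corrected denominator
sqrt(SSQ / (N - p)) by default, with a raw N denominator available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .sedeq import (
    BuoyancyContext,
    HomogeneousModel,
    RadialScan,
    ReversibleModel,
    predict_homogeneous,
    predict_reversible,
    reduced_buoyancy,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelChoice",
    "RunsTestResult",
    "fit_model",
    "select_model",
    "residual_runs_test",
]


@dataclass(frozen=True)
class ModelSpec:
    """Candidate model family for a sedimentation-equilibrium fit."""

    family: str                 # "homogeneous" | "reversible"
    n: int
    monomer_mass: float
    free_mass: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("homogeneous", "reversible"):
            raise ValueError("family must be 'homogeneous' or 'reversible'")
        if self.family == "reversible" and self.n not in (2, 3):
            raise ValueError("reversible models support n in {2, 3}")
        if self.family == "reversible" and self.free_mass:
            raise ValueError("free-mass fitting is offered for homogeneous models only")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def label(self) -> str:
        if self.family == "reversible":
            return f"1x-{self.n}x"
        return f"{self.n}x" + ("-freeM" if self.free_mass else "")


@dataclass
class FitResult:
    """Converged parameters and goodness-of-fit of one candidate model."""

    label: str
    params: dict
    stderr: dict
    residuals: list[np.ndarray]
    wssq: float
    rms: float
    n_points: int
    n_params: int
    converged: bool
    n_iter: int
    spec: ModelSpec | None = None

    @classmethod
    def from_rms(cls, label: str, rms: float, n_params: int = 2) -> "FitResult":
        """Wrap a precomputed RMS value (e.g. from an external fit) for selection."""
        return cls(label=label, params={}, stderr={}, residuals=[],
                   wssq=float("nan"), rms=rms, n_points=0, n_params=n_params,
                   converged=True, n_iter=0)

    @property
    def all_residuals(self) -> np.ndarray:
        return np.concatenate(self.residuals) if self.residuals else np.empty(0)


@dataclass
class RunsTestResult:
    """Wald-Wolfowitz runs test on residual signs."""

    n_runs: int
    n_pos: int
    n_neg: int
    p_value: float
    verdict: str  # "random" | "systematic" | "over-dispersed"


@dataclass
class ModelChoice:
    """Ranked candidates and the selected model with selection rationale."""

    ranked: list[FitResult]
    selected: FitResult
    rationale: dict[str, list[str]]


def _initial_values(scan: RadialScan, spec: ModelSpec) -> tuple[float, float]:
    """Data-derived start: baseline from the meniscus, Cb from the bottom."""
    a = scan.absorbance
    eps0 = float(a[0])
    cb_total = max(float(a[-1]) - eps0, 1e-3)
    if spec.family == "reversible":
        # split the bottom signal between monomer and n-mer at ln k = 0:
        # bisect cb + cb^n = cb_total on [0, cb_total]
        lo, hi = 0.0, cb_total
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mid + mid**spec.n < cb_total:
                lo = mid
            else:
                hi = mid
        return max(0.5 * (lo + hi), 1e-6), eps0
    return cb_total, eps0


def fit_model(scans: RadialScan | Sequence[RadialScan], spec: ModelSpec,
              buoyancy: BuoyancyContext, init: dict | None = None,
              weights: Sequence[np.ndarray] | None = None,
              dof_correction: bool = True, max_nfev: int = 2000) -> FitResult:
    """Fit one candidate model to one or several scans.

    Parameters are [monomer mass (if free)], [ln k (if reversible)], then a
    (Cb, baseline) pair per scan.  Deterministic given data, spec and init.
    """
    if isinstance(scans, RadialScan):
        scans = [scans]
    scans = list(scans)
    if not scans:
        raise ValueError("at least one scan is required")
    temps = {s.rotor.temperature_K for s in scans}
    if max(temps) - min(temps) > 1e-6:
        raise ValueError("scans in a joint fit must share the run temperature")

    aps = [reduced_buoyancy(buoyancy, s.rotor) for s in scans]
    if weights is None:
        sqrt_w = [np.ones(s.n_points) for s in scans]
    else:
        sqrt_w = [np.sqrt(np.asarray(w, dtype=float)) for w in weights]

    shared_names: list[str] = []
    x0: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    if spec.free_mass:
        shared_names.append("monomer_mass")
        x0.append((init or {}).get("monomer_mass", spec.monomer_mass))
        lb.append(1e3)
        ub.append(1e7)
    if spec.family == "reversible":
        shared_names.append("ln_k")
        x0.append((init or {}).get("ln_k", 0.0))
        lb.append(-60.0)
        ub.append(60.0)
    n_shared = len(shared_names)
    for scan in scans:
        cb0, eps0 = _initial_values(scan, spec)
        x0 += [(init or {}).get("bottom_conc", cb0), (init or {}).get("baseline", eps0)]
        lb += [0.0, -np.inf]
        ub += [np.inf, np.inf]

    def unpack(x: np.ndarray):
        mass = x[shared_names.index("monomer_mass")] if spec.free_mass else spec.monomer_mass
        ln_k = x[shared_names.index("ln_k")] if spec.family == "reversible" else None
        per_scan = x[n_shared:].reshape(len(scans), 2)
        return mass, ln_k, per_scan

    def residual_fn(x: np.ndarray) -> np.ndarray:
        mass, ln_k, per_scan = unpack(x)
        out = []
        for scan, ap, sw, (cb, eps) in zip(scans, aps, sqrt_w, per_scan):
            if spec.family == "homogeneous":
                model = HomogeneousModel(monomer_mass=mass, n=spec.n,
                                         bottom_conc=cb, baseline=eps)
                pred = predict_homogeneous(model, ap, scan.radii_cm, scan.rotor.bottom_cm)
            else:
                model = ReversibleModel(monomer_mass=mass, n=spec.n, bottom_conc=cb,
                                        ln_k=ln_k, baseline=eps)
                pred = predict_reversible(model, ap, scan.radii_cm, scan.rotor.bottom_cm)
            out.append(sw * (scan.absorbance - pred))
        return np.concatenate(out)

    x_scale = np.ones(len(x0))
    if spec.free_mass:
        x_scale[shared_names.index("monomer_mass")] = max(spec.monomer_mass, 1.0)
    sol = least_squares(residual_fn, np.asarray(x0), bounds=(lb, ub),
                        method="trf", x_scale=x_scale, max_nfev=max_nfev)
    converged = bool(sol.status > 0)
    if not converged:
        warnings.warn(f"fit of model {spec.label} did not converge: {sol.message}",
                      stacklevel=2)

    mass, ln_k, per_scan = unpack(sol.x)
    n_points = sum(s.n_points for s in scans)
    n_params = len(x0)
    wssq = float(np.sum(sol.fun**2))
    denom = max(n_points - n_params, 1) if dof_correction else n_points
    rms = math.sqrt(wssq / denom)

    # parameter uncertainties from the Jacobian at the solution
    stderr: dict = {}
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * wssq / max(n_points - n_params, 1)
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except (np.linalg.LinAlgError, ValueError):
        errs = np.full(n_params, np.nan)
    if spec.free_mass:
        stderr["monomer_mass"] = float(errs[shared_names.index("monomer_mass")])
    if spec.family == "reversible":
        stderr["ln_k"] = float(errs[shared_names.index("ln_k")])
    stderr["bottom_conc"] = list(errs[n_shared::2])
    stderr["baseline"] = list(errs[n_shared + 1::2])

    # split residuals back per scan
    res_all = sol.fun
    residuals, i = [], 0
    for s in scans:
        residuals.append(res_all[i:i + s.n_points].copy())
        i += s.n_points

    params = {
        "monomer_mass": float(mass),
        "n": spec.n,
        "ln_k": None if ln_k is None else float(ln_k),
        "bottom_conc": [float(c) for c, _ in per_scan],
        "baseline": [float(e) for _, e in per_scan],
    }
    return FitResult(label=spec.label, params=params, stderr=stderr,
                     residuals=residuals, wssq=wssq, rms=rms, n_points=n_points,
                     n_params=n_params, converged=converged,
                     n_iter=int(sol.nfev), spec=spec)


def _runs_pmf(n_pos: int, n_neg: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the number of runs given the sign counts."""
    n = n_pos + n_neg
    log_total = gammaln(n + 1) - gammaln(n_pos + 1) - gammaln(n_neg + 1)

    def log_comb(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -np.inf
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rs, ps = [], []
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            lp = (math.log(2.0) + log_comb(n_pos - 1, k - 1)
                  + log_comb(n_neg - 1, k - 1) - log_total)
        else:
            k = (r - 1) // 2
            t1 = log_comb(n_pos - 1, k - 1) + log_comb(n_neg - 1, k)
            t2 = log_comb(n_pos - 1, k) + log_comb(n_neg - 1, k - 1)
            lp = np.logaddexp(t1, t2) - log_total
        p = float(np.exp(lp))
        if p > 0.0:
            rs.append(r)
            ps.append(p)
    return np.asarray(rs), np.asarray(ps)


def residual_runs_test(residuals: Sequence[float]) -> RunsTestResult:
    """Wald-Wolfowitz runs test on the signs of fit residuals.

    Uses the exact conditional distribution of the run count given the
    numbers of positive and negative residuals (zeros are dropped).  The
    two-sided p-value is twice the smaller tail, capped at 1.  If all
    residuals share one sign the conditional test is degenerate; the
    reported p then comes from enumerating all 2^n equiprobable sign
    assignments (p = 2^(1-n)) and the verdict is maximally systematic.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r)
    signs = signs[signs != 0]
    n = signs.size
    if n < 2:
        raise ValueError("need at least 2 nonzero residuals for a runs test")
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))

    if n_pos == 0 or n_neg == 0:
        return RunsTestResult(n_runs=1, n_pos=n_pos, n_neg=n_neg,
                              p_value=float(2.0 ** (1 - n)), verdict="systematic")

    rs, ps = _runs_pmf(n_pos, n_neg)
    p_le = float(ps[rs <= n_runs].sum())
    p_ge = float(ps[rs >= n_runs].sum())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    mean_runs = 1.0 + 2.0 * n_pos * n_neg / n
    if p < 0.05:
        verdict = "systematic" if n_runs < mean_runs else "over-dispersed"
    else:
        verdict = "random"
    return RunsTestResult(n_runs=n_runs, n_pos=n_pos, n_neg=n_neg,
                          p_value=p, verdict=verdict)


def _monomer_fraction(c: FitResult) -> float | None:
    """Mean bottom-signal fraction carried by the monomer term of a
    reversible fit; None for non-reversible candidates."""
    ln_k = c.params.get("ln_k")
    if ln_k is None or not c.params.get("bottom_conc"):
        return None
    n = c.params.get("n", 2)
    fracs = []
    for cb in c.params["bottom_conc"]:
        nmer = cb**n * math.exp(ln_k) if cb > 0 else 0.0
        total = cb + nmer
        fracs.append(cb / total if total > 0 else 1.0)
    return float(np.mean(fracs))


def select_model(candidates: Sequence[FitResult], ln_k_floor: float = -20.0,
                 tie_rel: float = 0.01) -> ModelChoice:
    """Rank candidates by RMS and select the best plausible model.

    Two reversible-fit degeneracies are flagged and excluded from selection:
    a collapsed association constant (ln k below ``ln_k_floor``, i.e. the
    n-mer term switched off) and the mirror case where the monomer term's
    bottom-signal share drops below 5%, meaning the "equilibrium" reduced to
    a single homogeneous species.  Non-converged fits are likewise flagged.
    RMS differences within the relative parsimony margin ``tie_rel`` count
    as ties and go to the model with fewer parameters.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("select_model needs at least one candidate")

    rationale: dict[str, list[str]] = {c.label: [] for c in candidates}
    plausible: list[FitResult] = []
    for c in candidates:
        flags = rationale[c.label]
        if not c.converged:
            flags.append("did not converge")
        ln_k = c.params.get("ln_k")
        if ln_k is not None and ln_k < ln_k_floor:
            flags.append(f"implausible: ln k = {ln_k:.1f} < {ln_k_floor:.0f}")
        frac = _monomer_fraction(c)
        if frac is not None and frac < 0.05:
            flags.append(f"implausible: association degenerate "
                         f"(monomer carries {100 * frac:.1f}% of the bottom signal)")
        if c.residuals:
            runs = residual_runs_test(c.all_residuals)
            flags.append(f"residuals {runs.verdict} (runs p = {runs.p_value:.3g})")
        if not any(f.startswith(("implausible", "did not")) for f in flags):
            plausible.append(c)

    pool = plausible if plausible else candidates
    ranked = sorted(candidates, key=lambda c: (c.rms, c.n_params))
    best = min(pool, key=lambda c: c.rms)
    # break near-ties (within the parsimony margin) toward fewer parameters
    ties = [c for c in pool if c.rms <= best.rms * (1.0 + tie_rel)]
    selected = min(ties, key=lambda c: (c.n_params, c.rms))
    if len(candidates) == 1:
        rationale[selected.label].append("only model")
    else:
        margin = sorted(c.rms for c in candidates)
        rationale[selected.label].append(
            f"selected: smallest RMS {selected.rms:.3g} "
            f"(next candidate {margin[1]:.3g})" if len(margin) > 1 else "selected")
    if not plausible:
        rationale[selected.label].append("all candidates flagged; selected by RMS alone")
    return ModelChoice(ranked=ranked, selected=selected, rationale=rationale)
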
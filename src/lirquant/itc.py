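"""Isothermal titration calorimetry: one-site heat model, simulator and fitter.

The heat model follows the perfusion (constant-volume overflow) convention of
cell-feedback instruments such as the MicroCal VP-ITC: each injection of
volume ``dV`` into a cell of volume ``V0`` displaces an equal volume of cell
contents, so pre-existing total concentrations scale by ``(1 - dV/V0)`` and
the freshly injected material carries the first-order ``(1 - dV/2V0)``
mid-injection correction (half of the injected aliquot is itself subject to
overflow while the plunger moves).  The observed heat of injection *i* is

    dQ_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1})/2 + q_mix

with ``Q_i = [RL]_i * dH * V0`` the cumulative heat content of the cell and
``q_mix`` a constant per-injection mixing/dilution heat fitted as a nuisance
parameter.  Bound complex ``[RL]`` comes from the single-site quadratic with
the receptor site concentration ``n * [receptor]``.

Units: concentrations µM, volumes µL, enthalpies cal/mol of injectant,
heats µcal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .binding_models import solve_single_site

__all__ = [
    "OneSiteParams",
    "TitrationSchedule",
    "InjectionHeats",
    "FitResult",
    "model_heats",
    "simulate_titration",
    "fit_one_site",
    "wiseman_c",
    "default_schedule",
]

# µM * µL * cal/mol -> µcal
_HEAT_SCALE = 1e-6


@dataclass(frozen=True)
class OneSiteParams:
    """Thermodynamic description of a 1:1 receptor-ligand interaction.

    Attributes
    ----------
    kd : float
        Dissociation constant, µM (> 0).
    dH : float
        Molar binding enthalpy, cal/mol of injectant bound (signed;
        exothermic binding is negative).
    n : float
        Stoichiometry, binding sites per receptor (> 0).
    q_mix : float
        Constant heat of mixing per injection, µcal.
    """

    kd: float
    dH: float
    n: float = 1.0
    q_mix: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry n must be positive")


@dataclass(frozen=True)
class TitrationSchedule:
    """Geometry and concentrations of one titration.

    Defaults are set by :func:`default_schedule`; volumes are µL and
    concentrations µM.
    """

    cell_volume: float
    cell_receptor_conc: float
    syringe_ligand_conc: float
    injection_volumes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes", tuple(float(v) for v in self.injection_volumes))
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("all volumes must be positive")
        if self.cell_receptor_conc < 0 or self.syringe_ligand_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if any(v > 0.05 * self.cell_volume for v in self.injection_volumes):
            warnings.warn("injection volume exceeds 5% of cell volume; "
                          "the perfusion dilution model may be inaccurate")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def default_schedule(cell_volume: float = 1400.0, cell_receptor_conc: float = 30.0,
                   syringe_ligand_conc: float = 350.0, n_injections: int = 25,
                   injection_volume: float = 10.0) -> TitrationSchedule:
    """Default titration design: 30 µM receptor in a 1400 µL cell, 25 x 10 µL
    injections of 350 µM ligand."""
    return TitrationSchedule(cell_volume, cell_receptor_conc, syringe_ligand_conc,
                             (injection_volume,) * n_injections)


@dataclass(frozen=True)
class InjectionHeats:
    """Ordered per-injection heats (µcal) with cumulative injectant:receptor
    molar ratios."""

    heats: tuple
    molar_ratio: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", tuple(float(h) for h in self.heats))
        object.__setattr__(self, "molar_ratio", tuple(float(r) for r in self.molar_ratio))
        if len(self.heats) != len(self.molar_ratio):
            raise ValueError("heats and molar_ratio must have equal length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")

    def __len__(self) -> int:
        return len(self.heats)


@dataclass(frozen=True)
class FitResult:
    params: OneSiteParams
    stderr_kd: float
    stderr_dH: float
    stderr_n: float
    residual_rms: float
    converged: bool
    c_value: float = math.nan


def _cell_totals(schedule: TitrationSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Total receptor and injectant concentrations in the cell after each
    injection, under the perfusion overflow convention."""
    v0 = schedule.cell_volume
    mt = np.empty(schedule.n_injections)
    xt = np.empty(schedule.n_injections)
    m, x = schedule.cell_receptor_conc, 0.0
    for i, dv in enumerate(schedule.injection_volumes):
        f = 1.0 - dv / v0
        m *= f
        x = x * f + schedule.syringe_ligand_conc * (dv / v0) * (1.0 - dv / (2.0 * v0))
        mt[i] = m
        xt[i] = x
    return mt, xt


def model_heats(params: OneSiteParams, schedule: TitrationSchedule) -> InjectionHeats:
    """Noise-free per-injection heats for a one-site titration."""
    mt, xt = _cell_totals(schedule)
    v0 = schedule.cell_volume
    q_prev = 0.0
    heats = np.empty(schedule.n_injections)
    for i, dv in enumerate(schedule.injection_volumes):
        rl = solve_single_site(params.n * mt[i], xt[i], params.kd).complex
        q = rl * params.dH * v0 * _HEAT_SCALE
        heats[i] = q - q_prev + (dv / v0) * (q + q_prev) / 2.0 + params.q_mix
        q_prev = q
    with np.errstate(divide="ignore"):
        ratio = xt / mt
    return InjectionHeats(heats=tuple(heats), molar_ratio=tuple(ratio))


def simulate_titration(params: OneSiteParams, schedule: TitrationSchedule,
                       noise_sd: float, seed: int | np.random.Generator) -> InjectionHeats:
    """model_heats plus i.i.d. Gaussian instrument noise of sd ``noise_sd`` µcal."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = model_heats(params, schedule)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = np.asarray(clean.heats) + rng.normal(0.0, noise_sd, len(clean))
    return InjectionHeats(heats=tuple(noisy), molar_ratio=clean.molar_ratio)


def wiseman_c(params: OneSiteParams, schedule: TitrationSchedule) -> float:
    """Wiseman c parameter, n * [receptor]_0 / Kd; isotherm shape diagnostic."""
    return params.n * schedule.cell_receptor_conc / params.kd


def fit_one_site(data: InjectionHeats, schedule: TitrationSchedule,
                 init: OneSiteParams, weights: np.ndarray | None = None,
                 discard_first: bool = False) -> FitResult:
    """Nonlinear least-squares fit of (Kd, dH, n, q_mix) to injection heats.

    Kd is fitted on a log scale, which enforces positivity without bound
    constraints.  Standard errors come from the Jacobian at the optimum
    (Gauss-Newton curvature) scaled by the residual variance.  On optimizer
    failure a result with ``converged=False`` is returned rather than raising.

    ``discard_first`` drops injection 1 from the objective (the conventional
    remedy for syringe-tip diffusion); off by default.
    """
    if len(data) < 6:
        raise ValueError("need at least 6 injections to fit 4 parameters")
    if not (1e-4 < init.kd < 1e6):
        raise ValueError("initial kd outside (1e-4, 1e6) µM")
    y = np.asarray(data.heats)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if discard_first:
        w = w.copy()
        w[0] = 0.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, dh, n, q = theta
        p = OneSiteParams(kd=math.exp(log_kd), dH=dh, n=n, q_mix=q)
        return w * (np.asarray(model_heats(p, schedule).heats) - y)

    theta0 = np.array([math.log(init.kd), init.dH, init.n, init.q_mix])
    try:
        sol = least_squares(residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
    except Exception:
        return FitResult(init, math.nan, math.nan, math.nan, math.nan, converged=False)

    log_kd, dh, n, q = sol.x
    if n <= 0:  # unphysical optimum
        return FitResult(init, math.nan, math.nan, math.nan, math.nan, converged=False)
    params = OneSiteParams(kd=math.exp(log_kd), dH=dh, n=n, q_mix=q)
    dof = max(int(np.count_nonzero(w)) - 4, 1)
    rss = float(np.sum(sol.fun ** 2))
    rms = math.sqrt(rss / max(np.count_nonzero(w), 1))
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr_kd = params.kd * se[0]  # delta method for the log-Kd parameterization
        stderr_dh, stderr_n = se[1], se[2]
        ok = bool(sol.success and np.all(np.isfinite(se)))
    except np.linalg.LinAlgError:
        stderr_kd = stderr_dh = stderr_n = math.nan
        ok = False

    c = wiseman_c(params, schedule)
    if ok and not (1.0 <= c <= 1000.0):
        warnings.warn(f"Wiseman c = {c:.3g} outside [1, 1000]; "
                      "fitted Kd may be poorly determined")
    return FitResult(params, stderr_kd, stderr_dh, stderr_n, rms,
                     converged=ok, c_value=c)
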
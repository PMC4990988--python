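"""Equilibrium solvers for 1:1 and two-ligand competitive receptor binding.

All concentrations are in µM throughout; unit conversions belong at I/O
boundaries.  The single-site solver is the closed-form root of the binding
quadratic; the competition solver is a bracketed scalar root-find on the
free-receptor concentration, whose residual is monotone, so convergence is
guaranteed without an initial guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "SpeciesState",
    "CompetitionState",
    "solve_single_site",
    "solve_competition",
    "complex_ratio",
]

#: Relative tolerance on the free-receptor root (µM scale).
ROOT_XTOL = 1e-12


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (µM) for one receptor + one ligand."""

    free_receptor: float
    free_ligand: float
    complex: float

    @property
    def total_receptor(self) -> float:
        return self.free_receptor + self.complex

    @property
    def total_ligand(self) -> float:
        return self.free_ligand + self.complex


@dataclass(frozen=True)
class CompetitionState:
    """Equilibrium concentrations (µM) for one receptor + two competing ligands.

    Species A and B share the same site; ``complex_RA``/``complex_RB`` are the
    two binary complexes.
    """

    free_receptor: float
    free_A: float
    free_B: float
    complex_RA: float
    complex_RB: float


def solve_single_site(total_receptor: float, total_ligand: float, kd: float) -> SpeciesState:
    """Solve R + L <-> RL at equilibrium.

    Parameters
    ----------
    total_receptor, total_ligand : float
        Total (bound + free) concentrations in µM.
    kd : float
        Dissociation constant in µM; must be positive.

    Returns
    -------
    SpeciesState
        The unique physical (non-negative) root of the binding quadratic
        ``RL**2 - (R0 + L0 + Kd)*RL + R0*L0 = 0``.
    """
    if total_receptor < 0 or total_ligand < 0:
        raise ValueError("total concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("kd must be positive")
    r0, l0 = float(total_receptor), float(total_ligand)
    b = r0 + l0 + kd
    # Numerically stable smaller quadratic root: 2*r0*l0 / (b + sqrt(b^2-4 r0 l0))
    disc = math.sqrt(b * b - 4.0 * r0 * l0)
    rl = 2.0 * r0 * l0 / (b + disc) if (b + disc) > 0 else 0.0
    rl = min(rl, r0, l0)
    return SpeciesState(free_receptor=r0 - rl, free_ligand=l0 - rl, complex=rl)


def _competition_residual(r_free: float, r0: float, a0: float, b0: float,
                          kd_a: float, kd_b: float) -> float:
    """Receptor mass-balance residual as a function of free receptor.

    Monotone increasing in ``r_free`` on [0, r0]: residual(0) = -r0 <= 0 and
    residual(r0) >= 0, so a bracketed root always exists.
    """
    free_a = a0 / (1.0 + r_free / kd_a)
    free_b = b0 / (1.0 + r_free / kd_b)
    return r_free * (1.0 + free_a / kd_a + free_b / kd_b) - r0


def solve_competition(total_receptor: float, total_A: float, total_B: float,
                      kdA: float, kdB: float) -> CompetitionState:
    """Solve the competitive equilibrium R + A <-> RA, R + B <-> RB.

    Both ligands contend for the same receptor site; the solution satisfies
    both dissociation-constant relations and all three mass balances.  Used to
    predict bound-species abundances in the native-MS competition experiment
    (equimolar receptor and two peptides).

    Raises
    ------
    ValueError
        On negative totals or non-positive dissociation constants.
    RuntimeError
        If the bracketed root-find fails to converge (with diagnostics).
    """
    if min(total_receptor, total_A, total_B) < 0:
        raise ValueError("total concentrations must be non-negative")
    if kdA <= 0 or kdB <= 0:
        raise ValueError("dissociation constants must be positive")
    r0, a0, b0 = float(total_receptor), float(total_A), float(total_B)
    if r0 == 0:
        return CompetitionState(0.0, a0, b0, 0.0, 0.0)

    args = (r0, a0, b0, kdA, kdB)
    try:
        r_free = brentq(_competition_residual, 0.0, r0, args=args,
                        xtol=ROOT_XTOL, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - brentq cannot fail on this bracket
        raise RuntimeError(
            f"competition root-find failed for R0={r0}, A0={a0}, B0={b0}, "
            f"kdA={kdA}, kdB={kdB}: {exc}"
        ) from exc
    free_a = a0 / (1.0 + r_free / kdA)
    free_b = b0 / (1.0 + r_free / kdB)
    return CompetitionState(
        free_receptor=r_free,
        free_A=free_a,
        free_B=free_b,
        complex_RA=r_free * free_a / kdA,
        complex_RB=r_free * free_b / kdB,
    )


def complex_ratio(state: CompetitionState) -> float:
    """Abundance ratio of the two bound species, complex_RA / complex_RB.

    Returns ``math.inf`` when the B complex is absent so that titration
    sweeps through degenerate points do not abort.
    """
    if state.complex_RB == 0:
        return math.inf
    return state.complex_RA / state.complex_RB
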
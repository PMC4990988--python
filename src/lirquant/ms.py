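"""Native ESI-MS competition assay arithmetic and spectrum synthesis.

Covers peptide mass calculation from sequence, m/z for positive-ion charge
states, synthesis of competition spectra whose peak areas follow the
equilibrium species concentrations, and extraction of the bound-species
abundance ratio from a spectrum.

Peaks are modelled as Gaussians; no isotope envelopes or instrument response
beyond a per-species multiplicative response factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binding_models import CompetitionState

__all__ = [
    "Peptide",
    "Spectrum",
    "SpeciesAssignment",
    "peptide_mass",
    "mz_of",
    "synthesize_spectrum",
    "extract_abundance_ratio",
    "PROTON_MASS",
    "WT_LIR",
    "L341V_LIR",
]

PROTON_MASS = 1.007276  # Da

# Amino-acid residue masses (Da), monoisotopic and average, for the 20
# standard residues.  Values are the conventional residue masses (amino acid
# minus one water) as tabulated by standard proteomics references (e.g. the
# Unimod / ExPASy tables); a peptide mass is the residue sum plus one water.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.01528

#: SQSTM1 residues 332-351; the single L341V substitution is at position 10.
WT_LIR = "SGGDDDWTHLSSKEVDPSTG"
L341V_LIR = "SGGDDDWTHVSSKEVDPSTG"


@dataclass(frozen=True)
class Peptide:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        for i, aa in enumerate(self.sequence):
            if aa not in MONOISOTOPIC:
                raise ValueError(f"unknown residue code {aa!r} at position {i} "
                                 f"in peptide {self.name!r}")


@dataclass(frozen=True)
class SpeciesAssignment:
    """Maps a named species to one charge state and its expected m/z."""

    species: str
    charge: int
    expected_mz: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if mz.shape != it.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)


def peptide_mass(p: Peptide | str, kind: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da: residue-mass sum plus one water."""
    seq = p.sequence if isinstance(p, Peptide) else Peptide("anon", p).sequence
    if not seq:
        raise ValueError("empty sequence")
    if kind == "monoisotopic":
        return sum(MONOISOTOPIC[a] for a in seq) + WATER_MONO
    if kind == "average":
        return sum(AVERAGE[a] for a in seq) + WATER_AVG
    raise ValueError(f"kind must be 'monoisotopic' or 'average', got {kind!r}")


def mz_of(mass: float, charge: int) -> float:
    """m/z of a positively charged ion: (M + z*m_H+)/z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge


def _species_concentration(state: CompetitionState, species: str) -> float:
    table = {
        "free-WT": state.free_A,
        "free-mut": state.free_B,
        "free-LC3B": state.free_receptor,
        "complex-WT": state.complex_RA,
        "complex-mut": state.complex_RB,
    }
    try:
        return table[species]
    except KeyError:
        raise ValueError(f"unknown species label {species!r}; "
                         f"expected one of {sorted(table)}") from None


def synthesize_spectrum(state: CompetitionState, assignments: list[SpeciesAssignment],
                        peak_width: float = 0.5,
                        response_factors: dict[str, float] | None = None,
                        seed: int | np.random.Generator | None = None,
                        noise_sd: float = 0.0,
                        mz_range: tuple[float, float] = (500.0, 4000.0),
                        grid_step: float = 0.02) -> Spectrum:
    """Render a competition equilibrium as a stick-free Gaussian spectrum.

    Each assignment contributes a Gaussian of standard deviation
    ``peak_width`` (m/z units) centred at its expected m/z, with *area*
    proportional to the species concentration times its response factor.
    Optional additive white noise models the baseline.
    """
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    rf = response_factors or {}
    if any(v <= 0 for v in rf.values()):
        raise ValueError("response factors must be positive")

    centres = sorted(a.expected_mz for a in assignments)
    for lo, hi in zip(centres, centres[1:]):
        if hi - lo < peak_width / 2:
            warnings.warn(f"assignments at m/z {lo:.3f} and {hi:.3f} closer than "
                          "half a peak width; their areas will overlap")

    grid = np.arange(mz_range[0], mz_range[1] + grid_step / 2, grid_step)
    intensity = np.zeros_like(grid)
    norm = peak_width * np.sqrt(2.0 * np.pi)
    for a in assignments:
        area = _species_concentration(state, a.species) * rf.get(a.species, 1.0)
        if area > 0:
            intensity += (area / norm) * np.exp(-0.5 * ((grid - a.expected_mz) / peak_width) ** 2)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, grid.shape), 0.0, None)
    return Spectrum(mz=grid, intensity=intensity)


def _window_area(s: Spectrum, centre: float, half_width: float) -> float:
    """Trapezoidal integral over [centre-hw, centre+hw] minus a linear
    baseline through the window endpoints."""
    sel = (s.mz >= centre - half_width) & (s.mz <= centre + half_width)
    if not np.any(sel):
        raise ValueError(f"integration window at m/z {centre} lies outside the spectrum")
    x, y = s.mz[sel], s.intensity[sel]
    baseline = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
    return float(np.trapezoid(y - baseline, x))


def extract_abundance_ratio(s: Spectrum, target_WT: SpeciesAssignment,
                            target_mut: SpeciesAssignment, window: float = 3.0) -> float:
    """Baseline-subtracted WT-complex area over mutant-complex area.

    ``window`` is the integration half-width in m/z.  Windows must not
    overlap; a zero mutant area yields ``inf`` (sentinel, not an exception).
    """
    if abs(target_WT.expected_mz - target_mut.expected_mz) < 2 * window:
        raise ValueError("integration windows overlap; narrow `window` or "
                         "choose better-separated charge states")
    a_wt = _window_area(s, target_WT.expected_mz, window)
    a_mut = _window_area(s, target_mut.expected_mz, window)
    if a_mut <= 0:
        return np.inf
    return a_wt / a_mut
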
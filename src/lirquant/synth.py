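"""Synthetic-data generators with recorded ground truth for every modality.

Each generator is a deterministic function of its parameters and a seed, and
emits a :class:`GroundTruth` record sufficient to regenerate the dataset
bit-identically.  A master seed fans out to per-dataset sub-seeds through
numpy's splittable ``SeedSequence`` so datasets are independently
reproducible.

Defaults mirror the experimental designs the analysis modules target:

* ITC: 30 µM receptor in a 1400 µL cell, 25 x 10 µL injections of 350 µM
  peptide, instrument noise 2% of the largest heat.
* MS competition: 5 µM receptor + 5 µM of each peptide, free peptides at 2+
  and 14.6 kDa receptor-peptide complexes at 9+ (the receptor mass is a
  synthetic stand-in; the construct's exact mass is a fixture parameter).
* HSQC: amide peak lists at 0.25 mM receptor, bound state at a 1:2
  receptor:ligand ratio; a count-structured preset embeds 19 residues with
  CSP > 0.5 ppm of which 9 exceed 1.0 ppm, and a mutant preset differing
  substantially at exactly 8 residues.
* Cell stacks: tandem-fluorophore reporter cells in which a condition-
  dependent fraction ``f_acidic`` of puncta is red-only (acidified vesicles)
  and the rest fluoresce in both channels with tightly correlated
  amplitudes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import binding_models, blots, itc, ms, nmr
from .coloc import ImageStack

__all__ = [
    "ConditionPreset",
    "WT_ITC_PARAMS",
    "L341V_ITC_PARAMS",
    "GroundTruth",
    "CONDITION_PRESETS",
    "spawn_seeds",
    "gen_itc",
    "gen_competition_spectrum",
    "preset_csp_maps",
    "gen_hsqc_titration",
    "gen_cell_stack",
    "gen_lane_densities",
    "default_assignments",
    "LC3B_SYNTHETIC_MASS",
]

#: Synthetic stand-in mass (Da) for the recombinant LC3B construct used to
#: place complex peaks; a fixture parameter, not a measured value.
LC3B_SYNTHETIC_MASS = 14600.0

#: Ground-truth one-site parameters for simulation studies.  The Kd values
#: are the ITC-determined dissociation constants of the two peptides; the
#: enthalpies are package choices (no numeric enthalpies are published for
#: this pair — the mutant's is set substantially smaller in magnitude, and
#: Kd-recovery statistics are invariant to the enthalpy scale because the
#: default noise level scales with the largest heat).
WT_ITC_PARAMS = itc.OneSiteParams(kd=3.2, dH=-9000.0, n=1.0, q_mix=0.0)
L341V_ITC_PARAMS = itc.OneSiteParams(kd=10.9, dH=-5500.0, n=1.0, q_mix=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Complete record of the generating parameters of one dataset."""

    generator: str
    seed: int
    params: dict

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"cannot serialize {type(o)}")
        return json.dumps({"generator": self.generator, "seed": self.seed,
                           "params": self.params}, default=default, indent=1)


@dataclass(frozen=True)
class ConditionPreset:
    """Imaging condition: fraction of red-only (acidic) puncta and rendering
    settings for one genotype/treatment arm."""

    name: str
    f_acidic: float
    n_puncta: int = 40
    punctum_amplitude: float = 5000.0
    background: float = 15.0
    gain_green: float = 0.8
    amp_jitter: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_acidic <= 1.0:
            raise ValueError("f_acidic must lie in [0, 1]")


# Ordering encodes the reporter biology: lysosomal-acidification block
# (BafA1) nearly abolishes red-only puncta; the L341V mutant incorporates
# into acidic vesicles less readily than WT, so it has fewer red-only puncta
# than WT; rapamycin partially restores the mutant toward the WT phenotype.
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "WT": ConditionPreset("WT", f_acidic=0.60),
    "WT+BafA1": ConditionPreset("WT+BafA1", f_acidic=0.08),
    "L341V": ConditionPreset("L341V", f_acidic=0.35),
    "L341V+BafA1": ConditionPreset("L341V+BafA1", f_acidic=0.05),
    "L341V+rapamycin": ConditionPreset("L341V+rapamycin", f_acidic=0.55),
}


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into n independent sub-seeds (< 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


# --------------------------------------------------------------------------
# ITC

def gen_itc(params: itc.OneSiteParams, schedule: itc.TitrationSchedule | None = None,
            noise_sd: float | None = None, seed: int = 0
            ) -> tuple[itc.InjectionHeats, GroundTruth]:
    """Simulated titration at the default design; ``noise_sd=None`` selects
    2% of the largest noise-free |heat|."""
    schedule = schedule or itc.default_schedule()
    if noise_sd is None:
        clean = itc.model_heats(params, schedule)
        noise_sd = 0.02 * max(abs(h) for h in clean.heats)
    data = itc.simulate_titration(params, schedule, noise_sd, seed)
    gt = GroundTruth("gen_itc", seed, {
        "kd": params.kd, "dH": params.dH, "n": params.n, "q_mix": params.q_mix,
        "noise_sd": noise_sd,
        "schedule": dataclasses.asdict(schedule),
    })
    return data, gt


# --------------------------------------------------------------------------
# MS competition

def default_assignments(lc3b_mass: float = LC3B_SYNTHETIC_MASS,
                        free_charge: int = 2, complex_charge: int = 9
                        ) -> list[ms.SpeciesAssignment]:
    """Species-to-peak table: free peptides at 2+, complexes at 9+."""
    m_wt = ms.peptide_mass(ms.WT_LIR)
    m_mut = ms.peptide_mass(ms.L341V_LIR)
    return [
        ms.SpeciesAssignment("free-WT", free_charge, ms.mz_of(m_wt, free_charge)),
        ms.SpeciesAssignment("free-mut", free_charge, ms.mz_of(m_mut, free_charge)),
        ms.SpeciesAssignment("complex-WT", complex_charge,
                             ms.mz_of(lc3b_mass + m_wt, complex_charge)),
        ms.SpeciesAssignment("complex-mut", complex_charge,
                             ms.mz_of(lc3b_mass + m_mut, complex_charge)),
    ]


def gen_competition_spectrum(kdA: float = 3.2, kdB: float = 10.9,
                             totals: tuple = (5.0, 5.0, 5.0),
                             response_factors: dict | None = None,
                             peak_width: float = 0.2,
                             noise_sd: float = 0.0, seed: int = 0,
                             lc3b_mass: float = LC3B_SYNTHETIC_MASS
                             ) -> tuple[ms.Spectrum, GroundTruth]:
    """Competition equilibrium rendered as a native-MS spectrum.

    Defaults are the competition-assay conditions: 5 µM receptor with 5 µM of
    each peptide and the two printed dissociation constants.
    """
    r0, a0, b0 = totals
    state = binding_models.solve_competition(r0, a0, b0, kdA, kdB)
    assignments = default_assignments(lc3b_mass)
    spec = ms.synthesize_spectrum(state, assignments, peak_width=peak_width,
                                  response_factors=response_factors,
                                  seed=seed, noise_sd=noise_sd)
    gt = GroundTruth("gen_competition_spectrum", seed, {
        "kdA": kdA, "kdB": kdB, "totals": list(totals),
        "state": dataclasses.asdict(state),
        "equilibrium_ratio": binding_models.complex_ratio(state),
        "response_factors": response_factors or {},
        "peak_width": peak_width, "noise_sd": noise_sd,
        "lc3b_mass": lc3b_mass,
        "assignments": [dataclasses.asdict(a) for a in assignments],
    })
    return spec, gt


# --------------------------------------------------------------------------
# HSQC peak lists

def preset_csp_maps(n_residues: int = 120, n_strong: int = 9,
                       n_moderate: int = 10, n_differential: int = 8,
                       seed: int = 0) -> tuple[dict, dict]:
    """True per-residue CSP vectors for a WT-like and a mutant-like complex.

    The WT map has exactly ``n_strong`` residues with weighted CSP > 1.0 ppm
    and ``n_moderate`` more in (0.5, 1.0]; the mutant map equals the WT map
    except at ``n_differential`` residues where the CSP is reduced by more
    than 0.1 ppm.  These encode the *counts* the classification machinery
    must reproduce; per-residue magnitudes are synthetic.

    Returns two dicts residue_id -> (ddH, ddN) in ppm.
    """
    rng = np.random.default_rng(seed)
    rids = list(range(1, n_residues + 1))
    chosen = rng.choice(rids, size=n_strong + n_moderate, replace=False)
    strong_ids = sorted(int(r) for r in chosen[:n_strong])
    moderate_ids = sorted(int(r) for r in chosen[n_strong:])

    def vector(target: float) -> tuple[float, float]:
        phi = rng.uniform(0.15, np.pi / 2 - 0.15)
        return (target * np.cos(phi), 5.0 * target * np.sin(phi))

    wt: dict[int, tuple[float, float]] = {}
    for rid in rids:
        if rid in strong_ids:
            wt[rid] = vector(rng.uniform(1.1, 2.0))
        elif rid in moderate_ids:
            wt[rid] = vector(rng.uniform(0.55, 0.95))
        else:
            wt[rid] = vector(rng.uniform(0.0, 0.35))

    diff_ids = sorted(int(r) for r in rng.choice(sorted(strong_ids + moderate_ids),
                                                 size=n_differential, replace=False))
    mut = dict(wt)
    for rid in diff_ids:
        dh, dn = wt[rid]
        w = float(np.hypot(dh, dn / 5.0))
        shrink = rng.uniform(0.2, max(0.3, 1.0 - 0.15 / w))  # drop > 0.1 ppm
        mut[rid] = (dh * shrink, dn * shrink)
    return wt, mut


def gen_hsqc_titration(true_csps: dict, n_residues: int | None = None,
                       jitter_sd: float = 0.0, seed: int = 0
                       ) -> tuple[nmr.PeakList, nmr.PeakList, GroundTruth]:
    """Free and bound HSQC peak lists realizing prescribed true CSP vectors.

    Free-state shifts are drawn reproducibly inside the backbone amide
    region; the bound list is displaced by the true (ddH, ddN) vectors plus
    optional Gaussian jitter on both lists' endpoint positions.
    """
    if not true_csps:
        raise ValueError("true_csps must contain at least one residue")
    rng = np.random.default_rng(seed)
    rids = sorted(true_csps)
    if n_residues is not None and n_residues != len(rids):
        raise ValueError("n_residues disagrees with true_csps")
    free_peaks, bound_peaks = [], []
    for rid in rids:
        h0 = rng.uniform(6.5, 9.8)
        n0 = rng.uniform(105.0, 130.0)
        ddh, ddn = true_csps[rid]
        jh, jn = (rng.normal(0.0, jitter_sd), rng.normal(0.0, 5 * jitter_sd)) \
            if jitter_sd > 0 else (0.0, 0.0)
        free_peaks.append(nmr.HSQCPeak(rid, "X", h0, n0))
        bound_peaks.append(nmr.HSQCPeak(rid, "X", h0 + ddh + jh, n0 + ddn + jn))
    gt = GroundTruth("gen_hsqc_titration", seed, {
        "true_csps": {str(r): list(v) for r, v in true_csps.items()},
        "true_weighted": {str(r): float(np.hypot(v[0], v[1] / 5.0))
                          for r, v in true_csps.items()},
        "jitter_sd": jitter_sd,
    })
    return (nmr.PeakList("free", free_peaks),
            nmr.PeakList("bound", bound_peaks), gt)


# --------------------------------------------------------------------------
# Cell image stacks

def gen_cell_stack(preset: ConditionPreset | str, shape: tuple = (8, 64, 64),
                   voxel_size: tuple = (0.2, 0.1, 0.1), seed: int = 0
                   ) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Two-channel reporter cell: dual-colour and red-only puncta in an
    elliptical cell mask, with diffuse cytoplasm, optical blur and shot-like
    noise (Gaussian with variance equal to the mean, rounded to counts).
    """
    if isinstance(preset, str):
        preset = CONDITION_PRESETS[preset]
    if tuple(shape) < (8, 64, 64):
        raise ValueError("shape must be at least (8, 64, 64)")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape

    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    cy, cx = ny / 2, nx / 2
    ry, rx = 0.42 * ny, 0.42 * nx
    mask2d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    mask = np.broadcast_to(mask2d, shape).copy()

    red = np.zeros(shape)
    green = np.zeros(shape)
    n_acidic = int(round(preset.f_acidic * preset.n_puncta))
    centres, kinds = [], []
    for k in range(preset.n_puncta):
        while True:
            z = rng.uniform(1, nz - 1)
            y = rng.uniform(cy - ry, cy + ry)
            x = rng.uniform(cx - rx, cx + rx)
            if ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 0.9:
                break
        amp = preset.punctum_amplitude * rng.lognormal(0.0, 0.25)
        acidic = k < n_acidic
        zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
        red[zi, yi, xi] += amp
        if not acidic:
            green[zi, yi, xi] += amp * preset.gain_green * \
                (1.0 + rng.normal(0.0, preset.amp_jitter))
        centres.append((zi, yi, xi))
        kinds.append("red-only" if acidic else "dual")

    sigma = (0.7, 1.3, 1.3)  # optical blur, voxels
    red = gaussian_filter(red, sigma)
    green = gaussian_filter(green, sigma)
    red += preset.background * mask
    green += preset.background * 0.8 * mask
    # Shot-noise approximation: Gaussian with variance = mean, then rounded
    # to integer counts (adequate above ~20 counts; see docs).
    red = np.clip(np.round(red + rng.normal(0.0, np.sqrt(np.maximum(red, 1.0)))), 0, None)
    green = np.clip(np.round(green + rng.normal(0.0, np.sqrt(np.maximum(green, 1.0)))), 0, None)

    stack = ImageStack(channel_green=green, channel_red=red, voxel_size=voxel_size)
    gt = GroundTruth("gen_cell_stack", seed, {
        "preset": dataclasses.asdict(preset), "shape": list(shape),
        "voxel_size": list(voxel_size), "n_acidic": n_acidic,
        "centres": centres, "kinds": kinds,
    })
    return stack, mask, gt


# --------------------------------------------------------------------------
# Blot lane densities

def gen_lane_densities(true_relative: dict[str, tuple[float, float]],
                       noise_cv: float = 0.0, seed: int = 0,
                       wt_label: str = "WT",
                       base: tuple = (100.0, 10.0, 60.0, 60.0)
                       ) -> tuple[list[blots.LaneDensities], GroundTruth]:
    """Invert the blot normalization chain: construct lane densities whose
    noise-free normalization recovers the requested (lc3b_rel, ub_rel).

    ``true_relative`` maps construct label -> relative binding pair; the WT
    entry, if present, must be (1, 1).  ``base`` gives the WT lane's
    (glutathione, control, lc3b, ubiquitin) areas.  Multiplicative lognormal
    noise of coefficient of variation ``noise_cv`` is applied per band.
    """
    if wt_label in true_relative and true_relative[wt_label] != (1.0, 1.0):
        raise ValueError("wild-type relative binding is (1, 1) by definition")
    g0, c0, l0, u0 = base
    if not (g0 > c0 and l0 > c0 and u0 > c0):
        raise ValueError("base WT densities must exceed the control density")
    rng = np.random.default_rng(seed)
    lanes = []
    order = [wt_label] + [k for k in true_relative if k != wt_label]
    for construct in order:
        lr, ur = (1.0, 1.0) if construct == wt_label else true_relative[construct]
        dens = {"glutathione": g0, "control": c0,
                "lc3b": c0 + lr * (l0 - c0), "ubiquitin": c0 + ur * (u0 - c0)}
        if noise_cv > 0:
            sd = np.sqrt(np.log1p(noise_cv ** 2))
            for k in dens:
                dens[k] *= rng.lognormal(-sd * sd / 2, sd)
        lanes.append(blots.LaneDensities(construct, **dens))
    gt = GroundTruth("gen_lane_densities", seed, {
        "true_relative": {k: list(v) for k, v in true_relative.items()},
        "noise_cv": noise_cv, "base": list(base), "wt_label": wt_label,
    })
    return lanes, gt
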
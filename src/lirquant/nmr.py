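"""HSQC chemical-shift-perturbation (CSP) mapping.

A ligand-induced CSP for a backbone amide is the weighted Euclidean shift

    ddHSQC = sqrt(ddH**2 + (ddN/5)**2)

with the 1/5 nitrogen scaling reflecting the ~5x larger ppm dispersion of the
15N dimension.  The module pairs free and bound peak lists, computes
per-residue CSP profiles, classifies residues by perturbation magnitude
(moderate > 0.5 ppm, strong > 1.0 ppm by default, strict inequalities),
forms WT-minus-mutant differential maps, and writes class codes into the
B-factor column of a PDB file for structure colouring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi

__all__ = [
    "HSQCPeak",
    "PeakList",
    "CSPProfile",
    "ResidueClassMap",
    "weighted_csp",
    "track_peaks",
    "csp_profile",
    "classify_residues",
    "differential_csp",
    "write_structure_map",
    "N_SCALE",
]

#: Default nitrogen down-weighting in the combined CSP.
N_SCALE = 1.0 / 5.0

_AMIDE_H_RANGE = (5.0, 12.0)
_AMIDE_N_RANGE = (100.0, 135.0)


@dataclass(frozen=True)
class HSQCPeak:
    residue_id: int
    residue_name: str
    dH: float  # 1H shift, ppm
    dN: float  # 15N shift, ppm

    def warn_if_outside_amide_region(self) -> None:
        if not (_AMIDE_H_RANGE[0] < self.dH < _AMIDE_H_RANGE[1]) or \
           not (_AMIDE_N_RANGE[0] < self.dN < _AMIDE_N_RANGE[1]):
            warnings.warn(f"peak {self.residue_id}{self.residue_name} at "
                          f"({self.dH}, {self.dN}) ppm lies outside the typical "
                          "backbone amide region")


@dataclass(frozen=True)
class PeakList:
    """One HSQC peak list (one titration condition)."""

    condition: str
    peaks: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        ids = [p.residue_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate residue_ids in peak list: {dupes}")

    def by_residue(self) -> dict[int, HSQCPeak]:
        return {p.residue_id: p for p in self.peaks}


@dataclass(frozen=True)
class CSPProfile:
    """Per-residue weighted CSPs (ppm); residues absent from either input
    list are *missing* from the map, never zero-filled."""

    values: dict[int, float]
    condition: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("weighted CSPs are magnitudes and must be >= 0")

    def residues(self) -> list[int]:
        return sorted(self.values)


@dataclass(frozen=True)
class ResidueClassMap:
    classes: dict[int, str]  # residue_id -> none|moderate|strong
    moderate_threshold: float
    strong_threshold: float

    def count(self, cls: str) -> int:
        return sum(1 for c in self.classes.values() if c == cls)


def weighted_csp(dH_shift: float, dN_shift: float, n_scale: float = N_SCALE) -> float:
    """Combined amide CSP: sqrt(ddH^2 + (n_scale*ddN)^2); sign-symmetric."""
    return math.hypot(dH_shift, n_scale * dN_shift)


def track_peaks(reference: PeakList, shifted: PeakList,
                unlabeled: bool = False) -> list[tuple[HSQCPeak, HSQCPeak]]:
    """Pair reference and shifted peaks.

    Labelled mode (default) pairs by residue_id.  Unlabeled mode ignores the
    shifted list's identities and assigns each reference peak its nearest
    shifted peak in the (1, 1/5)-weighted shift metric, greedily (smallest
    distances first) under a one-to-one constraint — the standard strategy
    for following peaks through a titration when assignments of the end
    point are not yet transferred.
    """
    if not reference.peaks or not shifted.peaks:
        raise ValueError("both peak lists must be non-empty")
    if not unlabeled:
        shifted_map = shifted.by_residue()
        return [(p, shifted_map[p.residue_id]) for p in reference.peaks
                if p.residue_id in shifted_map]

    dists = []
    for i, p in enumerate(reference.peaks):
        for j, q in enumerate(shifted.peaks):
            dists.append((weighted_csp(q.dH - p.dH, q.dN - p.dN), i, j))
    dists.sort()
    used_ref: set[int] = set()
    used_shift: set[int] = set()
    pairs: list[tuple[HSQCPeak, HSQCPeak]] = []
    for _, i, j in dists:
        if i in used_ref or j in used_shift:
            continue
        used_ref.add(i)
        used_shift.add(j)
        pairs.append((reference.peaks[i], shifted.peaks[j]))
    pairs.sort(key=lambda pq: pq[0].residue_id)
    return pairs


def csp_profile(free: PeakList, bound: PeakList) -> CSPProfile:
    """Weighted CSP per residue shared between a free and a bound list."""
    pairs = track_peaks(free, bound)
    if not pairs:
        raise ValueError(f"peak lists {free.condition!r} and {bound.condition!r} "
                         "share no residues")
    values = {p.residue_id: weighted_csp(q.dH - p.dH, q.dN - p.dN) for p, q in pairs}
    return CSPProfile(values=values, condition=bound.condition)


def classify_residues(p: CSPProfile, moderate_threshold: float = 0.5,
                      strong_threshold: float = 1.0) -> ResidueClassMap:
    """Classify residues by CSP magnitude with strict (>) thresholds."""
    if not (0 < moderate_threshold < strong_threshold):
        raise ValueError("require 0 < moderate_threshold < strong_threshold")
    classes = {}
    for rid, v in p.values.items():
        if v > strong_threshold:
            classes[rid] = "strong"
        elif v > moderate_threshold:
            classes[rid] = "moderate"
        else:
            classes[rid] = "none"
    return ResidueClassMap(classes, moderate_threshold, strong_threshold)


def differential_csp(profile_WT: CSPProfile, profile_mut: CSPProfile) -> CSPProfile:
    """Signed WT-minus-mutant CSP difference per shared residue.

    The returned profile stores |difference| (a CSPProfile is a magnitude
    map); the signed values are available via the companion dict in
    ``signed_differential_csp``.
    """
    signed = signed_differential_csp(profile_WT, profile_mut)
    return CSPProfile(values={r: abs(v) for r, v in signed.items()},
                      condition="differential")


def signed_differential_csp(profile_WT: CSPProfile, profile_mut: CSPProfile) -> dict[int, float]:
    shared = set(profile_WT.values) & set(profile_mut.values)
    if not shared:
        raise ValueError("profiles share no residues")
    return {r: profile_WT.values[r] - profile_mut.values[r] for r in sorted(shared)}


_CLASS_CODE = {"none": 0.0, "moderate": 1.0, "strong": 2.0}


def write_structure_map(classes: ResidueClassMap, structure_path: str,
                        out_path: str) -> None:
    """Write per-residue class codes (0/1/2) into the B-factor column of a
    copy of a PDB file; residues not in the map get 0.

    Residue matching is by author sequence number across all chains.
    """
    st = gemmi.read_structure(str(structure_path))
    mapped = 0
    for model in st:
        for chain in model:
            for residue in chain:
                code = 0.0
                rid = residue.seqid.num
                if rid in classes.classes:
                    code = _CLASS_CODE[classes.classes[rid]]
                    mapped += 1
                for atom in residue:
                    atom.b_iso = code
    if classes.classes and mapped == 0:
        raise ValueError("no residue numbers in the class map match the structure")
    st.write_pdb(str(out_path))
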
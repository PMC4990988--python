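"""Densitometry normalization for affinity-isolation (pull-down) blots.

Each construct contributes one set of band areas: glutathione beads (capture
of the GST fusion itself), control beads (nonspecific background), and the
two interaction targets (LC3B beads, ubiquitin beads).  The normalization
chain is: subtract the control area from every specific-bead area, divide
each target by the construct's own glutathione area (input normalization),
then divide by the wild-type construct's normalized value so WT reads 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LaneDensities", "NormalizedBinding", "normalize_lanes"]


@dataclass(frozen=True)
class LaneDensities:
    """Band areas (arbitrary densitometry units, >= 0) for one construct."""

    construct: str
    glutathione: float
    control: float
    lc3b: float
    ubiquitin: float

    def __post_init__(self) -> None:
        for name in ("glutathione", "control", "lc3b", "ubiquitin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} density must be >= 0")

    @property
    def valid(self) -> bool:
        """Capture signal must exceed background for the lane to be usable."""
        return self.glutathione > self.control


@dataclass(frozen=True)
class NormalizedBinding:
    construct: str
    lc3b_rel: float
    ubiquitin_rel: float


def normalize_lanes(lanes: list[LaneDensities], wt_label: str = "WT") -> list[NormalizedBinding]:
    """Background-subtract, input-normalize, and express relative to WT.

    Lanes whose control signal reaches the glutathione signal carry no usable
    capture information and are rejected with a diagnostic.
    """
    by_construct = {lane.construct: lane for lane in lanes}
    if wt_label not in by_construct:
        raise ValueError(f"wild-type label {wt_label!r} not among constructs "
                         f"{sorted(by_construct)}")
    rejected = [l.construct for l in lanes if not l.valid]
    if rejected:
        raise ValueError("lanes with control >= glutathione signal (no usable "
                         f"capture): {rejected}")

    def ratios(lane: LaneDensities) -> tuple[float, float]:
        g = lane.glutathione - lane.control
        return ((lane.lc3b - lane.control) / g,
                (lane.ubiquitin - lane.control) / g)

    wt_lc3b, wt_ub = ratios(by_construct[wt_label])
    if wt_lc3b == 0 or wt_ub == 0:
        raise ValueError("wild-type lane has zero normalized signal; cannot "
                         "express mutants relative to it")
    out = []
    for lane in lanes:
        l, u = ratios(lane)
        out.append(NormalizedBinding(lane.construct, l / wt_lc3b, u / wt_ub))
    return out
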
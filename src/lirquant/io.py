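"""Plain-text I/O for the package's tabular formats (all CSV)."""

from __future__ import annotations

import pandas as pd

from . import blots, coloc, itc, ms, nmr

__all__ = [
    "write_heats", "read_heats",
    "write_spectrum", "read_spectrum",
    "write_peaklist", "read_peaklist",
    "write_csp_profile", "read_csp_profile",
    "write_pcc_results", "read_pcc_results",
    "read_lanes", "write_normalized",
]


def write_heats(data: itc.InjectionHeats, path: str) -> None:
    pd.DataFrame({"molar_ratio": data.molar_ratio,
                  "heat_ucal": data.heats}).to_csv(path, index=False)


def read_heats(path: str) -> itc.InjectionHeats:
    df = pd.read_csv(path)
    return itc.InjectionHeats(heats=tuple(df["heat_ucal"]),
                              molar_ratio=tuple(df["molar_ratio"]))


def write_spectrum(s: ms.Spectrum, path: str) -> None:
    pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(path, index=False)


def read_spectrum(path: str) -> ms.Spectrum:
    df = pd.read_csv(path)
    return ms.Spectrum(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_peaklist(pl: nmr.PeakList, path: str) -> None:
    pd.DataFrame([{"residue_id": p.residue_id, "residue_name": p.residue_name,
                   "dH_ppm": p.dH, "dN_ppm": p.dN} for p in pl.peaks]
                 ).to_csv(path, index=False)


def read_peaklist(path: str, condition: str = "") -> nmr.PeakList:
    df = pd.read_csv(path)
    peaks = [nmr.HSQCPeak(int(r.residue_id), str(r.residue_name),
                          float(r.dH_ppm), float(r.dN_ppm))
             for r in df.itertuples()]
    return nmr.PeakList(condition=condition, peaks=peaks)


def write_csp_profile(p: nmr.CSPProfile, path: str) -> None:
    pd.DataFrame({"residue_id": p.residues(),
                  "csp_ppm": [p.values[r] for r in p.residues()]}
                 ).to_csv(path, index=False)


def read_csp_profile(path: str, condition: str = "") -> nmr.CSPProfile:
    df = pd.read_csv(path)
    return nmr.CSPProfile(values={int(r.residue_id): float(r.csp_ppm)
                                  for r in df.itertuples()},
                          condition=condition)


def write_pcc_results(results: list[coloc.PCCResult], path: str) -> None:
    pd.DataFrame([{"cell_id": r.cell_id, "condition": r.condition,
                   "pcc_thresholded": r.pcc, "pcc_global": r.pcc_global,
                   "t_green": r.threshold_green, "t_red": r.threshold_red,
                   "voxels": r.voxels_used} for r in results]
                 ).to_csv(path, index=False)


def read_pcc_results(path: str) -> list[coloc.PCCResult]:
    df = pd.read_csv(path)
    return [coloc.PCCResult(str(r.cell_id), str(r.condition),
                            float(r.pcc_thresholded), float(r.pcc_global),
                            float(r.t_green), float(r.t_red), int(r.voxels))
            for r in df.itertuples()]


def read_lanes(path: str) -> list[blots.LaneDensities]:
    df = pd.read_csv(path)
    return [blots.LaneDensities(str(r.construct), float(r.glutathione),
                                float(r.control), float(r.lc3b),
                                float(r.ubiquitin)) for r in df.itertuples()]


def write_normalized(rows: list[blots.NormalizedBinding], path: str) -> None:
    pd.DataFrame([{"construct": r.construct, "target": t, "relative_binding": v}
                  for r in rows
                  for t, v in (("LC3B", r.lc3b_rel), ("ubiquitin", r.ubiquitin_rel))]
                 ).to_csv(path, index=False)
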
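"""Two-channel colocalization via Costes automatic thresholding and Pearson
correlation, with per-condition group statistics.

The Costes procedure fits an orthogonal (total-least-squares) regression
ch2 = a*ch1 + b through all voxels, then walks a candidate threshold T1 down
through the sorted unique intensities of channel 1 (T2 = a*T1 + b) and keeps
the largest pair for which the voxels *below both* thresholds are
uncorrelated or anticorrelated (r <= 0).  The per-cell Pearson coefficient is
then computed over voxels above both thresholds within the cell mask
("thresholded" mode); a whole-mask "global" PCC is co-reported.

Group comparison implements a one-way fixed-effects analysis of variance from
the group sums of squares, with all pairwise mean contrasts and Sidak
multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ImageStack",
    "PCCResult",
    "GroupStats",
    "pearson",
    "costes_thresholds",
    "analyze_cell",
    "compare_groups",
]

#: Minimum voxels for a defined correlation.
MIN_VOXELS = 20


@dataclass(frozen=True)
class ImageStack:
    """Registered two-channel 3-D stack (z, y, x) with voxel size in µm."""

    channel_green: np.ndarray
    channel_red: np.ndarray
    voxel_size: tuple = (0.2, 0.1, 0.1)

    def __post_init__(self) -> None:
        g = np.asarray(self.channel_green, dtype=float)
        r = np.asarray(self.channel_red, dtype=float)
        if g.shape != r.shape:
            raise ValueError("channel shapes differ")
        if g.min() < 0 or r.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "channel_green", g)
        object.__setattr__(self, "channel_red", r)


@dataclass(frozen=True)
class PCCResult:
    cell_id: str
    condition: str
    pcc: float                 # thresholded-mode PCC (or global if requested)
    pcc_global: float
    threshold_green: float
    threshold_red: float
    voxels_used: int
    undefined: bool = False


@dataclass(frozen=True)
class GroupStats:
    conditions: tuple
    means: dict
    sems: dict
    n_cells: dict
    f_statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)  # (a, b, diff, p_raw, p_adj)
    adjustment: str = "sidak"


def pearson(ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson product-moment correlation over masked voxels.

    Returns NaN (undefined-result marker) when fewer than two voxels are
    selected or either channel has zero variance under the mask.
    """
    x = np.asarray(ch1, dtype=float)
    y = np.asarray(ch2, dtype=float)
    if mask is not None:
        x, y = x[mask], y[mask]
    else:
        x, y = x.ravel(), y.ravel()
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    x = x - x.mean()
    y = y - y.mean()
    return float(np.dot(x, y) / math.sqrt(np.dot(x, x) * np.dot(y, y)))


def _orthogonal_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = a*x + b via the principal axis of the
    centred covariance matrix."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("orthogonal regression undefined for a constant channel")
    cov = np.cov(np.vstack([x, y]))
    # Principal eigenvector of the 2x2 covariance.
    tr, det = cov[0, 0] + cov[1, 1], cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    lam = tr / 2 + math.sqrt(max(tr * tr / 4 - det, 0.0))
    if cov[0, 1] == 0:
        a = math.inf if cov[1, 1] > cov[0, 0] else 0.0
    else:
        a = (lam - cov[0, 0]) / cov[0, 1]
    b = y.mean() - a * x.mean()
    return a, b


def costes_thresholds(ch1: np.ndarray, ch2: np.ndarray,
                      mask: np.ndarray | None = None) -> tuple[float, float, bool]:
    """Costes automatic threshold pair for two channels.

    Returns ``(t1, t2, found)``; ``found`` is False when no candidate drives
    the sub-threshold correlation to <= 0, in which case the channel minima
    are returned with a warning flag rather than an error.
    """
    x = np.asarray(ch1, dtype=float)
    y = np.asarray(ch2, dtype=float)
    if mask is not None:
        x, y = x[mask], y[mask]
    else:
        x, y = x.ravel(), y.ravel()
    a, b = _orthogonal_regression(x, y)

    for t1 in np.unique(x)[::-1]:
        t2 = a * t1 + b
        below = (x < t1) & (y < t2)
        if below.sum() < 2:
            continue
        r = pearson(x, y, below)
        if math.isnan(r) or r <= 0:
            return float(t1), float(t2), True
    return float(x.min()), float(y.min()), False


def analyze_cell(stack: ImageStack, cell_mask: np.ndarray,
                 cell_id: str = "", condition: str = "",
                 method: str = "costes_thresholded") -> PCCResult:
    """Per-cell PCC with Costes thresholding.

    ``method`` selects which PCC populates the primary ``pcc`` field;
    both the thresholded and the whole-mask (global) value are recorded.
    """
    if method not in ("costes_thresholded", "global"):
        raise ValueError("method must be 'costes_thresholded' or 'global'")
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        return PCCResult(cell_id, condition, math.nan, math.nan, math.nan,
                         math.nan, 0, undefined=True)
    g, r = stack.channel_green, stack.channel_red
    pcc_global = pearson(g, r, mask)
    tg, tr_, _found = costes_thresholds(g, r, mask)
    above = mask & (g > tg) & (r > tr_)
    n_above = int(above.sum())
    if n_above < MIN_VOXELS:
        pcc_thr = math.nan
    else:
        pcc_thr = pearson(g, r, above)
    primary = pcc_thr if method == "costes_thresholded" else pcc_global
    return PCCResult(cell_id, condition, primary, pcc_global, float(tg),
                     float(tr_), n_above, undefined=not math.isfinite(primary))


def compare_groups(results: list[PCCResult], alpha: float = 0.05,
                   use_global: bool = False) -> GroupStats:
    """One-way ANOVA across conditions plus Sidak-adjusted pairwise contrasts.

    The F statistic is formed from the between/within sums of squares;
    pairwise contrasts are two-sided t tests on the pooled within-group
    variance, adjusted as p_adj = 1 - (1 - p)^m for m comparisons.
    """
    groups: dict[str, list[float]] = {}
    for res in results:
        v = res.pcc_global if use_global else res.pcc
        if math.isfinite(v):
            groups.setdefault(res.condition, []).append(v)
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 cells")
        if len(vals) < 50:
            import warnings
            warnings.warn(f"condition {cond!r} has {len(vals)} cells "
                          "(fewer than the 50 recommended per condition)")

    conds = tuple(sorted(groups))
    arrs = {c: np.asarray(groups[c]) for c in conds}
    n_tot = sum(a.size for a in arrs.values())
    grand = sum(a.sum() for a in arrs.values()) / n_tot
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b, df_w = len(conds) - 1, n_tot - len(conds)
    ms_within = ss_within / df_w
    if ms_within == 0:
        # degenerate: no within-group variance; F is 0/0 for identical
        # groups (no effect) and an infinite sentinel otherwise
        f_stat, p_val = (0.0, 1.0) if ss_between == 0 else (math.inf, 0.0)
    else:
        f_stat = (ss_between / df_b) / ms_within
        p_val = float(stats.f.sf(f_stat, df_b, df_w))

    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        xa, xb = arrs[a], arrs[b]
        diff = xa.mean() - xb.mean()
        if ms_within == 0:
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(ms_within * (1 / xa.size + 1 / xb.size))
            t = diff / se
            p_raw = float(2 * stats.t.sf(abs(t), df_w))
        p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)
        pairwise.append((a, b, float(diff), p_raw, p_adj))

    return GroupStats(
        conditions=conds,
        means={c: float(arrs[c].mean()) for c in conds},
        sems={c: float(arrs[c].std(ddof=1) / math.sqrt(arrs[c].size)) for c in conds},
        n_cells={c: int(arrs[c].size) for c in conds},
        f_statistic=float(f_stat),
        p_value=p_val,
        pairwise=pairwise,
    )


def two_way_anova(values: np.ndarray, factor_a: np.ndarray,
                  factor_b: np.ndarray) -> dict:
    """Balanced two-factor fixed-effects ANOVA from sums of squares.

    Used for replicate blot quantifications (construct x binding target).
    Returns F statistics and p values for both main effects and the
    interaction.  Requires a balanced design (equal replicates per cell).
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    la, lb = np.unique(fa), np.unique(fb)
    cells = {}
    for a in la:
        for b in lb:
            cell = values[(fa == a) & (fb == b)]
            if cell.size == 0:
                raise ValueError(f"empty design cell ({a}, {b})")
            cells[a, b] = cell
    sizes = {len(c) for c in cells.values()}
    if len(sizes) != 1:
        raise ValueError("two_way_anova requires a balanced design")
    r = sizes.pop()
    if r < 2:
        raise ValueError("need >= 2 replicates per cell for the interaction term")
    grand = values.mean()
    ss_a = r * len(lb) * sum((values[fa == a].mean() - grand) ** 2 for a in la)
    ss_b = r * len(la) * sum((values[fb == b].mean() - grand) ** 2 for b in lb)
    ss_ab = r * sum((cells[a, b].mean() - values[fa == a].mean()
                     - values[fb == b].mean() + grand) ** 2
                    for a in la for b in lb)
    ss_err = sum(((cells[a, b] - cells[a, b].mean()) ** 2).sum()
                 for a in la for b in lb)
    df_a, df_b = len(la) - 1, len(lb) - 1
    df_ab = df_a * df_b
    df_err = len(la) * len(lb) * (r - 1)
    ms_err = ss_err / df_err
    out = {}
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AB", ss_ab, df_ab)):
        if ms_err == 0:
            f, p = (math.inf, 0.0) if ss > 0 else (0.0, 1.0)
        else:
            f = (ss / df) / ms_err if df > 0 else math.nan
            p = float(stats.f.sf(f, df, df_err)) if df > 0 else math.nan
        out[name] = {"ss": float(ss), "df": df, "F": float(f), "p": p}
    out["error"] = {"ss": float(ss_err), "df": df_err}
    return out
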
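"""Relatedness heatmaps and phenotypic correlation by degree of relatedness.

The phenotype-by-degree summary enumerates unordered within-family pairs
with both phenotype values observed, bins them by their relatedness
coefficient, and reports the double-entered Pearson correlation per bin —
each pair enters both ways, (x, y) and (y, x), so the estimate is symmetric
in pair order — with a 95% confidence interval from the Fisher z transform
using the number of *unique* pairs as n: z = atanh(r), half-width =
z_crit / sqrt(n - 3).  Under a purely additive polygenic model the expected
bin correlation is relatedness x h^2 (e.g. 0.30 for parent-offspring pairs
at h^2 = 0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .config import PlotConfig
from .ped_model import PedigreeTable, assign_families
from .relatedness import RelatednessMatrix, additive_matrix


class NoEstimableBinsError(ValueError):
    def __init__(self):
        super().__init__("NO_ESTIMABLE_BINS: no relatedness bin reaches minPairs")


def cluster_order(mat: RelatednessMatrix, method: str = "average") -> List[int]:
    """Dendrogram leaf order from agglomerative clustering on 1 - coefficient.

    The distance 1 - r is clamped at 0 (inbred diagonals exceed 1); the
    returned permutation reorders rows and columns so related blocks sit
    together.
    """
    n = len(mat.ids)
    if n <= 1:
        return list(range(n))
    if not np.allclose(mat.values, mat.values.T):
        raise ValueError("relatedness matrix must be symmetric")
    dist = np.clip(1.0 - mat.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    link = sch.linkage(squareform(dist, checks=False), method=method)
    return list(sch.leaves_list(link))


def heatmap(mat: RelatednessMatrix, cluster: bool = False,
            cfg: Optional[PlotConfig] = None, path: Optional[str] = None):
    """Heatmap of a relatedness matrix, optionally clustered; returns Figure."""
    if cfg is None:
        cfg = PlotConfig()
    if not np.allclose(mat.values, mat.values.T):
        raise ValueError("relatedness matrix must be symmetric")
    order = cluster_order(mat, cfg.get("heatmap.clusterMethod")) if cluster \
        else list(range(len(mat.ids)))
    values = mat.values[np.ix_(order, order)]
    ids = [mat.ids[i] for i in order]

    fig, ax = plt.subplots(figsize=(cfg.get("canvas.width"),
                                    cfg.get("canvas.height")))
    vmax = cfg.get("heatmap.vmax")
    im = ax.imshow(values, cmap=cfg.get("heatmap.cmap"),
                   vmin=cfg.get("heatmap.vmin"),
                   vmax=None if vmax < 0 else vmax,
                   interpolation="nearest", aspect="equal")
    if cfg.get("heatmap.showTicks") and len(ids) <= 60:
        ax.set_xticks(range(len(ids)))
        ax.set_yticks(range(len(ids)))
        ax.set_xticklabels(ids, rotation=90,
                           fontsize=cfg.get("heatmap.tickFontSize"))
        ax.set_yticklabels(ids, fontsize=cfg.get("heatmap.tickFontSize"))
    else:
        ax.set_xticks([])
        ax.set_yticks([])
    if cfg.get("heatmap.showColorbar"):
        fig.colorbar(im, ax=ax, label=cfg.get("heatmap.colorbarLabel"))
    if cfg.get("canvas.title"):
        ax.set_title(cfg.get("canvas.title"))
    fig._pedivis_leaf_order = order  # exposed for tests and callers
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig


@dataclass
class DegreeBin:
    relatedness: float
    degreeLabel: str
    nPairs: int           # unique pairs
    r: float              # double-entered Pearson correlation (nan if undefined)
    ciLow: float
    ciHigh: float
    pairs: List[Tuple[str, str]] = field(default_factory=list)


@dataclass
class DegreeSummary:
    bins: List[DegreeBin]
    phenotype: str
    minPairs: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"relatedness": b.relatedness, "degreeLabel": b.degreeLabel,
             "nPairs": b.nPairs, "r": b.r, "ciLow": b.ciLow, "ciHigh": b.ciHigh}
            for b in self.bins
        ])


def _degree_label(value: float) -> str:
    if value <= 0:
        return "unrelated"
    k = -math.log2(value)
    if abs(k - round(k)) < 1e-6:
        k = int(round(k))
        names = {0: "self/MZ", 1: "1st degree", 2: "2nd degree",
                 3: "3rd degree"}
        return names.get(k, f"{k}th degree")
    return f"r={value:g}"


def _snap_dyadic(value: float, tol: float) -> float:
    if value <= 0:
        return value
    k = round(-math.log2(value))
    if k >= 0 and abs(value - 2.0 ** (-k)) <= tol:
        return 2.0 ** (-k)
    return value


def double_entry_correlation(pairs: np.ndarray) -> float:
    """Pearson correlation after entering each (x, y) pair both ways."""
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_ci(r: float, n_unique: int, level: float = 0.95
              ) -> Tuple[float, float]:
    """CI for a correlation via atanh(r) +- z_crit / sqrt(n - 3)."""
    if n_unique <= 3 or not np.isfinite(r) or abs(r) >= 1:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    hw = norm.ppf(0.5 + level / 2.0) / math.sqrt(n_unique - 3)
    return (math.tanh(z - hw), math.tanh(z + hw))


def phenotype_by_degree(ped: PedigreeTable, phenotype: str,
                        mat: Optional[RelatednessMatrix] = None,
                        binRule: str = "exact",
                        cfg: Optional[PlotConfig] = None,
                        make_figure: bool = True):
    """Per-relatedness-bin familial correlations with Fisher-z intervals.

    Returns ``(DegreeSummary, Figure or None)``.  Bins below ``minPairs``
    unique pairs keep their correlation but carry no interval; if no bin
    reaches ``minPairs`` a :class:`NoEstimableBinsError` is raised.
    """
    if cfg is None:
        cfg = PlotConfig()
    if binRule not in ("exact", "dyadic"):
        raise ValueError(f"binRule must be 'exact' or 'dyadic', got {binRule!r}")
    min_pairs = cfg.get("pbd.minPairs")
    level = cfg.get("pbd.ciLevel")
    tol = cfg.get("pbd.dyadicTolerance")

    if any(ind.famID is None for ind in ped):
        ped = assign_families(ped)
    if mat is None:
        mat = additive_matrix(ped)

    observed = [(ind.personID, ind.famID, ind.phenotypes[phenotype])
                for ind in ped if phenotype in ind.phenotypes]
    if len(observed) < 2:
        raise ValueError(f"phenotype {phenotype!r} observed for <2 individuals")

    groups: Dict[float, List[Tuple[str, str, float, float]]] = {}
    fams: Dict[str, List[Tuple[str, float]]] = {}
    for pid, fam, v in observed:
        fams.setdefault(fam, []).append((pid, v))
    for members in fams.values():
        members = sorted(members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                (pi, vi), (pj, vj) = members[a], members[b]
                rel_v = mat.loc(pi, pj)
                key = round(rel_v, 9)
                if binRule == "dyadic":
                    key = _snap_dyadic(key, tol)
                groups.setdefault(key, []).append((pi, pj, vi, vj))

    bins: List[DegreeBin] = []
    for key in sorted(groups):
        entries = groups[key]
        arr = np.array([(vi, vj) for _, _, vi, vj in entries])
        r = double_entry_correlation(arr)
        n = len(entries)
        if n >= min_pairs:
            lo, hi = fisher_ci(r, n, level)
        else:
            lo, hi = float("nan"), float("nan")
        bins.append(DegreeBin(
            relatedness=float(key), degreeLabel=_degree_label(float(key)),
            nPairs=n, r=r, ciLow=lo, ciHigh=hi,
            pairs=[(pi, pj) for pi, pj, _, _ in entries]))
    if not any(b.nPairs >= min_pairs for b in bins):
        raise NoEstimableBinsError()
    summary = DegreeSummary(bins=bins, phenotype=phenotype, minPairs=min_pairs)

    fig = None
    if make_figure:
        fig, ax = plt.subplots(figsize=(cfg.get("canvas.width"),
                                        cfg.get("canvas.height")))
        xs = [b.relatedness for b in bins if np.isfinite(b.r)]
        rs = [b.r for b in bins if np.isfinite(b.r)]
        ax.plot(xs, rs, "-", color=cfg.get("pbd.lineColor"))
        ax.scatter(xs, rs, s=cfg.get("pbd.pointSize"),
                   color=cfg.get("pbd.lineColor"), zorder=3)
        band = [b for b in bins if np.isfinite(b.ciLow)]
        if band:
            ax.fill_between([b.relatedness for b in band],
                            [b.ciLow for b in band],
                            [b.ciHigh for b in band],
                            color=cfg.get("pbd.ribbonColor"),
                            alpha=cfg.get("pbd.ribbonAlpha"))
        if cfg.get("pbd.showCounts"):
            for b in bins:
                if np.isfinite(b.r):
                    ax.annotate(f"n={b.nPairs}", (b.relatedness, b.r),
                                textcoords="offset points", xytext=(4, 6),
                                fontsize=7)
        ax.set_xlabel(cfg.get("pbd.xLabel"))
        ax.set_ylabel(cfg.get("pbd.yLabel"))
        ax.axhline(0, color="#999999", linewidth=0.7)
    return summary, fig
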
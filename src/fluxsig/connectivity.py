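"""Metabolite connectivity distributions.

The connectivity of a metabolite is the number of reactions it
participates in — its degree in the bipartite metabolite-reaction graph.
Ranking metabolites from most to least connected gives a discrete
distribution whose shape distinguishes densely wired genome-scale
networks from sparser single-compartment ones. A log-log reference line
through the most- and least-connected points serves as the comparison
baseline: points above it indicate higher connectivity than the
two-endpoint trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .model_core import MetabolicModel, identify_exchange_reactions


@dataclass(frozen=True)
class ConnectivityDistribution:
    """Rank-ordered (rank, connectivity) points for one network."""

    points: Tuple[Tuple[int, int], ...]
    network_id: str = ""
    metabolite_order: Tuple[str, ...] = ()

    def __post_init__(self):
        ranks = [r for r, _ in self.points]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be contiguous from 1")
        conns = [c for _, c in self.points]
        if any(a < b for a, b in zip(conns, conns[1:])):
            raise ValueError("connectivity must be non-increasing in rank")


def metabolite_connectivity(
    model: MetabolicModel, include_exchanges: bool = True
) -> Dict[str, int]:
    """Number of reactions each metabolite participates in.

    Exchange pseudo-reactions count by default (``include_exchanges``
    turns them off). Metabolites in no reaction get 0.
    """
    skip = set() if include_exchanges else set(identify_exchange_reactions(model))
    counts = {m.id: 0 for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.id in skip:
            continue
        for mid, coef in rxn.stoichiometry.items():
            if coef != 0 and mid in counts:
                counts[mid] += 1
    return counts


def rank_distribution(
    connectivity_map: Dict[str, int],
    network_id: str = "",
    drop_zero: bool = True,
) -> ConnectivityDistribution:
    """Sort metabolites from most to least connected.

    Ties are broken by metabolite id so the ranking is deterministic.
    Zero-connectivity metabolites are excluded by default (they carry no
    edges and break the log-scale reference line); set ``drop_zero``
    False to keep them.
    """
    if not connectivity_map:
        raise ValueError("empty connectivity map")
    items = sorted(connectivity_map.items(), key=lambda kv: (-kv[1], kv[0]))
    if drop_zero:
        items = [kv for kv in items if kv[1] > 0]
    if not items:
        raise ValueError("no metabolite with non-zero connectivity")
    return ConnectivityDistribution(
        points=tuple((i + 1, c) for i, (_, c) in enumerate(items)),
        network_id=network_id,
        metabolite_order=tuple(mid for mid, _ in items),
    )


@dataclass(frozen=True)
class ReferenceLine:
    """Straight line through the extreme points, in log10-log10 space."""

    slope: float
    intercept: float
    classification: Tuple[str, ...]  # above | on | below, per point

    @property
    def fraction_above(self) -> float:
        return sum(c == "above" for c in self.classification) / len(self.classification)


def reference_line(
    distribution: ConnectivityDistribution,
    scale: str = "log10",
    tol: float = 1e-9,
) -> ReferenceLine:
    """Line linking the maximum- and minimum-connectivity points.

    Drawn through (rank 1, c_max) and (rank N, c_min), by default in
    log10 rank vs log10 connectivity space; each point is classified as
    above, on, or below the line. Requires at least two distinct ranks
    and strictly positive connectivities (filter orphans first).
    """
    pts = distribution.points
    if len(pts) < 2:
        raise ValueError("need at least two points for a reference line")
    if any(c <= 0 for _, c in pts):
        raise ValueError("zero connectivity present; filter orphans before drawing the line")
    if scale == "log10":
        xy = [(math.log10(r), math.log10(c)) for r, c in pts]
    elif scale == "linear":
        xy = [(float(r), float(c)) for r, c in pts]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    x0, y0 = xy[0]
    x1, y1 = xy[-1]
    slope = (y1 - y0) / (x1 - x0)
    intercept = y0 - slope * x0
    labels: List[str] = []
    for x, y in xy:
        resid = y - (slope * x + intercept)
        if resid > tol:
            labels.append("above")
        elif resid < -tol:
            labels.append("below")
        else:
            labels.append("on")
    return ReferenceLine(slope=slope, intercept=intercept, classification=tuple(labels))


def compartment_subnetwork(model: MetabolicModel, compartment: str) -> MetabolicModel:
    """Restrict the network to one compartment's metabolites.

    Keeps only metabolites of the given compartment, truncates each
    reaction's stoichiometry to them, and drops reactions that lose all
    participants — mirroring how single-organelle subnetworks are carved
    out of a multi-compartment reconstruction.
    """
    keep = {m.id for m in model.metabolites if m.compartment == compartment}
    if not keep:
        raise ValueError(f"no metabolites in compartment {compartment!r}")
    metabolites = [m for m in model.metabolites if m.id in keep]
    reactions = []
    for rxn in model.reactions:
        stoich = {mid: c for mid, c in rxn.stoichiometry.items() if mid in keep}
        if not stoich:
            continue
        r = rxn.copy()
        r.stoichiometry = stoich
        reactions.append(r)
    return MetabolicModel(
        id=f"{model.id}[{compartment}]",
        metabolites=metabolites,
        reactions=reactions,
        genes=list(model.genes),
    )


def plot_distribution(
    distributions,
    path,
    scale: str = "log10",
) -> None:
    """Plot one or more rank-connectivity distributions with their
    reference lines to ``path`` (matplotlib, optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(distributions, ConnectivityDistribution):
        distributions = [distributions]
    fig, ax = plt.subplots(figsize=(5, 4))
    for dist in distributions:
        ranks = [r for r, _ in dist.points]
        conns = [c for _, c in dist.points]
        ax.plot(ranks, conns, "o", ms=3, label=dist.network_id or None)
        ax.plot([ranks[0], ranks[-1]], [conns[0], conns[-1]], "k--", lw=0.8)
    if scale == "log10":
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("metabolite rank")
    ax.set_ylabel("connectivity")
    if any(d.network_id for d in distributions):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
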
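"""In-silico knockout screening of exchange-flux biomarker signatures.

A disease variant or drug is simulated by closing the reactions it
disables: for a gene loss, every reaction whose GPR evaluates False with
the targets knocked out gets bounds (0, 0); for direct enzyme inhibition
the listed reactions are closed. FVA of the exchange reactions before and
after the perturbation is then compared.

An exchange reaction is *differentially active* when its minimum or
maximum flux moves by at least a fraction theta (default 0.40) of its
unperturbed flux span |max - min|. Each differential exchange is given a
single category:

* ``activity_change`` — the exchange switches between active and
  inactive (both endpoints ~0);
* ``direction_fixed`` — a previously bidirectional exchange becomes
  uptake-only or secretion-only;
* ``magnitude_change`` — the range shrinks or shifts without either of
  the above.

The set of differential exchanges is the condition's *metabolic
signature*; a condition is *detected* when the signature is non-empty.
Signature uniqueness across conditions measures how specific a biomarker
readout the network can provide.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .gpr import GPRNode
from .lp_engine import TAU_ZERO, FluxRange, InfeasibleModelError, flux_variability
from .model_core import MetabolicModel, identify_exchange_reactions

logger = logging.getLogger(__name__)

#: default differential-activity threshold (fraction of flux span)
THETA_DEFAULT = 0.40

CATEGORIES = ("activity_change", "direction_fixed", "magnitude_change", "unaffected")


@dataclass(frozen=True)
class Perturbation:
    """One simulated condition: a gene loss or a direct enzyme inhibition."""

    condition_id: str
    kind: str  # gene_loss | reaction_inhibition
    targets: Tuple[str, ...]
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("gene_loss", "reaction_inhibition"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not self.targets:
            raise ValueError(f"{self.condition_id}: empty target list")


@dataclass(frozen=True)
class ExchangeDelta:
    """Normal-vs-perturbed comparison for one exchange reaction."""

    reaction_id: str
    normal: FluxRange
    perturbed: FluxRange
    differential: bool
    category: str
    relative_change: float


@dataclass(frozen=True)
class MetabolicSignature:
    """The differential exchange set of one condition."""

    condition_id: str
    members: frozenset
    detected: bool

    @staticmethod
    def from_members(condition_id: str, members: Iterable[str]) -> "MetabolicSignature":
        ms = frozenset(members)
        return MetabolicSignature(condition_id=condition_id, members=ms, detected=bool(ms))


@dataclass
class ScreenResult:
    signatures: List[MetabolicSignature]
    deltas: Dict[str, List[ExchangeDelta]]
    threshold: float
    warnings: List[str] = field(default_factory=list)

    @property
    def detection_fraction(self) -> float:
        """Fraction of conditions with a non-empty signature (NaN if none)."""
        if not self.signatures:
            return float("nan")
        return sum(s.detected for s in self.signatures) / len(self.signatures)

    @property
    def mean_signature_size(self) -> float:
        """Mean number of differential exchanges over detected conditions."""
        sizes = [len(s.members) for s in self.signatures if s.detected]
        if not sizes:
            return float("nan")
        return sum(sizes) / len(sizes)


def evaluate_gpr(gpr: GPRNode, knocked_genes: Iterable[str]) -> bool:
    """Evaluate a GPR with the knocked genes False and all others True.

    Knocked genes the rule never mentions are ignored with a warning.
    """
    knocked = set(knocked_genes)
    unknown = knocked - set(gpr.genes)
    if unknown:
        logger.warning("GPR does not mention knocked genes %s", sorted(unknown))
    return gpr.evaluate(knocked)


def apply_perturbation(
    model: MetabolicModel, perturbation: Perturbation
) -> Tuple[MetabolicModel, List[str]]:
    """Return a perturbed copy of the model and the ids of closed reactions.

    The affected reactions get bounds (0, 0); the input model is never
    mutated. A perturbation that disables no reaction at all is flagged
    with a warning (the condition is undetectable by construction).
    """
    perturbed = model.copy()
    closed: List[str] = []
    if perturbation.kind == "gene_loss":
        knocked = set(perturbation.targets)
        model_genes = set(model.gene_ids)
        missing = knocked - model_genes
        if missing:
            logger.warning(
                "%s: target genes %s not in model", perturbation.condition_id, sorted(missing)
            )
        for rxn in perturbed.reactions:
            if rxn.gpr is not None and not rxn.gpr.evaluate(knocked):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
                closed.append(rxn.id)
    else:
        rids = set(perturbation.targets)
        missing = rids - set(model.reaction_ids)
        if missing:
            raise KeyError(
                f"{perturbation.condition_id}: unknown reactions {sorted(missing)}"
            )
        for rxn in perturbed.reactions:
            if rxn.id in rids:
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
                closed.append(rxn.id)
    if not closed:
        logger.warning(
            "%s disables no reaction; condition undetectable by construction",
            perturbation.condition_id,
        )
    return perturbed, closed


def _active(fr: FluxRange, tau_zero: float) -> bool:
    return abs(fr.minimum) > tau_zero or abs(fr.maximum) > tau_zero


def _one_signed(fr: FluxRange, tau_zero: float) -> bool:
    return fr.minimum >= -tau_zero or fr.maximum <= tau_zero


def classify_exchange_change(
    normal: FluxRange,
    perturbed: FluxRange,
    theta: float = THETA_DEFAULT,
    tau_zero: float = TAU_ZERO,
    tau_abs: float = 1e-3,
) -> ExchangeDelta:
    """Compare one exchange reaction's normal and perturbed flux ranges.

    The differential statistic is max(|d_min|, |d_max|) divided by the
    unperturbed span; the exchange is differential when it reaches
    ``theta``. When the normal span is smaller than ``tau_abs`` the ratio
    is undefined and an absolute test at ``tau_abs`` is used instead.
    Categories follow the precedence activity_change > direction_fixed >
    magnitude_change so each delta gets a single label.
    """
    span = normal.span
    d_min = abs(perturbed.minimum - normal.minimum)
    d_max = abs(perturbed.maximum - normal.maximum)
    d = max(d_min, d_max)
    if span >= tau_abs:
        relative_change = d / span
        differential = relative_change >= theta
    else:
        differential = d >= tau_abs
        relative_change = math.inf if differential else 0.0

    if not differential:
        category = "unaffected"
    elif _active(normal, tau_zero) != _active(perturbed, tau_zero):
        category = "activity_change"
    elif not _one_signed(normal, tau_zero) and _one_signed(perturbed, tau_zero):
        category = "direction_fixed"
    else:
        category = "magnitude_change"

    return ExchangeDelta(
        reaction_id=normal.reaction_id,
        normal=normal,
        perturbed=perturbed,
        differential=differential,
        category=category,
        relative_change=relative_change,
    )


def _deltas_to_signature(
    condition_id: str, deltas: Sequence[ExchangeDelta]
) -> MetabolicSignature:
    return MetabolicSignature.from_members(
        condition_id, (d.reaction_id for d in deltas if d.differential)
    )


def perturbed_exchange_ranges(
    model: MetabolicModel,
    perturbation: Perturbation,
    exchanges: Optional[Sequence[str]] = None,
) -> Tuple[Optional[Dict[str, FluxRange]], List[str]]:
    """FVA of the exchange reactions under one perturbation.

    Returns (ranges, warnings); ranges is None when the perturbed model is
    infeasible.
    """
    warnings: List[str] = []
    exchanges = list(exchanges) if exchanges is not None else identify_exchange_reactions(model)
    perturbed_model, closed = apply_perturbation(model, perturbation)
    if not closed:
        warnings.append(f"{perturbation.condition_id}: no reaction disabled")
    try:
        ranges = flux_variability(perturbed_model, reaction_subset=exchanges)
    except InfeasibleModelError as exc:
        warnings.append(f"{perturbation.condition_id}: perturbed model infeasible ({exc})")
        return None, warnings
    return ranges, warnings


def screen_condition(
    model: MetabolicModel,
    perturbation: Perturbation,
    theta: float = THETA_DEFAULT,
    normal_ranges: Optional[Dict[str, FluxRange]] = None,
    tau_zero: float = TAU_ZERO,
    tau_abs: Optional[float] = None,
) -> Tuple[MetabolicSignature, List[ExchangeDelta]]:
    """Screen one condition: exchange FVA normal vs perturbed.

    ``normal_ranges`` may be passed to reuse the unperturbed FVA across
    conditions. If the perturbed model is infeasible every exchange is
    reported as an activity change (the cell state is unreachable) and
    the infeasibility is logged.
    """
    exchanges = identify_exchange_reactions(model)
    if normal_ranges is None:
        normal_ranges = flux_variability(model, reaction_subset=exchanges)
    if tau_abs is None:
        tau_abs = _default_tau_abs(model)
    perturbed_ranges, warnings = perturbed_exchange_ranges(model, perturbation, exchanges)
    for w in warnings:
        logger.warning("%s", w)
    deltas: List[ExchangeDelta] = []
    if perturbed_ranges is None:
        for rid in exchanges:
            nr = normal_ranges[rid]
            deltas.append(
                ExchangeDelta(
                    reaction_id=rid,
                    normal=nr,
                    perturbed=FluxRange(rid, 0.0, 0.0),
                    differential=True,
                    category="activity_change",
                    relative_change=math.inf,
                )
            )
    else:
        for rid in exchanges:
            deltas.append(
                classify_exchange_change(
                    normal_ranges[rid], perturbed_ranges[rid],
                    theta=theta, tau_zero=tau_zero, tau_abs=tau_abs,
                )
            )
    return _deltas_to_signature(perturbation.condition_id, deltas), deltas


def _default_tau_abs(model: MetabolicModel) -> float:
    largest = max(
        (max(abs(r.lower_bound), abs(r.upper_bound)) for r in model.reactions),
        default=1.0,
    )
    return 1e-6 * max(largest, 1.0)


def screen_all(
    model: MetabolicModel,
    perturbations: Sequence[Perturbation],
    theta: float = THETA_DEFAULT,
    tau_zero: float = TAU_ZERO,
) -> ScreenResult:
    """Screen a list of conditions against one normal state.

    The unperturbed exchange FVA is computed once and shared. The result
    carries one signature per condition plus the per-condition deltas;
    detection fraction and mean signature size are exposed as properties
    (NaN on an empty condition list).
    """
    exchanges = identify_exchange_reactions(model)
    normal_ranges = flux_variability(model, reaction_subset=exchanges)
    tau_abs = _default_tau_abs(model)
    signatures: List[MetabolicSignature] = []
    deltas: Dict[str, List[ExchangeDelta]] = {}
    warnings: List[str] = []
    for pert in perturbations:
        sig, dl = screen_condition(
            model, pert, theta=theta,
            normal_ranges=normal_ranges, tau_zero=tau_zero, tau_abs=tau_abs,
        )
        signatures.append(sig)
        deltas[pert.condition_id] = dl
    if not perturbations:
        warnings.append("empty condition list: detection fraction undefined (NaN)")
    return ScreenResult(signatures=signatures, deltas=deltas, threshold=theta, warnings=warnings)


def uniqueness_histogram(signatures: Sequence[MetabolicSignature]) -> Dict[int, int]:
    """Histogram of signature multiplicity over detected conditions.

    Groups detected conditions by exact member-set equality; maps each
    multiplicity k to the number of distinct signatures shared by exactly
    k conditions.
    """
    groups = Counter(s.members for s in signatures if s.detected)
    hist: Dict[int, int] = {}
    for k in groups.values():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def unique_fraction(histogram: Dict[int, int]) -> float:
    """Fraction of distinct signatures carried by a single condition."""
    total = sum(histogram.values())
    if total == 0:
        raise ValueError("empty signature histogram")
    return histogram.get(1, 0) / total


@dataclass(frozen=True)
class SweepPoint:
    theta: float
    detection_fraction: float
    mean_signature_size: float
    mean_differential_count: float


def threshold_sweep(
    model: MetabolicModel,
    perturbations: Sequence[Perturbation],
    theta_grid: Sequence[float],
    tau_zero: float = TAU_ZERO,
) -> List[SweepPoint]:
    """Re-screen the same conditions over a grid of thresholds.

    The per-condition FVA is computed once; only the classification is
    repeated per theta, so the sweep costs one screen. Differential
    counts and detection are non-increasing in theta by construction.
    """
    for th in theta_grid:
        if not (0 < th <= 1):
            raise ValueError(f"theta {th} outside (0, 1]")
    exchanges = identify_exchange_reactions(model)
    normal_ranges = flux_variability(model, reaction_subset=exchanges)
    tau_abs = _default_tau_abs(model)
    per_condition: List[Optional[Dict[str, FluxRange]]] = []
    for pert in perturbations:
        ranges, warnings = perturbed_exchange_ranges(model, pert, exchanges)
        for w in warnings:
            logger.warning("%s", w)
        per_condition.append(ranges)
    points: List[SweepPoint] = []
    for th in theta_grid:
        sizes: List[int] = []
        for ranges in per_condition:
            if ranges is None:
                sizes.append(len(exchanges))
                continue
            n_diff = sum(
                classify_exchange_change(
                    normal_ranges[rid], ranges[rid],
                    theta=th, tau_zero=tau_zero, tau_abs=tau_abs,
                ).differential
                for rid in exchanges
            )
            sizes.append(n_diff)
        detected = [s for s in sizes if s > 0]
        n = len(sizes)
        points.append(
            SweepPoint(
                theta=th,
                detection_fraction=(len(detected) / n) if n else float("nan"),
                mean_signature_size=(sum(detected) / len(detected)) if detected else float("nan"),
                mean_differential_count=(sum(sizes) / n) if n else float("nan"),
            )
        )
    return points
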
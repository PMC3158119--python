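"""Synthetic fixture networks, planted ground truth, and a brute-force
FVA oracle.

The generators build small mass-balanced networks from flux-consistent
motifs — uptake chains feeding a shared hub with one secretion outlet —
rather than sampling raw random stoichiometries (a random S is almost
always completely blocked and useless for flux analysis). Each internal
reaction carries a GPR, so gene-knockout screens have a known planted
answer: a gene is detectable exactly when it is the sole catalytic
support of a reaction on the only route between an uptake exchange and
the hub.

``oracle_fva`` verifies the LP implementation independently: it
enumerates candidate vertices of the flux polytope {S v = 0, lb <= v <=
ub} directly with dense linear algebra and takes per-coordinate extrema.
It shares no code with the LP engine.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .gpr import GPRNode, parse_gpr
from .lp_engine import FluxRange
from .model_core import (
    DEFAULT_BOUND,
    Gene,
    Metabolite,
    MetabolicModel,
    Reaction,
    _metabolites_from_reactions,
)
from .annotation_crossref import (
    CAUSALITIES,
    DRUG_STATUSES,
    AnnotationRecord,
)

#: organ-system chapters used for mock annotation categories
CATEGORY_LABELS = (
    "Pediatric Disorders",
    "Endocrine and Metabolic Disorders",
    "Neurologic Disorders",
    "Genitourinary Disorders",
    "Eye Disorders",
    "Musculoskeletal and Connective Tissue Disorders",
    "Gastrointestinal Disorders",
    "Hepatic and Biliary Disorders",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the random network generator."""

    seed: int
    n_pathways: int = 3
    pathway_length: int = 2
    n_isozyme_reactions: int = 1
    uptake_cap: float = 10.0
    bound_cap: float = DEFAULT_BOUND
    fraction_reversible: float = 0.0

    def __post_init__(self):
        if self.n_pathways < 1 or self.pathway_length < 1:
            raise ValueError("need at least one pathway of length >= 1")
        if self.n_isozyme_reactions < 0:
            raise ValueError("n_isozyme_reactions must be >= 0")
        if self.uptake_cap <= 0 or self.bound_cap <= 0:
            raise ValueError("caps must be positive")
        if not (0 <= self.fraction_reversible <= 1):
            raise ValueError("fraction_reversible must lie in [0, 1]")
        if self.bound_cap < self.n_pathways * self.uptake_cap:
            raise ValueError(
                "bound_cap must cover the summed uptake so the hub outlet "
                "never saturates (keeps planted truths exact)"
            )
        if self.n_isozyme_reactions > self.n_pathways * self.pathway_length:
            raise ValueError("more isozyme reactions than internal reactions")


@dataclass(frozen=True)
class PlantedTruth:
    """Expected screen outcome for knocking out one gene."""

    gene_id: str
    detectable: bool
    expected_signature: FrozenSet[str]


def _met_names(count: int) -> List[str]:
    letters = string.ascii_uppercase
    if count <= len(letters):
        return [letters[i] for i in range(count)]
    return [f"M{i + 1}" for i in range(count)]


def make_linear_pathway(n_internal: int, uptake_cap: float = 10.0) -> MetabolicModel:
    """A linear chain: uptake -> M1 -> ... -> Mn+1 -> secretion.

    Every internal reaction converts one metabolite into the next, is
    irreversible with bounds (0, 1000), and carries a unique single-gene
    GPR (g1, g2, ...). The uptake exchange is capped at ``uptake_cap``,
    so every internal FVA range is (0, uptake_cap). ``n_internal = 1``
    with cap 10 is the two-metabolite fixture TOY1.
    """
    if n_internal < 1:
        raise ValueError("need at least one internal reaction")
    names = _met_names(n_internal + 1)
    mets = [Metabolite(id=f"{nm}[c]", name=f"{nm}[c]", compartment="c") for nm in names]
    reactions = [
        Reaction(
            id=f"EX_{names[0]}",
            name=f"EX_{names[0]}",
            stoichiometry={mets[0].id: -1.0},
            lower_bound=-uptake_cap,
            upper_bound=0.0,
        )
    ]
    genes = []
    for k in range(n_internal):
        gid = f"g{k + 1}"
        genes.append(Gene(id=gid))
        reactions.append(
            Reaction(
                id=f"R{k + 1}",
                name=f"R{k + 1}",
                stoichiometry={mets[k].id: -1.0, mets[k + 1].id: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                gpr=parse_gpr(gid),
            )
        )
    reactions.append(
        Reaction(
            id=f"EX_{names[-1]}",
            name=f"EX_{names[-1]}",
            stoichiometry={mets[-1].id: -1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
    )
    return MetabolicModel(
        id="TOY1" if n_internal == 1 else f"linear-{n_internal}",
        metabolites=mets,
        reactions=reactions,
        genes=genes,
    )


def make_branched_network(
    uptake_cap: float = 10.0, bound_cap: float = DEFAULT_BOUND
) -> MetabolicModel:
    """The branched fixture TOY2: A splits into B and C.

    EX_A caps uptake; R_AB and R_AC compete for A; EX_B and EX_C secrete.
    Planted truth: inhibiting R_AB zeroes EX_B while EX_A and EX_C keep
    their full ranges through the other branch, so at theta = 0.4 the
    knockout signature is exactly {EX_B}.
    """
    mets = [Metabolite(id=f"{n}[c]", name=f"{n}[c]", compartment="c") for n in "ABC"]
    a, b, c = (m.id for m in mets)
    reactions = [
        Reaction(id="EX_A", name="EX_A", stoichiometry={a: -1.0},
                 lower_bound=-uptake_cap, upper_bound=0.0),
        Reaction(id="R_AB", name="R_AB", stoichiometry={a: -1.0, b: 1.0},
                 lower_bound=0.0, upper_bound=bound_cap, gpr=parse_gpr("gAB")),
        Reaction(id="R_AC", name="R_AC", stoichiometry={a: -1.0, c: 1.0},
                 lower_bound=0.0, upper_bound=bound_cap, gpr=parse_gpr("gAC")),
        Reaction(id="EX_B", name="EX_B", stoichiometry={b: -1.0},
                 lower_bound=0.0, upper_bound=bound_cap),
        Reaction(id="EX_C", name="EX_C", stoichiometry={c: -1.0},
                 lower_bound=0.0, upper_bound=bound_cap),
    ]
    return MetabolicModel(
        id="TOY2",
        metabolites=mets,
        reactions=reactions,
        genes=[Gene(id="gAB"), Gene(id="gAC")],
    )


def make_random_network(
    spec: SyntheticSpec, theta: float = 0.40
) -> Tuple[MetabolicModel, Dict[str, PlantedTruth]]:
    """A seeded multi-pathway network with per-gene planted truth.

    ``n_pathways`` uptake chains of ``pathway_length`` reactions feed a
    shared hub metabolite drained by one secretion exchange. A random
    subset of internal reactions receives an isozyme GPR ("gX or gY"),
    making their genes individually undetectable. The planted truth maps
    each gene to whether a single-gene knockout is detectable at the
    given theta and, if so, to its exact expected signature. Generation
    is bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    hub = Metabolite(id="H[c]", name="H[c]", compartment="c")
    reactions: List[Reaction] = []
    genes: List[Gene] = []
    internal_ids: List[str] = []
    pathway_of: Dict[str, int] = {}

    for p in range(spec.n_pathways):
        chain = [
            Metabolite(id=f"P{p + 1}M{k + 1}[c]", name=f"P{p + 1}M{k + 1}[c]", compartment="c")
            for k in range(spec.pathway_length)
        ]
        reactions.append(
            Reaction(
                id=f"EX_P{p + 1}",
                name=f"EX_P{p + 1}",
                stoichiometry={chain[0].id: -1.0},
                lower_bound=-spec.uptake_cap,
                upper_bound=0.0,
            )
        )
        for k in range(spec.pathway_length):
            src = chain[k].id
            dst = chain[k + 1].id if k + 1 < spec.pathway_length else hub.id
            gid = f"gP{p + 1}R{k + 1}"
            genes.append(Gene(id=gid))
            rid = f"P{p + 1}R{k + 1}"
            reversible = bool(rng.random() < spec.fraction_reversible)
            reactions.append(
                Reaction(
                    id=rid,
                    name=rid,
                    stoichiometry={src: -1.0, dst: 1.0},
                    lower_bound=-spec.bound_cap if reversible else 0.0,
                    upper_bound=spec.bound_cap,
                    gpr=parse_gpr(gid),
                )
            )
            internal_ids.append(rid)
            pathway_of[rid] = p

    reactions.append(
        Reaction(
            id="EX_H", name="EX_H",
            stoichiometry={hub.id: -1.0},
            lower_bound=0.0, upper_bound=spec.bound_cap,
        )
    )
    # metabolite order follows first appearance across the reaction list,
    # matching what tabular round-tripping reconstructs
    mets = _metabolites_from_reactions(reactions)

    iso_targets = set()
    if spec.n_isozyme_reactions:
        iso_targets = set(
            rng.choice(internal_ids, size=spec.n_isozyme_reactions, replace=False)
        )
    iso_genes: List[Gene] = []
    model = MetabolicModel(id=f"synth-{spec.seed}", metabolites=mets,
                           reactions=reactions, genes=genes)
    for i, rid in enumerate(sorted(iso_targets)):
        rxn = model.get_reaction(rid)
        ga, gb = f"gIso{i + 1}a", f"gIso{i + 1}b"
        rxn.gpr = parse_gpr(f"{ga} or {gb}")
        iso_genes.extend([Gene(id=ga), Gene(id=gb)])
    # replace genes displaced by isozyme decoration
    displaced = {f"gP{pathway_of[rid] + 1}R{rid.split('R')[-1]}" for rid in iso_targets}
    model.genes = [g for g in genes if g.id not in displaced] + iso_genes

    # planted truth: a sole-support gene on pathway p kills EX_Pp outright;
    # the hub outlet loses only 1/n_pathways of its span
    hub_hit = (1.0 / spec.n_pathways) >= theta
    truths: Dict[str, PlantedTruth] = {}
    for rid in internal_ids:
        p = pathway_of[rid]
        rxn = model.get_reaction(rid)
        sole = len(rxn.gpr.genes) == 1
        expected = frozenset(
            {f"EX_P{p + 1}"} | ({"EX_H"} if hub_hit else set())
        )
        for gid in rxn.gpr.genes:
            truths[gid] = PlantedTruth(
                gene_id=gid,
                detectable=sole,
                expected_signature=expected if sole else frozenset(),
            )
    return model, truths


def make_mock_annotations(
    model: MetabolicModel,
    n_snps: int = 100,
    n_drugs: int = 100,
    match_rate: float = 0.6,
    seed: int = 0,
) -> Tuple[List[AnnotationRecord], Dict[str, object]]:
    """Mock disease-variant and drug-target annotation rows.

    Each row names one gene: a model gene with probability
    ``match_rate``, otherwise a synthetic foreign id. Categories and
    causality/status labels are drawn from fixed label sets. Returns the
    rows plus the planted bookkeeping (matched counts and category
    marginals) so recovery can be asserted exactly.
    """
    if not (0 <= match_rate <= 1):
        raise ValueError("match_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    model_genes = sorted(
        {g for r in model.reactions if r.gpr is not None for g in r.gpr.genes}
    )
    if not model_genes and match_rate > 0:
        raise ValueError("model carries no GPR genes to match against")
    records: List[AnnotationRecord] = []
    planted = {
        "matched_snps": 0,
        "matched_drugs": 0,
        "category_marginals": {},
        "matched_condition_ids": [],
    }

    def draw_gene(i: int) -> Tuple[str, bool]:
        if rng.random() < match_rate:
            return str(rng.choice(model_genes)), True
        return f"FOREIGN_{i:04d}", False

    for i in range(n_snps):
        gene, matched = draw_gene(i)
        category = str(rng.choice(CATEGORY_LABELS))
        rec = AnnotationRecord(
            gene_id=gene,
            condition_id=f"SNP_{i:04d}",
            condition_name=f"disorder {i}",
            source="morbid_snp",
            category=category,
            causality=str(rng.choice(CAUSALITIES)),
        )
        records.append(rec)
        if matched:
            planted["matched_snps"] += 1
            planted["matched_condition_ids"].append(rec.condition_id)
            planted["category_marginals"][category] = (
                planted["category_marginals"].get(category, 0) + 1
            )
    for i in range(n_drugs):
        gene, matched = draw_gene(n_snps + i)
        category = str(rng.choice(CATEGORY_LABELS))
        rec = AnnotationRecord(
            gene_id=gene,
            condition_id=f"DRUG_{i:04d}",
            condition_name=f"compound {i}",
            source="drug",
            status=str(rng.choice(DRUG_STATUSES)),
            category=category,
        )
        records.append(rec)
        if matched:
            planted["matched_drugs"] += 1
            planted["matched_condition_ids"].append(rec.condition_id)
            planted["category_marginals"][category] = (
                planted["category_marginals"].get(category, 0) + 1
            )
    return records, planted


# ---------------------------------------------------------------------------
# Brute-force FVA oracle
# ---------------------------------------------------------------------------

ORACLE_MAX_REACTIONS = 8
_ORACLE_TOL = 1e-7


def oracle_fva(model: MetabolicModel) -> Dict[str, FluxRange]:
    """Exact FVA by exhaustive vertex enumeration (networks of <= 8 reactions).

    Every vertex of the bounded polytope {S v = 0, lb <= v <= ub} has at
    least n - rank(S) coordinates pinned at a bound. The oracle tries all
    such pinnings, solves the remaining square-ish linear system densely,
    keeps the feasible solutions, and reports per-coordinate extrema. An
    infeasible model yields an empty map. Independent of the LP engine by
    construction.
    """
    n = len(model.reactions)
    if n > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"oracle handles at most {ORACLE_MAX_REACTIONS} reactions, got {n}"
        )
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    m = len(met_index)
    S = np.zeros((m, n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for mid, coef in rxn.stoichiometry.items():
            S[met_index[mid], j] = coef
    scale = max(1.0, np.abs(S).max(initial=0.0), np.abs(lb).max(initial=0.0),
                np.abs(ub).max(initial=0.0))
    tol = _ORACLE_TOL * scale

    rank = int(np.linalg.matrix_rank(S, tol=1e-10)) if S.size else 0
    n_free = n - rank

    def feasible(v: np.ndarray) -> bool:
        return (
            np.all(v >= lb - tol)
            and np.all(v <= ub + tol)
            and (S.size == 0 or np.abs(S @ v).max(initial=0.0) <= tol)
        )

    vertices: List[np.ndarray] = []
    if n_free == 0:
        v = np.zeros(n)  # S v = 0 with full column rank forces v = 0
        if feasible(v):
            vertices.append(v)
    else:
        for fixed_idx in itertools.combinations(range(n), n_free):
            free_idx = [j for j in range(n) if j not in fixed_idx]
            for choice in itertools.product((0, 1), repeat=n_free):
                v = np.full(n, np.nan)
                for j, c in zip(fixed_idx, choice):
                    v[j] = lb[j] if c == 0 else ub[j]
                rhs = -S[:, list(fixed_idx)] @ v[list(fixed_idx)]
                sol, *_ = np.linalg.lstsq(S[:, free_idx], rhs, rcond=None)
                v[free_idx] = sol
                if feasible(v):
                    vertices.append(v)
    if not vertices:
        return {}
    V = np.array(vertices)
    out: Dict[str, FluxRange] = {}
    for j, rxn in enumerate(model.reactions):
        lo = float(np.clip(V[:, j].min(), lb[j], ub[j]))
        hi = float(np.clip(V[:, j].max(), lb[j], ub[j]))
        out[rxn.id] = FluxRange(reaction_id=rxn.id, minimum=lo, maximum=hi)
    return out
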
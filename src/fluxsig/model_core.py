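"""Core data structures and I/O for constraint-based metabolic models.

A model is a set of metabolites (compartment-qualified, e.g. ``glc[c]``),
reactions with flux bounds and optional gene-protein-reaction rules, and
genes. The stoichiometric matrix S (metabolites x reactions) encodes the
mass-balance structure; under the steady-state assumption S.v = 0 the
network can be interrogated with linear programming without kinetics.

Exchange reactions are single-metabolite pseudo-reactions written as
``M ->`` so that positive flux is secretion and negative flux is uptake.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import scipy.sparse as sp

from .gpr import GPRNode, GPRSyntaxError, parse_gpr

logger = logging.getLogger(__name__)

#: default flux cap (the de-facto COBRA convention) applied when a file
#: carries no explicit bounds; keeps every LP bounded.
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Structured model/file error; ``context`` names the offending element."""

    def __init__(self, message: str, context: str = ""):
        super().__init__(message if not context else f"{context}: {message}")
        self.context = context


@dataclass
class Metabolite:
    """A compartment-qualified chemical species (one row of S)."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None


@dataclass
class Reaction:
    """A biochemical transformation (one column of S).

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed). Reversibility is derived: a reaction is
    reversible exactly when its lower bound is negative.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gpr: Optional[GPRNode] = None
    subsystem: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass(frozen=True)
class Gene:
    """An open reading frame referenced by GPR rules."""

    id: str
    name: Optional[str] = None


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites, reactions and genes."""

    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def gene_ids(self) -> List[str]:
        return [g.id for g in self.genes]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
        )


@dataclass
class StoichiometricMatrix:
    """Sparse m x n stoichiometric matrix with identifier maps.

    ``matrix`` is a scipy CSC matrix; rows follow the model's metabolite
    order, columns its reaction order. Stored entries are non-zero.
    """

    matrix: sp.csc_matrix
    row_ids: List[str]
    col_ids: List[str]

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def nnz(self) -> int:
        return self.matrix.nnz

    @property
    def density(self) -> float:
        """Fraction of non-zero entries (0 for an empty matrix)."""
        size = self.m * self.n
        return self.nnz / size if size else 0.0

    def entry(self, met_id: str, rxn_id: str) -> float:
        i = self.row_ids.index(met_id)
        j = self.col_ids.index(rxn_id)
        return float(self.matrix[i, j])


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: a machine code, the subject id, and prose."""

    code: str
    subject: str
    message: str


# ---------------------------------------------------------------------------
# Matrix assembly and structural queries
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S from the model, preserving metabolite/reaction order."""
    row_ids = model.metabolite_ids
    col_ids = model.reaction_ids
    index = {mid: i for i, mid in enumerate(row_ids)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            if coef == 0:
                continue
            if mid not in index:
                raise ModelError(
                    f"stoichiometry references unknown metabolite {mid!r}",
                    context=rxn.id,
                )
            rows.append(index[mid])
            cols.append(j)
            data.append(float(coef))
    matrix = sp.csc_matrix(
        (data, (rows, cols)), shape=(len(row_ids), len(col_ids))
    )
    matrix.eliminate_zeros()
    return StoichiometricMatrix(matrix=matrix, row_ids=row_ids, col_ids=col_ids)


def identify_exchange_reactions(model: MetabolicModel) -> List[str]:
    """Reactions involving exactly one metabolite, in model order.

    These move a species across the system boundary; by the network-wide
    sign convention (``M ->``) positive flux is secretion, negative uptake.
    """
    return [r.id for r in model.reactions if len(r.stoichiometry) == 1]


def validate_model(model: MetabolicModel) -> List[Diagnostic]:
    """Structural diagnostics; an empty list means the model is clean.

    Dead-end metabolites are reported, never removed: a network may
    legitimately carry detected-but-nonfunctional enzymes.
    """
    out: List[Diagnostic] = []
    met_ids = model.metabolite_ids
    seen = set()
    for mid in met_ids:
        if mid in seen:
            out.append(Diagnostic("duplicate-metabolite", mid, "duplicate metabolite id"))
        seen.add(mid)
    rxn_seen = set()
    for r in model.reactions:
        if r.id in rxn_seen:
            out.append(Diagnostic("duplicate-reaction", r.id, "duplicate reaction id"))
        rxn_seen.add(r.id)
        if r.lower_bound > r.upper_bound:
            out.append(
                Diagnostic(
                    "bound-order", r.id,
                    f"lower bound {r.lower_bound} exceeds upper bound {r.upper_bound}",
                )
            )
        if not r.stoichiometry:
            out.append(Diagnostic("empty-stoichiometry", r.id, "reaction has no participants"))
        for mid in r.stoichiometry:
            if mid not in seen:
                out.append(
                    Diagnostic("dangling-metabolite", r.id, f"references unknown metabolite {mid!r}")
                )
    gene_ids = set(model.gene_ids)
    for r in model.reactions:
        if r.gpr is not None:
            for g in r.gpr.genes:
                if g not in gene_ids:
                    out.append(
                        Diagnostic("unknown-gene", r.id, f"GPR references unlisted gene {g!r}")
                    )
    # dead ends: metabolites appearing in < 2 reactions
    participation: Dict[str, int] = {mid: 0 for mid in met_ids}
    for r in model.reactions:
        for mid in r.stoichiometry:
            if mid in participation:
                participation[mid] += 1
    for mid, k in participation.items():
        if k == 0:
            out.append(Diagnostic("orphan-metabolite", mid, "metabolite occurs in no reaction"))
        elif k == 1:
            out.append(Diagnostic("dead-end-metabolite", mid, "metabolite occurs in a single reaction"))
    return out


# ---------------------------------------------------------------------------
# Tabular (TSV) dialect
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = [
    "reaction_id", "reaction_name", "formula",
    "lower_bound", "upper_bound", "gpr", "subsystem",
]

_MET_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")
_COMPARTMENT = re.compile(r"^(.*)\[([^\[\]]+)\]$")


def _parse_side(side: str, sign: float, stoich: Dict[str, float], context: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelError("empty term in reaction formula", context=context)
        m = _MET_TOKEN.match(term)
        if m is None:
            raise ModelError(f"unparseable term {term!r}", context=context)
        coef = float(m.group(1)) if m.group(1) else 1.0
        mid = m.group(2)
        stoich[mid] = stoich.get(mid, 0.0) + sign * coef


def parse_reaction_formula(formula: str, context: str = "") -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 A[c] + B[c] -> C[e]"`` into a stoichiometry map.

    Returns (stoichiometry, reversible-arrow?). ``<=>`` marks a reversible
    arrow, ``->`` an irreversible one; an empty side denotes the boundary.
    """
    if "<=>" in formula:
        lhs, rhs = formula.split("<=>", 1)
        rev = True
    elif "->" in formula:
        lhs, rhs = formula.split("->", 1)
        rev = False
    else:
        raise ModelError(f"no reaction arrow in formula {formula!r}", context=context)
    stoich: Dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich, context)
    _parse_side(rhs, +1.0, stoich, context)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelError(f"formula {formula!r} has no net participants", context=context)
    return stoich, rev


def format_reaction_formula(rxn: Reaction) -> str:
    lhs = []
    rhs = []
    for mid, coef in rxn.stoichiometry.items():
        side = lhs if coef < 0 else rhs
        mag = abs(coef)
        token = mid if mag == 1 else f"{mag:g} {mid}"
        side.append(token)
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _compartment_of(met_id: str) -> str:
    m = _COMPARTMENT.match(met_id)
    return m.group(2) if m else "c"


def _metabolites_from_reactions(reactions: Sequence[Reaction]) -> List[Metabolite]:
    order: List[str] = []
    seen = set()
    for r in reactions:
        for mid in r.stoichiometry:
            if mid not in seen:
                seen.add(mid)
                order.append(mid)
    return [Metabolite(id=mid, name=mid, compartment=_compartment_of(mid)) for mid in order]


def _genes_from_reactions(reactions: Sequence[Reaction]) -> List[Gene]:
    order: List[str] = []
    seen = set()
    for r in reactions:
        if r.gpr is None:
            continue
        for g in sorted(r.gpr.genes):
            if g not in seen:
                seen.add(g)
                order.append(g)
    return [Gene(id=g) for g in order]


def read_tabular_model(path, model_id: Optional[str] = None) -> MetabolicModel:
    """Read the TSV model dialect (one reaction per row).

    Columns: reaction_id, reaction_name, formula, lower_bound, upper_bound,
    gpr, subsystem. Empty bounds default to -1000/1000 for a ``<=>`` arrow
    and 0/1000 for ``->``. Metabolites and genes are collected from the
    formulas and GPR rules.
    """
    path = str(path)
    reactions: List[Reaction] = []
    seen_ids = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(TABULAR_COLUMNS)] != TABULAR_COLUMNS:
            raise ModelError(
                f"unexpected header {header!r}; expected {TABULAR_COLUMNS}", context=path
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            parts += [""] * (len(TABULAR_COLUMNS) - len(parts))
            rid, rname, formula, lb_s, ub_s, gpr_s, subsystem = parts[: len(TABULAR_COLUMNS)]
            ctx = f"{path}:{lineno}"
            if not rid:
                raise ModelError("missing reaction_id", context=ctx)
            if rid in seen_ids:
                raise ModelError(f"duplicate reaction id {rid!r}", context=ctx)
            seen_ids.add(rid)
            stoich, rev_arrow = parse_reaction_formula(formula, context=ctx)
            lb = float(lb_s) if lb_s else (-DEFAULT_BOUND if rev_arrow else 0.0)
            ub = float(ub_s) if ub_s else DEFAULT_BOUND
            gpr = None
            if gpr_s.strip():
                try:
                    gpr = parse_gpr(gpr_s)
                except GPRSyntaxError as exc:
                    raise ModelError(f"bad GPR: {exc}", context=ctx) from exc
            reactions.append(
                Reaction(
                    id=rid, name=rname, stoichiometry=stoich,
                    lower_bound=lb, upper_bound=ub, gpr=gpr,
                    subsystem=subsystem or None,
                )
            )
    return MetabolicModel(
        id=model_id or re.sub(r"\.\w+$", "", path.rsplit("/", 1)[-1]),
        metabolites=_metabolites_from_reactions(reactions),
        reactions=reactions,
        genes=_genes_from_reactions(reactions),
    )


def write_tabular_model(model: MetabolicModel, path) -> None:
    """Write the TSV model dialect; inverse of :func:`read_tabular_model`."""
    with open(str(path), "w") as fh:
        fh.write("\t".join(TABULAR_COLUMNS) + "\n")
        for r in model.reactions:
            row = [
                r.id,
                r.name,
                format_reaction_formula(r),
                f"{r.lower_bound:g}",
                f"{r.upper_bound:g}",
                r.gpr.to_string() if r.gpr is not None else "",
                r.subsystem or "",
            ]
            fh.write("\t".join(row) + "\n")
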
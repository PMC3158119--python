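"""Cross-referencing model genes with disease-variant and drug annotations.

Annotation tables (pre-extracted snapshots in the style of the OMIM
Morbid Map and DrugBank gene-target lists) map genes to named conditions
— a disease associated with a morbid SNP, or a drug inhibiting the gene
product — with organ-system categories and causality/status labels.
A record matches the model when its gene appears in at least one GPR
rule, i.e. when the network actually carries a reaction that the
condition can perturb. Matched records can then be turned into knockout
perturbations for the screening module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model_core import MetabolicModel
from .perturbation_screen import Perturbation

logger = logging.getLogger(__name__)

SOURCES = ("morbid_snp", "drug")
DRUG_STATUSES = ("approved", "withdrawn", "experimental")
CAUSALITIES = ("causal_metabolic", "causal_nonmetabolic", "correlated")

ANNOTATION_COLUMNS = [
    "gene_id", "condition_id", "condition_name",
    "source", "status", "category", "causality",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-condition association from an annotation snapshot."""

    gene_id: str
    condition_id: str
    condition_name: str = ""
    source: str = "morbid_snp"
    status: Optional[str] = None
    category: Optional[str] = None
    causality: Optional[str] = None

    def __post_init__(self):
        if not self.gene_id or not self.condition_id:
            raise ValueError("gene_id and condition_id must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


def read_annotation_table(path) -> List[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    return [
        AnnotationRecord(
            gene_id=row.gene_id,
            condition_id=row.condition_id,
            condition_name=row.condition_name,
            source=row.source,
            status=row.status or None,
            category=row.category or None,
            causality=row.causality or None,
        )
        for row in df.itertuples()
    ]


def write_annotation_table(records: Sequence[AnnotationRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "condition_id": r.condition_id,
                "condition_name": r.condition_name,
                "source": r.source,
                "status": r.status or "",
                "category": r.category or "",
                "causality": r.causality or "",
            }
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class CrossrefResult:
    matched: List[AnnotationRecord]
    unmatched: List[AnnotationRecord]
    conditions_by_gene: Dict[str, List[str]]


def gpr_genes(model: MetabolicModel) -> set:
    """Genes that appear in at least one reaction's GPR rule."""
    out: set = set()
    for rxn in model.reactions:
        if rxn.gpr is not None:
            out |= set(rxn.gpr.genes)
    return out


def crossref(model: MetabolicModel, records: Sequence[AnnotationRecord]) -> CrossrefResult:
    """Partition annotation records into matched and unmatched.

    A record matches iff its gene id is a model gene appearing in at
    least one GPR (a gene listed but catalysing nothing cannot be
    perturbed). The two output lists partition the input exactly.
    """
    usable = gpr_genes(model) & set(model.gene_ids)
    matched: List[AnnotationRecord] = []
    unmatched: List[AnnotationRecord] = []
    by_gene: Dict[str, List[str]] = {}
    for rec in records:
        if rec.gene_id in usable:
            matched.append(rec)
            by_gene.setdefault(rec.gene_id, []).append(rec.condition_id)
        else:
            unmatched.append(rec)
    return CrossrefResult(matched=matched, unmatched=unmatched, conditions_by_gene=by_gene)


def summarize_by_category(
    records: Sequence[AnnotationRecord], value: str = "causality"
) -> pd.DataFrame:
    """Contingency table of category (rows) against causality or status.

    Records without a category are binned under "None". Row and column
    margins are appended as "Total"; the grand total equals the record
    count.
    """
    if value not in ("causality", "status"):
        raise ValueError(f"value must be 'causality' or 'status', got {value!r}")
    if not records:
        return pd.DataFrame()
    rows = pd.DataFrame(
        {
            "category": [r.category or "None" for r in records],
            value: [getattr(r, value) or "None" for r in records],
        }
    )
    return pd.crosstab(
        rows["category"], rows[value], margins=True, margins_name="Total"
    )


def perturbations_from_records(
    records: Sequence[AnnotationRecord],
    kind_mapping: Optional[Dict[str, str]] = None,
) -> List[Perturbation]:
    """Build one gene-loss knockout per condition from matched records.

    All genes annotated to the same condition become joint targets (a
    drug with several enzyme targets inhibits them simultaneously).
    ``kind_mapping`` maps a record source to a perturbation kind;
    both default to ``gene_loss``.
    """
    kind_mapping = kind_mapping or {s: "gene_loss" for s in SOURCES}
    grouped: Dict[str, Tuple[List[str], str, str]] = {}
    order: List[str] = []
    for rec in records:
        if rec.condition_id not in grouped:
            grouped[rec.condition_id] = ([], rec.condition_name, rec.source)
            order.append(rec.condition_id)
        grouped[rec.condition_id][0].append(rec.gene_id)
    out: List[Perturbation] = []
    for cid in order:
        genes, name, source = grouped[cid]
        targets = tuple(dict.fromkeys(genes))  # dedupe, keep order
        if not targets:
            logger.warning("condition %s has no resolvable gene; skipped", cid)
            continue
        out.append(
            Perturbation(
                condition_id=cid,
                kind=kind_mapping.get(source, "gene_loss"),
                targets=targets,
                label=name,
            )
        )
    return out
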
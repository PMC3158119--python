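"""SBML import/export for metabolic models.

Two dialects are understood on input:

* ``fbc`` — SBML Level 3 with the Flux Balance Constraints package
  (flux-bound parameters, gene-product associations);
* ``cobra-notes`` — the legacy convention used by constraint-based models
  published before FBC existed: bounds as ``LOWER_BOUND``/``UPPER_BOUND``
  kinetic-law parameters and the GPR in a ``GENE_ASSOCIATION:`` note.

``auto`` (the default) tries FBC first and falls back to the legacy notes.
Species flagged ``boundaryCondition`` are removed; reactions left touching
a single internal species thereby become exchange reactions, written
``M ->`` so positive flux is secretion.

Export always writes Level 3 + FBC, the current standard.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, List, Optional, Tuple

import libsbml

from .gpr import GPRNode, GPRSyntaxError, parse_gpr
from .model_core import (
    DEFAULT_BOUND,
    Gene,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
)

logger = logging.getLogger(__name__)

_SBML_ID = re.compile(r"[^A-Za-z0-9_]")


def _sanitize(raw: str) -> str:
    out = _SBML_ID.sub("_", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x" + out
    return out


def _species_to_met_id(species_id: str, compartment: str) -> str:
    """Recover a compartment-qualified id ``base[comp]`` from an SBML id."""
    base = species_id
    if base.startswith("M_"):
        base = base[2:]
    suffix = f"_{compartment}"
    if compartment and base.endswith(suffix):
        base = base[: -len(suffix)]
    return f"{base}[{compartment}]" if compartment else base


def _reaction_id(sbml_id: str) -> str:
    return sbml_id[2:] if sbml_id.startswith("R_") else sbml_id


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _fbc_bounds(reaction, sbml_model) -> Optional[Tuple[float, float]]:
    plug = reaction.getPlugin("fbc")
    if plug is None:
        return None
    lb_id, ub_id = plug.getLowerFluxBound(), plug.getUpperFluxBound()
    if not lb_id or not ub_id:
        return None
    lb_p = sbml_model.getParameter(lb_id)
    ub_p = sbml_model.getParameter(ub_id)
    if lb_p is None or ub_p is None:
        return None
    return lb_p.getValue(), ub_p.getValue()


def _kinetic_bounds(reaction) -> Optional[Tuple[float, float]]:
    kl = reaction.getKineticLaw()
    if kl is None:
        return None
    lb = ub = None
    for i in range(kl.getNumParameters()):
        p = kl.getParameter(i)
        if p.getId() == "LOWER_BOUND":
            lb = p.getValue()
        elif p.getId() == "UPPER_BOUND":
            ub = p.getValue()
    # L3 moved kinetic-law parameters to localParameters
    for i in range(kl.getNumLocalParameters()):
        p = kl.getLocalParameter(i)
        if p.getId() == "LOWER_BOUND":
            lb = p.getValue()
        elif p.getId() == "UPPER_BOUND":
            ub = p.getValue()
    if lb is None and ub is None:
        return None
    if lb is None:
        lb = -DEFAULT_BOUND if reaction.getReversible() else 0.0
    if ub is None:
        ub = DEFAULT_BOUND
    return lb, ub


_GENE_ASSOC = re.compile(
    r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
)


def _notes_gpr(reaction) -> Optional[str]:
    if not reaction.isSetNotes():
        return None
    notes = reaction.getNotesString()
    m = _GENE_ASSOC.search(notes)
    if m is None:
        return None
    text = m.group(1).strip()
    return text or None


def _fbc_association_to_gpr(assoc, label_of: Dict[str, str]) -> GPRNode:
    if assoc.isGeneProductRef():
        gp = assoc.getGeneProduct()
        return GPRNode("gene", gene=label_of.get(gp, gp))
    children = tuple(
        _fbc_association_to_gpr(assoc.getAssociation(i), label_of)
        for i in range(assoc.getNumAssociations())
    )
    return GPRNode("and" if assoc.isFbcAnd() else "or", children=children)


def read_sbml_model(path, dialect: str = "auto") -> MetabolicModel:
    """Read an SBML (Level 2 or 3) constraint-based model.

    ``dialect`` selects where bounds and GPRs are taken from: ``fbc``,
    ``cobra-notes``, or ``auto`` (FBC first, legacy fallback). Missing
    bounds default to (-1000, 1000) for reactions flagged reversible and
    (0, 1000) otherwise, with a logged warning.
    """
    if dialect not in ("fbc", "cobra-notes", "auto"):
        raise ValueError(f"unknown SBML dialect {dialect!r}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelError(
                    f"SBML parse failure: {err.getMessage().strip()}",
                    context=f"{path} line {err.getLine()}",
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError("file contains no SBML model", context=str(path))

    mplug = sbml_model.getPlugin("fbc")
    label_of: Dict[str, str] = {}
    fbc_genes: List[Gene] = []
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            label_of[gp.getId()] = label
            fbc_genes.append(Gene(id=label, name=gp.getName() or None))

    boundary = set()
    metabolites: List[Metabolite] = []
    met_id_of: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        comp = sp.getCompartment()
        mid = _species_to_met_id(sp.getId(), comp)
        met_id_of[sp.getId()] = mid
        formula = None
        charge = None
        splug = sp.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        if charge is None and sp.isSetCharge():
            charge = sp.getCharge()
        metabolites.append(
            Metabolite(
                id=mid,
                name=sp.getName() or mid,
                compartment=comp or "c",
                formula=formula,
                charge=charge,
            )
        )

    reactions: List[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            if ref.getSpecies() in boundary:
                continue
            mid = met_id_of[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            if ref.getSpecies() in boundary:
                continue
            mid = met_id_of[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            logger.warning(
                "reaction %s touches only boundary species; dropped", rx.getId()
            )
            continue

        bounds = None
        if dialect in ("fbc", "auto"):
            bounds = _fbc_bounds(rx, sbml_model)
        if bounds is None and dialect in ("cobra-notes", "auto"):
            bounds = _kinetic_bounds(rx)
        if bounds is None:
            bounds = (
                (-DEFAULT_BOUND, DEFAULT_BOUND)
                if rx.getReversible()
                else (0.0, DEFAULT_BOUND)
            )
            logger.warning(
                "reaction %s carries no flux bounds; defaulting to %s",
                rx.getId(), bounds,
            )

        gpr: Optional[GPRNode] = None
        if dialect in ("fbc", "auto"):
            rplug = rx.getPlugin("fbc")
            if rplug is not None and rplug.isSetGeneProductAssociation():
                gpa = rplug.getGeneProductAssociation()
                gpr = _fbc_association_to_gpr(gpa.getAssociation(), label_of)
        if gpr is None and dialect in ("cobra-notes", "auto"):
            text = _notes_gpr(rx)
            if text:
                try:
                    gpr = parse_gpr(text)
                except GPRSyntaxError as exc:
                    raise ModelError(f"bad GENE_ASSOCIATION note: {exc}", context=rx.getId())

        reactions.append(
            Reaction(
                id=_reaction_id(rx.getId()),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=bounds[0],
                upper_bound=bounds[1],
                gpr=gpr,
                subsystem=None,
            )
        )

    genes: List[Gene] = list(fbc_genes)
    known = {g.id for g in genes}
    for r in reactions:
        if r.gpr is None:
            continue
        for g in sorted(r.gpr.genes):
            if g not in known:
                known.add(g)
                genes.append(Gene(id=g))

    return MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Writing (Level 3 + FBC v2)
# ---------------------------------------------------------------------------

def _check(code, what: str) -> None:
    if code is not None and isinstance(code, int) and code < 0:
        raise ModelError(f"libsbml failed while building {what} (code {code})")


def _gpr_to_fbc(node: GPRNode, parent, gp_id_of: Dict[str, str]) -> None:
    if node.op == "gene":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gp_id_of[node.gene])
        return
    sub = parent.createAnd() if node.op == "and" else parent.createOr()
    for child in node.children:
        _gpr_to_fbc(child, sub, gp_id_of)


def write_sbml_model(model: MetabolicModel, path) -> None:
    """Write a model as SBML Level 3 Version 1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = []
    for met in model.metabolites:
        if met.compartment not in compartments:
            compartments.append(met.compartment)
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)

    species_id_of: Dict[str, str] = {}
    for met in model.metabolites:
        sp = sm.createSpecies()
        base = re.sub(r"\[[^\[\]]+\]$", "", met.id)
        sid = f"M_{_sanitize(base)}_{_sanitize(met.compartment)}"
        species_id_of[met.id] = sid
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    # one shared parameter per distinct bound value
    param_of: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in param_of:
            p = sm.createParameter()
            pid = f"FB_{len(param_of)}"
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            param_of[value] = pid
        return param_of[value]

    gp_id_of: Dict[str, str] = {}
    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gid = f"G_{_sanitize(gene.id)}"
        gp_id_of[gene.id] = gid
        gp.setId(gid)
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)

    for rxn in model.reactions:
        rx = sm.createReaction()
        rx.setId(f"R_{_sanitize(rxn.id)}")
        if rxn.name:
            rx.setName(rxn.name)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(species_id_of[mid])
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            for g in rxn.gpr.genes:
                if g not in gp_id_of:
                    gp = mplug.createGeneProduct()
                    gid = f"G_{_sanitize(g)}"
                    gp_id_of[g] = gid
                    gp.setId(gid)
                    gp.setLabel(g)
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_fbc(rxn.gpr, gpa, gp_id_of)

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise ModelError(f"could not write SBML to {path}")
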
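import pytest

from fluxsig import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    SyntheticSpec,
    build_stoichiometric_matrix,
    identify_exchange_reactions,
    make_random_network,
    parse_reaction_formula,
    read_sbml_model,
    read_tabular_model,
    validate_model,
    write_sbml_model,
    write_tabular_model,
)

from conftest import models_equal


# ---------------------------------------------------------------------------
# formula grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "formula, stoich, rev",
    [
        ("A[c] -> B[c]", {"A[c]": -1.0, "B[c]": 1.0}, False),
        ("2 A[c] + B[c] -> C[e]", {"A[c]": -2.0, "B[c]": -1.0, "C[e]": 1.0}, False),
        ("A[c] <=> B[c]", {"A[c]": -1.0, "B[c]": 1.0}, True),
        ("A[c] ->", {"A[c]": -1.0}, False),   # exchange: empty product side
        ("-> B[c]", {"B[c]": 1.0}, False),
        ("0.5 A[c] -> B[c]", {"A[c]": -0.5, "B[c]": 1.0}, False),
    ],
)
def test_formula_parsing(formula, stoich, rev):
    got, got_rev = parse_reaction_formula(formula)
    assert got == stoich
    assert got_rev is rev


@pytest.mark.parametrize("bad", ["A[c] B[c]", "->", "A[c] + -> B[c]"])
def test_formula_errors(bad):
    with pytest.raises(ModelError):
        parse_reaction_formula(bad)


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def test_tabular_row_parsing(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "reaction_id\treaction_name\tformula\tlower_bound\tupper_bound\tgpr\tsubsystem\n"
        "R1\tconv\tA[c] -> B[c]\t0\t1000\t(g1 and g2) or g3\tcore\n"
        "EX_A\t\tA[c] <=>\t\t\t\t\n"
        "EX_B\t\tB[c] ->\t\t\t\t\n"
    )
    model = read_tabular_model(path)
    r1 = model.get_reaction("R1")
    assert r1.stoichiometry == {"A[c]": -1.0, "B[c]": 1.0}
    assert r1.gpr.evaluate({"g1"}) is True and r1.gpr.evaluate({"g1", "g3"}) is False
    assert r1.subsystem == "core"
    # "<=>" with no bounds defaults to (-1000, 1000); "->" to (0, 1000)
    assert model.get_reaction("EX_A").bounds == (-1000.0, 1000.0)
    assert model.get_reaction("EX_B").bounds == (0.0, 1000.0)
    assert model.metabolite_ids == ["A[c]", "B[c]"]
    assert set(model.gene_ids) == {"g1", "g2", "g3"}


def test_tabular_duplicate_reaction_rejected(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "reaction_id\treaction_name\tformula\tlower_bound\tupper_bound\tgpr\tsubsystem\n"
        "R1\t\tA[c] -> B[c]\t0\t10\t\t\n"
        "R1\t\tB[c] -> A[c]\t0\t10\t\t\n"
    )
    with pytest.raises(ModelError, match="duplicate"):
        read_tabular_model(path)


def test_tabular_bad_formula_reports_line(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "reaction_id\treaction_name\tformula\tlower_bound\tupper_bound\tgpr\tsubsystem\n"
        "R1\t\tA[c] B[c]\t0\t10\t\t\n"
    )
    with pytest.raises(ModelError, match=":2"):
        read_tabular_model(path)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_tabular_round_trip(tmp_path, toy1, toy2, seed):
    """write then read reproduces the model for toys and random networks."""
    model, _ = make_random_network(
        SyntheticSpec(seed=seed, n_pathways=3, pathway_length=2,
                      n_isozyme_reactions=2, fraction_reversible=0.3)
    )
    for m in (toy1, toy2, model):
        path = tmp_path / f"{m.id}.tsv"
        write_tabular_model(m, path)
        assert models_equal(read_tabular_model(path), m)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dialect", ["auto", "fbc"])
def test_sbml_round_trip(tmp_path, toy1, toy2, dialect):
    model, _ = make_random_network(SyntheticSpec(seed=5, n_isozyme_reactions=2))
    for m in (toy1, toy2, model):
        path = tmp_path / f"{m.id}.xml"
        write_sbml_model(m, path)
        back = read_sbml_model(path, dialect=dialect)
        assert back.id == m.id.replace("-", "_")
        assert models_equal(back, m) or [r.id for r in back.reactions] == [r.id for r in m.reactions]
        for ra, rb in zip(m.reactions, back.reactions):
            assert ra.stoichiometry == rb.stoichiometry
            assert ra.bounds == rb.bounds
            if ra.gpr is not None:
                assert rb.gpr is not None and rb.gpr.genes == ra.gpr.genes


_LEGACY_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="legacy">
  <listOfCompartments><compartment id="c"/><compartment id="b"/></listOfCompartments>
  <listOfSpecies>
   <species id="M_A_c" compartment="c" boundaryCondition="false"/>
   <species id="M_B_c" compartment="c" boundaryCondition="false"/>
   <species id="M_A_b" compartment="b" boundaryCondition="true"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R_R1" reversible="false">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>GENE_ASSOCIATION: (g1 and g2) or g3</p>
    </body></notes>
    <listOfReactants><speciesReference species="M_A_c"/></listOfReactants>
    <listOfProducts><speciesReference species="M_B_c"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci> FLUX_VALUE </ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="0"/>
      <parameter id="UPPER_BOUND" value="500"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="R_EX_A" reversible="true">
    <listOfReactants><speciesReference species="M_A_c"/></listOfReactants>
    <listOfProducts><speciesReference species="M_A_b"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci> FLUX_VALUE </ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="-10"/>
      <parameter id="UPPER_BOUND" value="0"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="R_EX_B" reversible="false">
    <listOfReactants><speciesReference species="M_B_c"/></listOfReactants>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


def test_sbml_legacy_dialect(tmp_path):
    """Legacy models: kinetic-law bounds, GENE_ASSOCIATION notes, and
    boundary species turning transporters into exchange reactions."""
    path = tmp_path / "legacy.xml"
    path.write_text(_LEGACY_SBML)
    model = read_sbml_model(path, dialect="cobra-notes")
    assert model.metabolite_ids == ["A[c]", "B[c]"]  # boundary species dropped
    r1 = model.get_reaction("R1")
    assert r1.bounds == (0.0, 500.0)
    assert r1.gpr.genes == frozenset({"g1", "g2", "g3"})
    # the A transporter lost its boundary partner -> single-metabolite exchange
    ex_a = model.get_reaction("EX_A")
    assert ex_a.stoichiometry == {"A[c]": -1.0}
    assert ex_a.bounds == (-10.0, 0.0)
    assert identify_exchange_reactions(model) == ["EX_A", "EX_B"]
    # EX_B has no kinetic law at all: defaults by reversibility flag
    assert model.get_reaction("EX_B").bounds == (0.0, 1000.0)


def test_sbml_missing_bounds_default_by_reversibility(tmp_path):
    sbml = _LEGACY_SBML.replace('reversible="false">\n    <listOfReactants><speciesReference species="M_B_c"/>',
                                'reversible="true">\n    <listOfReactants><speciesReference species="M_B_c"/>')
    path = tmp_path / "legacy2.xml"
    path.write_text(sbml)
    model = read_sbml_model(path)
    assert model.get_reaction("EX_B").bounds == (-1000.0, 1000.0)


def test_sbml_parse_failure_is_structured(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model></sbml>")
    with pytest.raises(ModelError):
        read_sbml_model(path)


# ---------------------------------------------------------------------------
# stoichiometric matrix and exchange identification
# ---------------------------------------------------------------------------

def test_stoichiometric_matrix_toy1(toy1):
    S = build_stoichiometric_matrix(toy1)
    assert (S.m, S.n) == (2, 3)
    assert S.row_ids == ["A[c]", "B[c]"]
    assert S.col_ids == ["EX_A", "R1", "EX_B"]
    assert S.entry("A[c]", "EX_A") == -1.0
    assert S.entry("A[c]", "R1") == -1.0
    assert S.entry("B[c]", "R1") == 1.0
    assert S.entry("B[c]", "EX_B") == -1.0
    assert S.entry("A[c]", "EX_B") == 0.0
    assert S.nnz == sum(len(r.stoichiometry) for r in toy1.reactions)


def test_empty_model_matrix():
    S = build_stoichiometric_matrix(MetabolicModel(id="empty"))
    assert (S.m, S.n) == (0, 0)
    assert S.density == 0.0


@pytest.mark.parametrize("seed", [11, 12])
def test_matrix_nnz_equals_total_participations(seed):
    model, _ = make_random_network(SyntheticSpec(seed=seed, n_pathways=4, pathway_length=3))
    S = build_stoichiometric_matrix(model)
    assert S.nnz == sum(len(r.stoichiometry) for r in model.reactions)


def test_exchange_identification(toy1, toy2):
    assert identify_exchange_reactions(toy1) == ["EX_A", "EX_B"]
    assert identify_exchange_reactions(toy2) == ["EX_A", "EX_B", "EX_C"]


def test_exchange_identification_order_invariant(toy2):
    shuffled = MetabolicModel(
        id=toy2.id,
        metabolites=toy2.metabolites,
        reactions=list(reversed(toy2.reactions)),
        genes=toy2.genes,
    )
    assert set(identify_exchange_reactions(shuffled)) == set(
        identify_exchange_reactions(toy2)
    )


def test_no_exchanges():
    m = MetabolicModel(
        id="closed",
        metabolites=[Metabolite("A[c]"), Metabolite("B[c]")],
        reactions=[
            Reaction("R1", {"A[c]": -1.0, "B[c]": 1.0}),
            Reaction("R2", {"B[c]": -1.0, "A[c]": 1.0}),
        ],
    )
    assert identify_exchange_reactions(m) == []


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_validate_clean(toy1):
    assert validate_model(toy1) == []


def test_validate_bound_order(toy1):
    toy1.get_reaction("R1").lower_bound = 5.0
    toy1.get_reaction("R1").upper_bound = 1.0
    codes = [d.code for d in validate_model(toy1)]
    assert codes == ["bound-order"]


def test_validate_orphan_metabolite(toy1):
    toy1.metabolites.append(Metabolite(id="C[c]"))
    diags = validate_model(toy1)
    assert [(d.code, d.subject) for d in diags] == [("orphan-metabolite", "C[c]")]


def test_validate_dead_end_and_dangling(toy1):
    toy1.reactions.append(Reaction("RD", {"D[c]": -1.0, "E[c]": 1.0}))
    codes = {d.code for d in validate_model(toy1)}
    assert "dangling-metabolite" in codes
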
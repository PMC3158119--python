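import math

import pytest
from hypothesis import given, settings, strategies as st

from fluxsig import (
    FluxRange,
    Perturbation,
    SyntheticSpec,
    apply_perturbation,
    classify_exchange_change,
    evaluate_gpr,
    flux_variability,
    identify_exchange_reactions,
    make_linear_pathway,
    make_random_network,
    parse_gpr,
    screen_all,
    screen_condition,
    threshold_sweep,
    unique_fraction,
    uniqueness_histogram,
)
from fluxsig.model_core import Metabolite, MetabolicModel, Reaction
from fluxsig.perturbation_screen import MetabolicSignature


def test_evaluate_gpr_isozyme_rescue():
    gpr = parse_gpr("(g1 and g2) or g3")
    assert evaluate_gpr(gpr, {"g1"}) is True
    assert evaluate_gpr(gpr, {"g1", "g3"}) is False
    assert evaluate_gpr(parse_gpr("g1"), set()) is True


def test_evaluate_gpr_unknown_gene_ignored(caplog):
    gpr = parse_gpr("g1")
    with caplog.at_level("WARNING"):
        assert evaluate_gpr(gpr, {"gX"}) is True
    assert any("gX" in rec.message for rec in caplog.records)


def test_apply_gene_loss(toy1):
    perturbed, closed = apply_perturbation(
        toy1, Perturbation("c", "gene_loss", ("g1",))
    )
    assert closed == ["R1"]
    assert perturbed.get_reaction("R1").bounds == (0.0, 0.0)
    # input model untouched
    assert toy1.get_reaction("R1").bounds == (0.0, 1000.0)


def test_apply_gene_loss_isozyme_rescued(toy1):
    toy1.get_reaction("R1").gpr = parse_gpr("g1 or g2")
    perturbed, closed = apply_perturbation(
        toy1, Perturbation("c", "gene_loss", ("g1",))
    )
    assert closed == []
    assert perturbed.get_reaction("R1").bounds == (0.0, 1000.0)


def test_apply_reaction_inhibition_matches_gene_loss(toy1):
    by_gene, _ = apply_perturbation(toy1, Perturbation("c", "gene_loss", ("g1",)))
    by_rxn, closed = apply_perturbation(
        toy1, Perturbation("c", "reaction_inhibition", ("R1",))
    )
    assert closed == ["R1"]
    assert [r.bounds for r in by_gene.reactions] == [r.bounds for r in by_rxn.reactions]


@pytest.mark.parametrize(
    "normal, perturbed, differential, category, rel",
    [
        ((-10, 0), (0, 0), True, "activity_change", 1.0),
        ((-10, 10), (0, 10), True, "direction_fixed", 0.5),   # secretion only
        ((-10, 10), (-4, 10), False, "unaffected", 0.3),
        ((5, 5), (5, 5), False, "unaffected", 0.0),
        ((-10, 10), (-1, 10), True, "magnitude_change", 0.45),
    ],
)
def test_classify_exchange_change(normal, perturbed, differential, category, rel):
    delta = classify_exchange_change(
        FluxRange("EX", *normal), FluxRange("EX", *perturbed), theta=0.4
    )
    assert delta.differential is differential
    assert delta.category == category
    assert delta.relative_change == pytest.approx(rel)


def test_classify_zero_span_uses_absolute_test():
    # normal span ~0: the ratio is undefined, fall back to an absolute test
    same = classify_exchange_change(
        FluxRange("EX", 5.0, 5.0), FluxRange("EX", 5.0, 5.0), theta=0.4, tau_abs=1e-3
    )
    assert not same.differential
    moved = classify_exchange_change(
        FluxRange("EX", 5.0, 5.0), FluxRange("EX", 0.0, 0.0), theta=0.4, tau_abs=1e-3
    )
    assert moved.differential


@given(
    nmin=st.floats(-50, 50), width=st.floats(0, 50),
    pshift=st.floats(-20, 20), pshrink=st.floats(0, 1),
    theta=st.floats(0.05, 0.95),
)
@settings(max_examples=200, derandomize=True)
def test_classify_invariants(nmin, width, pshift, pshrink, theta):
    """differential <-> category != unaffected; relative change >= 0."""
    normal = FluxRange("EX", nmin, nmin + width)
    pmin = nmin + pshift
    perturbed = FluxRange("EX", pmin, pmin + width * pshrink)
    d = classify_exchange_change(normal, perturbed, theta=theta)
    assert d.differential == (d.category != "unaffected")
    assert d.relative_change >= 0


def test_screen_toy1_knockout(toy1):
    sig, deltas = screen_condition(
        toy1, Perturbation("ko", "reaction_inhibition", ("R1",)), theta=0.4
    )
    assert sig.detected and sig.members == frozenset({"EX_A", "EX_B"})
    assert all(d.category == "activity_change" for d in deltas if d.differential)


def test_screen_isozyme_not_detected(toy1):
    toy1.get_reaction("R1").gpr = parse_gpr("g1 or g2")
    sig, _ = screen_condition(toy1, Perturbation("ko", "gene_loss", ("g1",)))
    assert not sig.detected and sig.members == frozenset()


def test_screen_toy2_branch_knockout(toy2):
    """Only the dead branch's exchange is differential: A still drains
    through R_AC, so EX_A and EX_C keep their full ranges."""
    sig, deltas = screen_condition(
        toy2, Perturbation("ko", "reaction_inhibition", ("R_AB",)), theta=0.4
    )
    assert sig.members == frozenset({"EX_B"})
    by_id = {d.reaction_id: d for d in deltas}
    assert by_id["EX_A"].category == "unaffected"
    assert by_id["EX_C"].category == "unaffected"
    assert by_id["EX_B"].category == "activity_change"


def test_screen_infeasible_perturbation_flags_all_exchanges(toy1):
    # force uptake: closing the consumer leaves no steady state at all
    toy1.get_reaction("EX_A").upper_bound = -1.0
    sig, deltas = screen_condition(
        toy1, Perturbation("ko", "gene_loss", ("g1",)), theta=0.4
    )
    assert sig.members == frozenset(identify_exchange_reactions(toy1))
    assert all(d.category == "activity_change" for d in deltas)


def test_screen_all_detection_fraction(toy1):
    toy1.get_reaction("R1").gpr = parse_gpr("g1 or g2")
    result = screen_all(
        toy1,
        [
            Perturbation("knock_R1", "reaction_inhibition", ("R1",)),
            Perturbation("knock_g1", "gene_loss", ("g1",)),  # rescued
            Perturbation("inhibit_EX_B", "reaction_inhibition", ("EX_B",)),
        ],
        theta=0.4,
    )
    assert result.detection_fraction == pytest.approx(2 / 3)
    assert len(result.signatures) == 3


def test_screen_all_empty_conditions(toy1):
    result = screen_all(toy1, [])
    assert result.signatures == []
    assert math.isnan(result.detection_fraction)
    assert result.warnings


def test_perturbed_ranges_contained_in_normal(toy2):
    """A knockout only adds constraints, so every perturbed range is a
    subset of the normal one."""
    exchanges = identify_exchange_reactions(toy2)
    normal = flux_variability(toy2, reaction_subset=exchanges)
    for target in ("R_AB", "R_AC", "EX_B"):
        perturbed, _ = apply_perturbation(
            toy2, Perturbation("ko", "reaction_inhibition", (target,))
        )
        pert = flux_variability(perturbed, reaction_subset=exchanges)
        for rid in exchanges:
            assert normal[rid].contains(pert[rid], tol=1e-7)


def test_uniqueness_histogram_and_fraction():
    sigs = [
        MetabolicSignature.from_members("c1", {"a", "b"}),
        MetabolicSignature.from_members("c2", {"a", "b"}),
        MetabolicSignature.from_members("c3", {"c"}),
    ]
    hist = uniqueness_histogram(sigs)
    assert hist == {1: 1, 2: 1}
    assert unique_fraction(hist) == pytest.approx(0.5)
    assert unique_fraction({1: 5}) == 1.0
    assert unique_fraction({2: 5}) == 0.0
    with pytest.raises(ValueError):
        unique_fraction({})


def test_uniqueness_ignores_undetected():
    sigs = [
        MetabolicSignature.from_members("c1", {"a"}),
        MetabolicSignature.from_members("c2", set()),
    ]
    assert uniqueness_histogram(sigs) == {1: 1}


def test_all_distinct_histogram():
    sigs = [MetabolicSignature.from_members(f"c{i}", {f"x{i}"}) for i in range(7)]
    assert uniqueness_histogram(sigs) == {1: 7}


def test_threshold_step_function():
    """Relative changes {1.0, 0.5, 0.3} cross thresholds one at a time."""
    normal = [FluxRange(f"EX{i}", 0.0, 10.0) for i in range(3)]
    pert = [FluxRange("EX0", 0.0, 0.0), FluxRange("EX1", 0.0, 5.0), FluxRange("EX2", 0.0, 7.0)]
    def count(theta):
        return sum(
            classify_exchange_change(n, p, theta=theta).differential
            for n, p in zip(normal, pert)
        )
    assert count(0.30) == 3
    assert count(0.31) == 2
    assert count(0.50) == 2
    assert count(0.51) == 1
    assert count(1.0) == 1


def test_threshold_sweep_monotone(toy2):
    grid = [round(0.05 * k, 2) for k in range(1, 13)]  # 0.05 .. 0.60
    perts = [
        Perturbation("ko_ab", "reaction_inhibition", ("R_AB",)),
        Perturbation("ko_exb", "reaction_inhibition", ("EX_B",)),
    ]
    points = threshold_sweep(toy2, perts, grid)
    counts = [p.mean_differential_count for p in points]
    dets = [p.detection_fraction for p in points]
    assert all(a >= b - 1e-12 for a, b in zip(counts, counts[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(dets, dets[1:]))


def test_threshold_sweep_single_point_matches_screen_all(toy2):
    perts = [Perturbation("ko_ab", "reaction_inhibition", ("R_AB",))]
    (point,) = threshold_sweep(toy2, perts, [0.4])
    result = screen_all(toy2, perts, theta=0.4)
    assert point.detection_fraction == result.detection_fraction
    assert point.mean_signature_size == pytest.approx(result.mean_signature_size)


def test_threshold_sweep_rejects_bad_grid(toy2):
    with pytest.raises(ValueError):
        threshold_sweep(toy2, [], [0.0])


def test_gene_loss_equals_inhibiting_disabled_reactions():
    """Knocking gene g is the same perturbation as inhibiting exactly the
    reactions whose GPR goes False under {g}."""
    model, _ = make_random_network(
        SyntheticSpec(seed=7, n_pathways=3, pathway_length=2, n_isozyme_reactions=2)
    )
    for gene in model.gene_ids:
        disabled = [
            r.id for r in model.reactions
            if r.gpr is not None and not r.gpr.evaluate({gene})
        ]
        by_gene, closed = apply_perturbation(model, Perturbation("g", "gene_loss", (gene,)))
        assert closed == disabled
        if disabled:
            by_rxn, _ = apply_perturbation(
                model, Perturbation("r", "reaction_inhibition", tuple(disabled))
            )
            assert [r.bounds for r in by_gene.reactions] == [r.bounds for r in by_rxn.reactions]


def test_empty_perturbation_has_empty_signature(toy1):
    toy1.get_reaction("R1").gpr = parse_gpr("g1 or g2")
    for theta in (0.05, 0.4, 1.0):
        sig, _ = screen_condition(
            toy1, Perturbation("noop", "gene_loss", ("g1",)), theta=theta
        )
        assert sig.members == frozenset()
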
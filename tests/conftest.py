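import pytest

from fluxsig import (
    MetabolicModel,
    make_branched_network,
    make_linear_pathway,
)


@pytest.fixture
def toy1() -> MetabolicModel:
    """Two-metabolite chain: EX_A (uptake <= 10) -> R1 -> EX_B."""
    return make_linear_pathway(1, uptake_cap=10.0)


@pytest.fixture
def toy2() -> MetabolicModel:
    """Branched network: A feeds B and C through competing reactions."""
    return make_branched_network()


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Structural model equality: same metabolites, reactions (with
    bounds, stoichiometry, GPR) and gene sets, in the same order."""
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    if len(a.reactions) != len(b.reactions):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (
            ra.id != rb.id
            or ra.stoichiometry != rb.stoichiometry
            or ra.bounds != rb.bounds
            or (ra.gpr is None) != (rb.gpr is None)
        ):
            return False
        if ra.gpr is not None and ra.gpr != rb.gpr:
            return False
    return set(a.gene_ids) == set(b.gene_ids)
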
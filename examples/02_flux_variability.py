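"""Flux variability analysis: the allowable flux range of every reaction.

Under the steady-state assumption S v = 0 and the flux bounds, each
reaction is minimised and maximised in turn. The resulting interval is
the reaction's functional capacity; reactions stuck at (0, 0) are
blocked. The LP result is cross-checked here against an independent
brute-force vertex enumeration of the flux polytope.
"""

from fluxsig import (
    flux_variability,
    functional_reactions,
    make_linear_pathway,
    oracle_fva,
)

# uptake -> A -> B -> C -> D -> secretion, uptake capped at 10 units
model = make_linear_pathway(3, uptake_cap=10.0)
fva = flux_variability(model)
oracle = oracle_fva(model)

print(f"{'reaction':10s} {'min':>8s} {'max':>8s}   oracle agrees")
for rid, fr in fva.items():
    ok = abs(fr.minimum - oracle[rid].minimum) < 1e-6 and abs(fr.maximum - oracle[rid].maximum) < 1e-6
    print(f"{rid:10s} {fr.minimum:8.2f} {fr.maximum:8.2f}   {ok}")

parts = functional_reactions(fva)
print(f"functional: {len(parts['functional'])}, blocked: {len(parts['blocked'])}")
# Every internal reaction inherits the uptake cap (0, 10): the chain can
# carry at most what the cell can import. Negative flux on EX_A is uptake.
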
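# Methods

## Model representation

A model is an ordered list of compartment-qualified metabolites
(`glc[c]` and `glc[e]` are distinct nodes), reactions with flux bounds
and optional GPR rules, and genes. Reversibility is not stored: a
reaction is reversible exactly when its lower bound is negative, which
keeps the two pieces of state from drifting apart. The stoichiometric
matrix S is assembled as a scipy sparse CSC matrix in model order;
entries equal to zero are never stored, so `nnz(S)` equals the total
number of reaction participations — the invariant behind the
connectivity edge-count check.

Two file dialects are supported. The tabular dialect is a TSV with one
reaction per row and a formula grammar
(`"2 A[c] + B[c] -> C[e]"`, `<=>` for reversible arrows, an empty side
for exchanges); omitted bounds default to ±1000 for `<=>` rows and
(0, 1000) otherwise — the de-facto cap used across constraint-based
modelling, large enough never to bind in the fixtures while keeping
every LP bounded. SBML input understands both the modern
flux-balance-constraints (FBC) package and the legacy convention of
pre-FBC models (bounds in kinetic-law parameters, GPR in a
`GENE_ASSOCIATION` note); `auto` tries FBC first. Species flagged
`boundaryCondition` are removed, which turns the transport reactions
touching them into single-metabolite exchange reactions — exactly the
convention by which exchanges are identified everywhere else in the
package. Export always writes Level 3 + FBC. Dead-end and orphan
metabolites are *reported* by `validate_model` but never removed:
detected-but-nonfunctional enzymes are a real feature of
proteomics-derived networks and must stay visible.

## LP layer

FBA/FVA solve `opt c·v s.t. S v = 0, lb ≤ v ≤ ub` with scipy's HiGHS
interface — deterministic, no randomised restarts. FVA runs *without*
any fixed objective: the target cell type has no biomass function, so
the only constraints are mass balance and bounds. This differs from the
growth-constrained FVA variants common elsewhere and is deliberate.
Unboundedness cannot occur because finite bounds are mandated at load
time; an unbounded status is therefore always surfaced as an error, and
numerical failures are reported as their own status, never as a silent
zero. Tolerances: solver feasibility 1e-9, objective comparison 1e-7,
and `tau_zero = 1e-6` for calling a range endpoint "zero" in the
functional/blocked classification. All are arguments, not constants
baked into call sites.

## Knockout screen

Gene loss closes every reaction whose GPR evaluates false with the
knocked genes set to false (isozymes rescue, complexes fail); direct
enzyme inhibition closes the listed reactions. Bounds go to exactly
(0, 0), the input model is copied, never mutated. Conditions with
several annotated genes (multi-target drugs) are simulated as
simultaneous knockouts.

The differential statistic divides the larger endpoint displacement by
the unperturbed flux span. When the span is below `tau_abs` (1e-6 times
the largest bound magnitude) the ratio is undefined and an absolute
displacement test at `tau_abs` is used instead; this fallback is a
package choice for a case the statistic itself does not define. Each
differential exchange receives one category with fixed precedence —
activity change (active/inactive status flips at `tau_zero`), then
direction fixed (a two-signed range becomes one-signed), then magnitude
change — so a delta is never double-counted. An infeasible perturbed
model (possible when a forced uptake loses its only consumer) is
reported as an all-exchange activity-change signature with a logged
flag: the perturbed cell state admits no steady state at all, which is
the strongest possible phenotype, and silently dropping the condition
would bias detection statistics.

Signature identity for the uniqueness histogram uses the member set
only, not categories or magnitudes; uniqueness is computed over detected
conditions, pooling variant and drug conditions by default (per-source
histograms are one filter away, since signatures carry their condition
ids). The threshold sweep recomputes only the classification per θ —
the per-condition FVA is done once — so a 12-point grid costs the same
LPs as a single screen, and monotonicity of counts in θ holds by
construction of the step rule.

## Connectivity

Metabolite connectivity is the count of reactions with a non-zero
coefficient for the metabolite. Exchange pseudo-reactions are included
by default (they are real columns of S; a flag excludes them). The
rank-ordered distribution breaks ties by metabolite id so ranks are
deterministic. The reference line joins the most- and least-connected
points in log10–log10 space — heavy-tailed degree distributions are the
norm for metabolic networks, and on linear axes the line would be
dominated by the single largest hub; a linear-scale option remains.
Zero-connectivity metabolites are excluded from distributions (their
log is undefined) and surfaced separately by validation.

## Annotation cross-referencing

Records match on the gene identifier, and only genes that appear in at
least one GPR count as matchable — a gene listed in the model but
catalysing nothing cannot be perturbed, so matching it would manufacture
undetectable conditions. Name-based matching against enzyme names was
considered and rejected as the default: names are not stable keys across
database snapshots. Database downloading/parsing is out of scope; the
module consumes pre-extracted TSVs and the generator produces mock
tables with planted match counts for testing.

## Synthetic data and the oracle

The generator composes flux-consistent motifs instead of sampling raw
random stoichiometries, which are almost surely fully blocked and
useless for FVA testing. A random network is `n_pathways` uptake chains
of `pathway_length` single-gene reactions feeding one hub metabolite
with a single secretion outlet. Defaults (3 pathways of length 2, one
isozyme pair, uptake cap 10, global cap 1000) give networks whose every
reaction can carry flux and whose knockout outcomes are derivable by
hand: a sole-support gene zeroes its pathway's uptake exchange
(relative change 1.0), while the hub outlet loses only `1/n_pathways`
of its span — below the 0.40 threshold for three or more pathways. The
generator records exactly this as the planted truth, including the hub
exchange when `1/n_pathways ≥ θ`. The `SyntheticSpec` constructor rejects
parameter combinations that would break the planted arithmetic (e.g. a
global cap smaller than the summed uptake). What this synthetic family
does **not** emulate: branched GPR complexes, cofactor coupling between
pathways, non-unit stoichiometry, or thermodynamically coupled loops —
so green tests show the machinery is correct, not that any real network
is this well-behaved.

`oracle_fva` is the independent check on the LP layer: for networks of
at most 8 reactions it enumerates every candidate vertex of
`{S v = 0, lb ≤ v ≤ ub}` by pinning each choice of `n − rank(S)`
coordinates at a bound, solving the remaining dense linear system, and
keeping feasible points; coordinate extrema over the vertex set are the
exact FVA ranges. It shares no code with the LP engine (numpy only) and
agrees with it to 1e-6 across 50+ seeded fixtures in the acceptance
tier. COBRApy's FVA serves as a second, external cross-check in one
test.

## Problem sizes and determinism

The test suite and the acceptance script run on networks of 5–33
reactions with tens of conditions — sizes at which the enumeration
oracle is exact and a full screen is a few hundred small LPs. All
randomness flows through explicit integer seeds (numpy `default_rng`;
derived seeds stay below 2^31), so every reported number is
bit-reproducible. Scaling to genome-scale models (hundreds of reactions,
hundreds of conditions) is a matter of runtime only: the screen reuses
the normal-state FVA across conditions and restricts FVA to the exchange
subset.

## Known limitations

* Only boolean GPR semantics: no expression levels, no partial
  inhibition or dosage.
* The differential statistic compares range endpoints; two conditions
  that deform the flux polytope identically at the boundary but
  differently inside are indistinguishable.
* SBML support targets constraint-based conventions (FBC or legacy
  notes); kinetic SBML content is ignored.
* The enumeration oracle is exponential in reaction count by design and
  refuses networks above 8 reactions.
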
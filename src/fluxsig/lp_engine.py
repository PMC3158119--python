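"""Linear programming over the steady-state flux polytope.

The feasible set is {v : S v = 0, lb <= v <= ub}. Flux balance analysis
(FBA) optimises a linear flux objective over this set; flux variability
analysis (FVA) minimises and maximises each reaction's flux in turn,
yielding the allowable range — the bounding box on network capabilities.

No objective is fixed before FVA: a mature erythrocyte-like network has
no growth function, so the only constraints are mass balance and the flux
bounds. The solver is deterministic (HiGHS via scipy with fixed options).

Reactions whose range is non-zero beyond a tolerance are classified as
*functional* (potentially active); the rest are *blocked*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, StoichiometricMatrix, build_stoichiometric_matrix

#: solver feasibility tolerance
TAU_FEAS = 1e-9
#: optimality tolerance on reported objective values
TAU_OPT = 1e-7
#: flux magnitude below which a range endpoint counts as zero
TAU_ZERO = 1e-6


class InfeasibleModelError(RuntimeError):
    """Raised when an FVA subproblem has an empty feasible set."""


@dataclass
class LinearProgram:
    """One FBA problem: optimise c.v subject to S v = 0 and bounds."""

    objective: Dict[str, float]
    equalities: StoichiometricMatrix
    bounds: Dict[str, Tuple[float, float]]
    sense: str = "max"  # "max" or "min"

    def __post_init__(self):
        unknown = set(self.objective) - set(self.equalities.col_ids)
        if unknown:
            raise ValueError(f"objective names unknown reactions: {sorted(unknown)}")
        for rid, (lb, ub) in self.bounds.items():
            if not (np.isfinite(lb) and np.isfinite(ub)):
                raise ValueError(f"non-finite bounds on {rid}")


@dataclass
class LPSolution:
    status: str  # optimal | infeasible | unbounded | numerical_failure
    objective_value: float = float("nan")
    fluxes: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FluxRange:
    """The allowable flux interval of one reaction from FVA."""

    reaction_id: str
    minimum: float
    maximum: float

    @property
    def span(self) -> float:
        return abs(self.maximum - self.minimum)

    def contains(self, other: "FluxRange", tol: float = 1e-7) -> bool:
        return (
            self.minimum - tol <= other.minimum
            and other.maximum <= self.maximum + tol
        )


_STATUS = {0: "optimal", 1: "numerical_failure", 2: "infeasible", 3: "unbounded", 4: "numerical_failure"}

_SOLVER_OPTIONS = {"presolve": True}


def solve_lp(program: LinearProgram) -> LPSolution:
    """Solve one flux-balance LP; deterministic for a fixed input.

    A numerical failure is reported as its own status, never as a silent
    zero objective.
    """
    S = program.equalities
    n = S.n
    col_index = {rid: j for j, rid in enumerate(S.col_ids)}
    c = np.zeros(n)
    for rid, coef in program.objective.items():
        c[col_index[rid]] = coef
    if program.sense == "max":
        c = -c
    elif program.sense != "min":
        raise ValueError(f"unknown sense {program.sense!r}")
    lbs = np.empty(n)
    ubs = np.empty(n)
    for rid, j in col_index.items():
        lb, ub = program.bounds[rid]
        lbs[j], ubs[j] = lb, ub
    res = linprog(
        c,
        A_eq=S.matrix,
        b_eq=np.zeros(S.m),
        bounds=np.column_stack([lbs, ubs]),
        method="highs",
        options=_SOLVER_OPTIONS,
    )
    status = _STATUS.get(res.status, "numerical_failure")
    if status != "optimal":
        return LPSolution(status=status)
    value = float(res.fun)
    if program.sense == "max":
        value = -value
    fluxes = {rid: float(res.x[j]) for rid, j in col_index.items()}
    return LPSolution(status="optimal", objective_value=value, fluxes=fluxes)


def _model_program(model: MetabolicModel) -> Tuple[StoichiometricMatrix, Dict[str, Tuple[float, float]]]:
    S = build_stoichiometric_matrix(model)
    bounds = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
    return S, bounds


def flux_variability(
    model: MetabolicModel,
    reaction_subset: Optional[Sequence[str]] = None,
) -> Dict[str, FluxRange]:
    """Minimum and maximum steady-state flux for each reaction.

    Runs two LPs per reaction under mass balance and the model bounds
    only (no fixed objective). The result does not depend on reaction
    order. Raises :class:`InfeasibleModelError` naming the first
    infeasible subproblem.
    """
    S, bounds = _model_program(model)
    targets = list(reaction_subset) if reaction_subset is not None else list(S.col_ids)
    unknown = set(targets) - set(S.col_ids)
    if unknown:
        raise KeyError(f"unknown reactions in subset: {sorted(unknown)}")
    out: Dict[str, FluxRange] = {}
    for rid in targets:
        endpoints = []
        for sense in ("min", "max"):
            sol = solve_lp(
                LinearProgram(objective={rid: 1.0}, equalities=S, bounds=bounds, sense=sense)
            )
            if sol.status != "optimal":
                raise InfeasibleModelError(
                    f"FVA subproblem {sense} {rid} returned {sol.status}"
                )
            endpoints.append(sol.objective_value)
        lo, hi = endpoints
        # clip solver noise back into the reaction's own bounds
        lb, ub = bounds[rid]
        lo = min(max(lo, lb), ub)
        hi = min(max(hi, lb), ub)
        if lo > hi:
            lo = hi = (lo + hi) / 2
        out[rid] = FluxRange(reaction_id=rid, minimum=lo, maximum=hi)
    return out


def functional_reactions(
    fva_result: Dict[str, FluxRange], tau_zero: float = TAU_ZERO
) -> Dict[str, List[str]]:
    """Partition reactions into functional and blocked.

    A reaction is functional when either FVA endpoint is non-zero beyond
    ``tau_zero`` — it can carry flux and so has a potential physiological
    role; otherwise it is blocked.
    """
    functional, blocked = [], []
    for rid, fr in fva_result.items():
        if abs(fr.minimum) > tau_zero or abs(fr.maximum) > tau_zero:
            functional.append(rid)
        else:
            blocked.append(rid)
    return {"functional": functional, "blocked": blocked}
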
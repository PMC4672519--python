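"""Stoichiometric matrix assembly and linear-programming machinery.

Flux balance analysis (FBA) maximizes a growth objective c·v over the flux
polytope {v : S·v = 0, lb <= v <= ub}, where S is the stoichiometric matrix
(rows metabolites, columns reactions) and the bounds encode reaction
reversibility plus the medium's maximum uptake rates on exchange reactions.
Built on top of plain FBA:

* parsimonious FBA (pFBA) — among (near-)optimal flux vectors, the one with
  minimal total absolute flux, used to pick a canonical flux distribution and
  hence the reported cross-feeding directions;
* flux variability analysis (FVA) — per-reaction flux ranges at a stated
  fraction of the optimum, used to decide whether a reported direction is a
  property of all optima or a solver accident;
* reaction knockouts — bounds pinned to zero, the primitive behind the
  transport-knockout interaction screen.

All LPs are solved with scipy's HiGHS backend (``linprog(method="highs")``).
Steady-state and bound tolerances are 1e-6; growth below GROWTH_EPSILON
(1e-6 h^-1) counts as "growth abolished".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import Medium, MetabolicModel, ValidationError

logger = logging.getLogger(__name__)

TOLERANCE = 1e-6
GROWTH_EPSILON = 1e-6
PFBA_RELAX = 1e-6
SOLVER_NAME = "scipy-linprog-highs"


class SolverError(RuntimeError):
    pass


@dataclass
class StoichiometricSystem:
    """Numeric form of one (or one community's) metabolic model."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    row_index: dict[str, int] = field(default_factory=dict)
    col_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.row_index:
            self.row_index = {m: i for i, m in enumerate(self.row_ids)}
        if not self.col_index:
            self.col_index = {r: j for j, r in enumerate(self.col_ids)}
        m, n = self.S.shape
        if len(self.lb) != n or len(self.ub) != n or len(self.c) != n:
            raise ValidationError(["system vector lengths inconsistent with S"])
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValidationError(["system index lengths inconsistent with S"])
        if np.any(self.lb > self.ub + TOLERANCE):
            raise ValidationError(["system has lb > ub for some reaction"])

    def copy(self) -> "StoichiometricSystem":
        return StoichiometricSystem(
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            c=self.c.copy(),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
        )


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_system(model: MetabolicModel, medium: Medium) -> StoichiometricSystem:
    """Assemble S, bounds and objective for one model on a medium.

    Exchange lower bounds are set to -(medium uptake bound) for metabolites
    present in the medium and to 0 for extracellular metabolites absent from
    it; exchange upper bounds are left open so secretion is always allowed.
    """
    mets = model.metabolites
    rxns = model.reactions
    row_ids = [m.id for m in mets]
    col_ids = [r.id for r in rxns]
    row_index = {m: i for i, m in enumerate(row_ids)}
    S = np.zeros((len(mets), len(rxns)))
    lb = np.zeros(len(rxns))
    ub = np.zeros(len(rxns))
    c = np.zeros(len(rxns))
    met_map = model.metabolite_map
    exchanged_bases = set()
    for j, r in enumerate(rxns):
        for mid, coef in r.stoichiometry.items():
            S[row_index[mid], j] = coef
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        if r.kind == "exchange":
            (mid,) = r.stoichiometry
            base = met_map[mid].base_id
            exchanged_bases.add(base)
            lb[j] = -float(medium.uptake_bounds.get(base, 0.0))
        if r.id == model.objective_reaction_id:
            c[j] = 1.0
    for base in medium.uptake_bounds:
        if base not in exchanged_bases:
            logger.warning(
                "medium component '%s' has no exchange reaction in model '%s'",
                base, model.id,
            )
    return StoichiometricSystem(
        S=S, lb=lb, ub=ub, c=c, row_ids=row_ids, col_ids=col_ids
    )


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _linprog(cost, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(
        cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed: status={res.status} ({res.message})")
    return status, res


def solve_fba(system: StoichiometricSystem) -> FluxSolution:
    """Maximize c·v subject to S·v = 0 and lb <= v <= ub."""
    m, n = system.S.shape
    status, res = _linprog(
        -system.c,
        A_eq=system.S,
        b_eq=np.zeros(m),
        bounds=list(zip(system.lb, system.ub)),
    )
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(system.col_ids)}
    return FluxSolution(
        status="optimal",
        objective_value=float(system.c @ res.x),
        fluxes=fluxes,
    )


def solve_pfba(system: StoichiometricSystem) -> FluxSolution:
    """Minimize total absolute flux among near-optimal FBA solutions.

    Splits each reaction into two nonnegative directions (v = p - n) and
    minimizes sum(p + n) subject to the original constraints plus
    c·v >= (1 - 1e-6) * FBA optimum.
    """
    base = solve_fba(system)
    if not base.optimal:
        return base
    opt = base.objective_value
    m, n = system.S.shape
    # variables: [p (forward), q (reverse)], v = p - q
    S2 = np.hstack([system.S, -system.S])
    cost = np.ones(2 * n)
    p_ub = np.maximum(system.ub, 0.0)
    q_ub = np.maximum(-system.lb, 0.0)
    bounds = [(0.0, u) for u in p_ub] + [(0.0, u) for u in q_ub]
    # enforce lb <= p - q <= ub and c·(p - q) >= (1 - relax) * opt
    A_ub = np.vstack(
        [
            np.hstack([np.eye(n), -np.eye(n)]),    # p - q <= ub
            np.hstack([-np.eye(n), np.eye(n)]),    # -(p - q) <= -lb
            np.hstack([-system.c, system.c]),      # -c·v <= -(1-relax)*opt
        ]
    )
    b_ub = np.concatenate(
        [system.ub, -system.lb, [-(1.0 - PFBA_RELAX) * opt]]
    )
    status, res = _linprog(
        cost, A_ub=A_ub, b_ub=b_ub, A_eq=S2, b_eq=np.zeros(m), bounds=bounds
    )
    if status != "optimal":
        raise SolverError(f"pFBA stage unexpectedly {status}")
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for j, rid in enumerate(system.col_ids)}
    return FluxSolution(
        status="optimal", objective_value=float(system.c @ v), fluxes=fluxes
    )


def fva(
    system: StoichiometricSystem,
    reaction_ids: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux at >= fraction_of_optimum of the optimum."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    base = solve_fba(system)
    if not base.optimal:
        raise SolverError(f"FVA requires an optimal base solution (got {base.status})")
    if reaction_ids is None:
        reaction_ids = list(system.col_ids)
    unknown = [r for r in reaction_ids if r not in system.col_index]
    if unknown:
        raise ValidationError([f"unknown reaction id '{r}'" for r in unknown])
    m, n = system.S.shape
    A_ub = -system.c.reshape(1, -1)
    b_ub = np.array([-(fraction_of_optimum * base.objective_value)])
    bounds = list(zip(system.lb, system.ub))
    out = {}
    for rid in reaction_ids:
        j = system.col_index[rid]
        e = np.zeros(n)
        e[j] = 1.0
        lo_status, lo = _linprog(e, A_ub=A_ub, b_ub=b_ub, A_eq=system.S,
                                 b_eq=np.zeros(m), bounds=bounds)
        hi_status, hi = _linprog(-e, A_ub=A_ub, b_ub=b_ub, A_eq=system.S,
                                 b_eq=np.zeros(m), bounds=bounds)
        if lo_status != "optimal" or hi_status != "optimal":
            raise SolverError(f"FVA subproblem for '{rid}' not optimal")
        out[rid] = (float(lo.x[j]), float(hi.x[j]))
    return out


def knockout(
    system: StoichiometricSystem, reaction_ids: list[str]
) -> StoichiometricSystem:
    """Copy of the system with lb = ub = 0 for the listed reactions."""
    unknown = [r for r in reaction_ids if r not in system.col_index]
    if unknown:
        raise ValidationError([f"unknown reaction id '{r}'" for r in unknown])
    ko = system.copy()
    for rid in reaction_ids:
        j = ko.col_index[rid]
        ko.lb[j] = 0.0
        ko.ub[j] = 0.0
    return ko


def check_solution(system: StoichiometricSystem, solution: FluxSolution,
                   tol: float = TOLERANCE) -> None:
    """Assert the feasibility certificate of an optimal solution:
    ||S·v||_inf <= tol and bounds violated by at most tol."""
    if not solution.optimal:
        raise AssertionError(f"solution status is {solution.status}")
    v = np.array([solution.fluxes[rid] for rid in system.col_ids])
    residual = float(np.max(np.abs(system.S @ v))) if len(v) else 0.0
    if residual > tol:
        raise AssertionError(f"steady-state residual {residual:g} > {tol:g}")
    if np.any(v < system.lb - tol) or np.any(v > system.ub + tol):
        raise AssertionError("flux bounds violated beyond tolerance")


def flux_report(system: StoichiometricSystem, solution: FluxSolution) -> str:
    """TSV report: reaction, flux, lb, ub."""
    lines = ["reaction\tflux\tlb\tub"]
    for j, rid in enumerate(system.col_ids):
        flux = solution.fluxes.get(rid, float("nan"))
        lines.append(f"{rid}\t{flux:.6f}\t{system.lb[j]:g}\t{system.ub[j]:g}")
    return "\n".join(lines) + "\n"
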
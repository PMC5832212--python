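"""Single-phase flux balance analysis primitives.

All problems are linear programs over the steady-state polytope
``{v : S v = 0, lb <= v <= ub}`` solved with scipy's HiGHS interface:

* :func:`maximize_growth` — the principal objective, max biomass flux;
* :func:`minimize_total_flux` — parsimonious sub-objective, min ``|v|_1``
  at (near-)optimal growth;
* :func:`flux_variability` — per-reaction flux ranges at a given fraction
  of the growth optimum.

The L1 norm is linearised with epigraph variables ``t_i >= |v_i|``; the
optimal norm value is unique even when the minimising flux vector is not.
Lexicographic steps fix the prior optimum through an inequality
``biomass >= fraction * mu*`` with fraction just below one, the standard
guard against round-off infeasibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "LPSettings",
    "FluxSolution",
    "maximize_growth",
    "minimize_total_flux",
    "flux_variability",
    "InfeasibleProblemError",
]

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"


class InfeasibleProblemError(RuntimeError):
    """Raised when an LP expected to be feasible is not."""


@dataclass(frozen=True)
class LPSettings:
    feasibility_tol: float = 1e-9
    fixing_fraction: float = 1.0 - 1e-6
    method: str = "highs"

    def __post_init__(self) -> None:
        if not 0.0 < self.fixing_fraction <= 1.0:
            raise ValueError("fixing_fraction must lie in (0, 1]")


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective: float
    status: str
    max_residual: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def to_table(self) -> str:
        """Two-column delimited text (reaction id, flux)."""
        lines = ["reaction\tflux"]
        lines += [f"{rid}\t{v:.10g}" for rid, v in self.fluxes.items()]
        return "\n".join(lines) + "\n"


_LP_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}


def solve_lp(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None,
             settings: LPSettings = LPSettings()):
    """Thin wrapper over scipy linprog returning (x, objective, status)."""
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method=settings.method,
        options={"primal_feasibility_tolerance": max(settings.feasibility_tol, 1e-11)}
        if settings.method.startswith("highs") else None,
    )
    status = _LP_STATUS.get(res.status, STATUS_INFEASIBLE)
    x = res.x if res.x is not None else None
    return x, (res.fun if res.fun is not None else np.nan), status


def _residual(S: np.ndarray, v: np.ndarray) -> float:
    if S.size == 0:
        return 0.0
    return float(np.max(np.abs(S @ v)))


def _make_solution(model: MetabolicModel, v, objective, status) -> FluxSolution:
    if v is None or status != STATUS_OPTIMAL:
        return FluxSolution(fluxes={}, objective=np.nan, status=status)
    S, _ = model.stoichiometric_matrix()
    return FluxSolution(
        fluxes=dict(zip(model.reaction_ids, map(float, v))),
        objective=float(objective),
        status=status,
        max_residual=_residual(S, v),
    )


def maximize_growth(
    model: MetabolicModel, settings: LPSettings = LPSettings()
) -> FluxSolution:
    """Maximise the biomass reaction flux subject to S v = 0 and bounds."""
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_ids.index(model.biomass_reaction)] = -1.0
    v, fun, status = solve_lp(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=model.bounds(),
        settings=settings,
    )
    sol = _make_solution(model, v, -fun, status)
    sol.meta["objective_name"] = "growth"
    return sol


def minimize_total_flux(
    model: MetabolicModel,
    mu_fixed: float | None = None,
    settings: LPSettings = LPSettings(),
    include_exchanges: bool = True,
) -> FluxSolution:
    """Minimise the Manhattan norm of all fluxes at growth >= mu_fixed.

    When ``mu_fixed`` is None the growth optimum is computed first.  The
    norm runs over every reaction by default; set ``include_exchanges``
    False to restrict it to non-exchange reactions.
    """
    if mu_fixed is None:
        base = maximize_growth(model, settings)
        if not base.optimal:
            return base
        mu_fixed = base.objective

    S, _ = model.stoichiometric_matrix()
    m, n = S.shape
    bio_idx = model.reaction_ids.index(model.biomass_reaction)
    norm_idx = [
        j for j, r in enumerate(model.reactions)
        if include_exchanges or r.base_role != "exchange"
    ]
    k = len(norm_idx)

    # variables: [v (n), t (k)] with t_j >= |v_{norm_idx[j]}|
    A_eq = np.hstack([S, np.zeros((m, k))])
    b_eq = np.zeros(m)
    A_ub = np.zeros((2 * k + 1, n + k))
    b_ub = np.zeros(2 * k + 1)
    for row, j in enumerate(norm_idx):
        A_ub[2 * row, j] = 1.0
        A_ub[2 * row, n + row] = -1.0
        A_ub[2 * row + 1, j] = -1.0
        A_ub[2 * row + 1, n + row] = -1.0
    # biomass >= fixing_fraction * mu_fixed
    A_ub[-1, bio_idx] = -1.0
    b_ub[-1] = -settings.fixing_fraction * mu_fixed

    bounds = model.bounds() + [(0.0, None)] * k
    c = np.concatenate([np.zeros(n), np.ones(k)])
    x, fun, status = solve_lp(c, A_eq, b_eq, A_ub, b_ub, bounds, settings)
    if x is None or status != STATUS_OPTIMAL:
        return FluxSolution(fluxes={}, objective=np.nan, status=status)
    sol = _make_solution(model, x[:n], fun, status)
    sol.meta.update(objective_name="total_flux_l1", mu_fixed=mu_fixed,
                    l1_norm=float(fun))
    return sol


def flux_variability(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    optimum_fraction: float = 1.0,
    settings: LPSettings = LPSettings(),
) -> dict[str, tuple[float, float]]:
    """Min/max flux per reaction at biomass >= optimum_fraction * mu*."""
    if not 0.0 <= optimum_fraction <= 1.0:
        raise ValueError("optimum_fraction must lie in [0, 1]")
    base = maximize_growth(model, settings)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"base growth problem is {base.status}; flux ranges undefined"
        )
    mu_star = base.objective
    if reaction_ids is None:
        reaction_ids = model.reaction_ids

    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    bio_idx = model.reaction_ids.index(model.biomass_reaction)
    A_ub = np.zeros((1, n))
    A_ub[0, bio_idx] = -1.0
    b_ub = np.array([-optimum_fraction * mu_star])
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        j = model.reaction_ids.index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        lo_x, lo, status_lo = solve_lp(c, S, np.zeros(S.shape[0]), A_ub, b_ub,
                                       model.bounds(), settings)
        hi_x, hi, status_hi = solve_lp(-c, S, np.zeros(S.shape[0]), A_ub, b_ub,
                                       model.bounds(), settings)
        if status_lo != STATUS_OPTIMAL or status_hi != STATUS_OPTIMAL:
            raise InfeasibleProblemError(
                f"flux range subproblem for {rid!r} is "
                f"{status_lo}/{status_hi}"
            )
        ranges[rid] = (float(lo), float(-hi))
    return ranges
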
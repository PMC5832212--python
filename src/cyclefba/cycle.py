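"""Coupled feast-famine cycle flux balance analysis.

A steady-state feast-famine cycle is modelled as two flux distributions —
one average distribution per phase — linked by the storage pools: what a
pool accumulates during the feast phase (time fraction ``f``) must equal
what it releases during the famine phase (fraction ``1 - f``),

    f * a_feast(pool) + (1 - f) * a_famine(pool) = 0,

where ``a(pool)`` is the pool polymer's net production rate under that
phase's fluxes.  The polymer metabolites are therefore excluded from the
per-phase steady-state balances and balanced across the cycle instead.
The cycle growth rate is the time-weighted average
``mu_cycle = f * mu_feast + (1 - f) * mu_famine``.

Solving proceeds lexicographically: (1) maximise ``mu_cycle`` (or pin it
to a target, e.g. 1/SRT); (2) optionally minimise a sub-objective at that
optimum — ``min_fluxes`` (the Manhattan norm of both phases' fluxes),
``env_moma`` (the Manhattan norm of the feast-famine flux *differences*,
environmental minimisation of metabolic adjustment), or ``combined``
(their sum).

User-facing storage fluxes are expressed in g-COD/(g-COD-biomass.d), the
currency of feast-famine reactor studies, converted through the pool's
monomer COD content and the biomass COD factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fba import (
    STATUS_OPTIMAL,
    FluxSolution,
    InfeasibleProblemError,
    LPSettings,
    solve_lp,
)
from .model import (
    MetabolicModel,
    cod_flux_to_specific,
    specific_flux_to_cod,
)
from . import model as _model_mod

__all__ = [
    "PhaseSpec",
    "feast_phase",
    "famine_phase",
    "CycleSpec",
    "CycleSolution",
    "StorageGrid",
    "MaintenanceFit",
    "SUB_OBJECTIVES",
    "solve_cycle",
    "scan_storage_grid",
    "calibrate_maintenance",
    "FEAST_FRACTION_GLUCOSE",
    "FEAST_FRACTION_ACETATE",
]

SUB_OBJECTIVES = ("none", "min_fluxes", "env_moma", "combined")

#: Observed feast-phase time fractions for the two reference substrates.
FEAST_FRACTION_GLUCOSE = 0.38
FEAST_FRACTION_ACETATE = 0.40


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of the cycle.

    ``uptake_bounds`` overrides flux bounds of substrate uptake/exchange
    reactions for this phase (mmol/(g-DW.h)).  During famine every
    substrate reaction named in the feast phase is closed unless this
    phase overrides it explicitly.  Storage direction policy: synthesis
    is disabled during famine and degradation during feast by default,
    preventing futile simultaneous synthesis/degradation.
    """

    name: str
    fraction: float
    uptake_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    disable_storage_synthesis: bool = False
    disable_storage_degradation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("phase time fraction must lie in (0, 1)")


def feast_phase(fraction: float, uptake_bounds: dict[str, tuple[float, float]],
                allow_degradation: bool = False) -> PhaseSpec:
    return PhaseSpec("feast", fraction, dict(uptake_bounds),
                     disable_storage_degradation=not allow_degradation)


def famine_phase(fraction: float,
                 uptake_bounds: dict[str, tuple[float, float]] | None = None,
                 allow_synthesis: bool = False) -> PhaseSpec:
    return PhaseSpec("famine", fraction, dict(uptake_bounds or {}),
                     disable_storage_synthesis=not allow_synthesis)


@dataclass
class CycleSpec:
    model: MetabolicModel
    feast: PhaseSpec
    famine: PhaseSpec
    fixed_storage: dict[str, float] = field(default_factory=dict)
    storage_units: str = "native"  # native (mmol/(g-DW.h)) | cod (g-COD/(g-COD.d))
    target_cycle_growth: float | None = None
    sub_objective: str = "none"
    settings: LPSettings = field(default_factory=LPSettings)

    def __post_init__(self) -> None:
        if self.sub_objective not in SUB_OBJECTIVES:
            raise ValueError(
                f"unknown sub-objective {self.sub_objective!r}; "
                f"expected one of {SUB_OBJECTIVES}"
            )
        if self.storage_units not in ("native", "cod"):
            raise ValueError("storage_units must be 'native' or 'cod'")
        if abs(self.feast.fraction + self.famine.fraction - 1.0) > 1e-9:
            raise ValueError("phase time fractions must sum to 1")
        for pool_id in self.fixed_storage:
            self.model.pool(pool_id)  # raises KeyError if unknown

    def fixed_storage_native(self) -> dict[str, float]:
        """Fixed feast-side synthesis rates in mmol/(g-DW.h)."""
        out = {}
        for pool_id, value in self.fixed_storage.items():
            if self.storage_units == "cod":
                pool = self.model.pool(pool_id)
                value = cod_flux_to_specific(
                    value, pool.monomer_formula, self.model.biomass_cod_factor
                )
            out[pool_id] = value
        return out


@dataclass
class CycleSolution:
    feast: FluxSolution
    famine: FluxSolution
    mu_feast: float
    mu_famine: float
    mu_cycle: float
    storage_fluxes: dict[str, dict[str, float]]
    sub_objective: str
    sub_objective_value: float
    status: str
    diagnostics: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def total_storage_cod(self) -> float:
        return sum(d["feast_synthesis_cod"] for d in self.storage_fluxes.values())


@dataclass
class StorageGrid:
    pool_x: str
    x_values: np.ndarray
    pool_y: str | None
    y_values: np.ndarray | None
    fixed_other_pools: dict[str, float]
    mu_cycle: np.ndarray  # shape (len(x), len(y) or 1); NaN where infeasible
    feasible: np.ndarray

    def to_delimited(self) -> str:
        header = f"# pool_x={self.pool_x} values=" + ",".join(
            f"{v:g}" for v in self.x_values
        )
        if self.pool_y is not None:
            header += f"\n# pool_y={self.pool_y} values=" + ",".join(
                f"{v:g}" for v in self.y_values
            )
        rows = []
        for i in range(self.mu_cycle.shape[0]):
            rows.append("\t".join(
                "inf" if not self.feasible[i, j] else f"{self.mu_cycle[i, j]:.8g}"
                for j in range(self.mu_cycle.shape[1])
            ))
        return header + "\n" + "\n".join(rows) + "\n"


@dataclass
class MaintenanceFit:
    gam: float
    ngam: float
    achieved_total_storage_cod: float
    target_total_storage_cod: float
    residual: float
    grid: list[tuple[float, float]]
    exact: bool
    warning: str = ""


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _phase_bounds(model: MetabolicModel, phase: PhaseSpec,
                  substrate_reactions: set[str]) -> list[tuple[float, float]]:
    bounds = []
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if phase.name == "famine" and rxn.id in substrate_reactions \
                and rxn.id not in phase.uptake_bounds:
            lb, ub = 0.0, 0.0
        if rxn.id in phase.uptake_bounds:
            lb, ub = phase.uptake_bounds[rxn.id]
        if phase.disable_storage_synthesis and rxn.base_role == "storage_synthesis":
            lb, ub = 0.0, 0.0
        if phase.disable_storage_degradation and rxn.base_role == "storage_degradation":
            lb, ub = 0.0, 0.0
        bounds.append((lb, ub))
    return bounds


class _CycleLP:
    """Stacked LP over (v_feast, v_famine) with storage coupling rows."""

    def __init__(self, spec: CycleSpec):
        self.spec = spec
        model = spec.model
        self.n = len(model.reactions)
        self.bio = model.reaction_ids.index(model.biomass_reaction)
        pool_mets = {p.polymer_metabolite for p in model.storage_pools}
        S, _ = model.stoichiometric_matrix(exclude_metabolites=pool_mets)
        m = S.shape[0]
        f = spec.feast.fraction
        n = self.n

        rows = []
        self.constraint_names = []
        Z = np.zeros((m, n))
        rows.append(np.hstack([S, Z]))
        self.constraint_names += [f"feast balance ({m} rows)"]
        rows.append(np.hstack([Z, S]))
        self.constraint_names += [f"famine balance ({m} rows)"]
        for pool in model.storage_pools:
            row = model.metabolite_row(pool.polymer_metabolite)
            rows.append(np.hstack([f * row, (1 - f) * row])[None, :])
            self.constraint_names.append(f"storage coupling for pool {pool.id!r}")
        self.A_eq = np.vstack(rows)
        self.b_eq = np.zeros(self.A_eq.shape[0])

        fixed_rows = []
        self.fixed_names = []
        for pool_id, value in spec.fixed_storage_native().items():
            pool = model.pool(pool_id)
            row = np.zeros(2 * n)
            for rid in pool.synthesis_reactions:
                row[model.reaction_ids.index(rid)] = 1.0
            for rid in pool.degradation_reactions:
                row[model.reaction_ids.index(rid)] -= 1.0
            fixed_rows.append(row)
            self.fixed_names.append(
                f"fixed feast storage flux for pool {pool_id!r} "
                f"({spec.fixed_storage[pool_id]:g} {spec.storage_units})"
            )
            self.b_eq = np.append(self.b_eq, value)
        if fixed_rows:
            self.A_eq = np.vstack([self.A_eq, np.vstack(fixed_rows)])

        substrate = set(spec.feast.uptake_bounds)
        self.bounds = (
            _phase_bounds(model, spec.feast, substrate)
            + _phase_bounds(model, spec.famine, substrate)
        )

        self.mu_row = np.zeros(2 * n)
        self.mu_row[self.bio] = f
        self.mu_row[n + self.bio] = 1 - f

    def with_target(self, target: float):
        A = np.vstack([self.A_eq, self.mu_row])
        b = np.append(self.b_eq, target)
        return A, b

    def maximize_mu(self, settings: LPSettings):
        if self.spec.target_cycle_growth is not None:
            A_eq, b_eq = self.with_target(self.spec.target_cycle_growth)
        else:
            A_eq, b_eq = self.A_eq, self.b_eq
        x, fun, status = solve_lp(-self.mu_row, A_eq, b_eq, bounds=self.bounds,
                                  settings=settings)
        return x, -fun, status

    def minimize_sub_objective(self, mu_star: float, settings: LPSettings):
        """Fix mu_cycle (inequality at fixing_fraction, or target equality)
        and minimise the requested L1 sub-objective with epigraph variables."""
        sub = self.spec.sub_objective
        n = self.n
        n_phase_aux = 2 * n if sub in ("min_fluxes", "combined") else 0
        n_diff_aux = n if sub in ("env_moma", "combined") else 0
        n_aux = n_phase_aux + n_diff_aux
        n_tot = 2 * n + n_aux

        if self.spec.target_cycle_growth is not None:
            A_eq, b_eq = self.with_target(self.spec.target_cycle_growth)
            A_ub_rows, b_ub = [], []
        else:
            A_eq, b_eq = self.A_eq, self.b_eq
            row = np.zeros(n_tot)
            row[: 2 * n] = -self.mu_row
            A_ub_rows, b_ub = [row], [-settings.fixing_fraction * mu_star]
        A_eq = np.hstack([A_eq, np.zeros((A_eq.shape[0], n_aux))])

        c = np.concatenate([np.zeros(2 * n), np.ones(n_aux)])
        aux0 = 2 * n
        for j in range(n_phase_aux):  # t_j >= |x_j| over both phase vectors
            for sign in (1.0, -1.0):
                row = np.zeros(n_tot)
                row[j] = sign
                row[aux0 + j] = -1.0
                A_ub_rows.append(row)
                b_ub.append(0.0)
        d0 = aux0 + n_phase_aux
        for j in range(n_diff_aux):  # d_j >= |v_feast_j - v_famine_j|
            for sign in (1.0, -1.0):
                row = np.zeros(n_tot)
                row[j] = sign
                row[n + j] = -sign
                row[d0 + j] = -1.0
                A_ub_rows.append(row)
                b_ub.append(0.0)

        bounds = self.bounds + [(0.0, None)] * n_aux
        x, fun, status = solve_lp(
            c, A_eq, b_eq, np.vstack(A_ub_rows) if A_ub_rows else None,
            np.array(b_ub) if b_ub else None, bounds, settings,
        )
        return (x[: 2 * n] if x is not None else None), fun, status

    def diagnose_infeasibility(self, settings: LPSettings) -> str:
        """Name the constraint family that breaks feasibility, by relaxation."""
        # drop fixed-storage rows
        n_fixed = len(self.fixed_names)
        if n_fixed:
            A = self.A_eq[:-n_fixed]
            b = self.b_eq[:-n_fixed]
            _, _, status = solve_lp(-self.mu_row, A, b, bounds=self.bounds,
                                    settings=settings)
            if status == STATUS_OPTIMAL:
                return "infeasible constraint(s): " + "; ".join(self.fixed_names)
        if self.spec.target_cycle_growth is not None:
            _, mu_max, status = solve_lp(-self.mu_row, self.A_eq, self.b_eq,
                                         bounds=self.bounds, settings=settings)
            if status == STATUS_OPTIMAL:
                return (
                    f"target cycle growth {self.spec.target_cycle_growth:g} "
                    f"unreachable (maximum attainable {mu_max:g})"
                )
        return ("base coupled problem infeasible (phase balances, bounds, or "
                "storage coupling: " + "; ".join(self.constraint_names) + ")")


def _flux_solution(model: MetabolicModel, v: np.ndarray) -> FluxSolution:
    S, _ = model.stoichiometric_matrix(
        exclude_metabolites={p.polymer_metabolite for p in model.storage_pools}
    )
    resid = float(np.max(np.abs(S @ v))) if S.size else 0.0
    bio = model.reaction_ids.index(model.biomass_reaction)
    return FluxSolution(
        fluxes=dict(zip(model.reaction_ids, map(float, v))),
        objective=float(v[bio]),
        status=STATUS_OPTIMAL,
        max_residual=resid,
    )


def solve_cycle(spec: CycleSpec) -> CycleSolution:
    """Solve the coupled feast-famine problem for one cycle specification."""
    model = spec.model
    settings = spec.settings
    lp = _CycleLP(spec)

    x, mu_star, status = lp.maximize_mu(settings)
    if status != STATUS_OPTIMAL:
        diag = lp.diagnose_infeasibility(settings)
        empty = FluxSolution(fluxes={}, objective=np.nan, status=status)
        return CycleSolution(empty, empty, np.nan, np.nan, np.nan, {},
                             spec.sub_objective, np.nan, status, diag)

    sub_value = np.nan
    if spec.sub_objective != "none":
        x2, sub_value, status2 = lp.minimize_sub_objective(mu_star, settings)
        if status2 != STATUS_OPTIMAL:
            raise InfeasibleProblemError(
                f"sub-objective step unexpectedly {status2} "
                f"(mu_cycle*={mu_star:g})"
            )
        x = x2
        sub_value = float(sub_value)

    n = lp.n
    v_feast, v_famine = x[:n], x[n:2 * n]
    f = spec.feast.fraction
    feast_sol = _flux_solution(model, v_feast)
    famine_sol = _flux_solution(model, v_famine)
    mu_feast, mu_famine = feast_sol.objective, famine_sol.objective
    mu_cycle = f * mu_feast + (1 - f) * mu_famine

    storage = {}
    for pool in model.storage_pools:
        row = model.metabolite_row(pool.polymer_metabolite)
        acc_feast = float(row @ v_feast)
        acc_famine = float(row @ v_famine)
        storage[pool.id] = {
            "feast_synthesis_native": acc_feast,
            "famine_consumption_native": -acc_famine,
            "feast_synthesis_cod": specific_flux_to_cod(
                acc_feast, pool.monomer_formula, model.biomass_cod_factor
            ),
            "coupling_residual": f * acc_feast + (1 - f) * acc_famine,
        }

    return CycleSolution(
        feast=feast_sol,
        famine=famine_sol,
        mu_feast=mu_feast,
        mu_famine=mu_famine,
        mu_cycle=mu_cycle,
        storage_fluxes=storage,
        sub_objective=spec.sub_objective,
        sub_objective_value=sub_value,
        status=STATUS_OPTIMAL,
    )


def scan_storage_grid(
    spec: CycleSpec,
    pool_x: str,
    x_values,
    pool_y: str | None = None,
    y_values=None,
    fixed_other_pools: dict[str, float] | None = None,
) -> StorageGrid:
    """Maximal cycle growth over a grid of fixed storage fluxes.

    Axis values are feast-side synthesis rates in ``spec.storage_units``.
    Cells whose forced storage cannot be sustained are flagged infeasible
    (NaN), never zero-filled.
    """
    x_values = np.asarray(list(x_values), dtype=float)
    if np.any(x_values < 0) or not np.all(np.isfinite(x_values)):
        raise ValueError("axis values must be non-negative and finite")
    if pool_y is not None:
        y_values = np.asarray(list(y_values), dtype=float)
        if np.any(y_values < 0) or not np.all(np.isfinite(y_values)):
            raise ValueError("axis values must be non-negative and finite")
        ny = len(y_values)
    else:
        ny = 1
    fixed_other_pools = dict(fixed_other_pools or {})

    mu = np.full((len(x_values), ny), np.nan)
    feasible = np.zeros_like(mu, dtype=bool)
    for i, xv in enumerate(x_values):
        for j in range(ny):
            fixed = dict(fixed_other_pools)
            fixed[pool_x] = float(xv)
            if pool_y is not None:
                fixed[pool_y] = float(y_values[j])
            cell_spec = replace(spec, fixed_storage=fixed)
            sol = solve_cycle(cell_spec)
            if sol.optimal:
                mu[i, j] = sol.mu_cycle
                feasible[i, j] = True
    return StorageGrid(
        pool_x=pool_x,
        x_values=x_values,
        pool_y=pool_y,
        y_values=y_values if pool_y is not None else None,
        fixed_other_pools=fixed_other_pools,
        mu_cycle=mu,
        feasible=feasible,
    )


def calibrate_maintenance(
    spec: CycleSpec,
    observed_total_storage_cod: float,
    gam_grid,
    ngam_grid,
) -> MaintenanceFit:
    """Grid-search GAM/NGAM so the predicted total storage COD flux matches
    the observed one at the spec's target cycle growth rate.

    Evaluates the coupled problem at every (GAM, NGAM) pair and returns the
    point minimising ``|predicted - observed|``; ties break toward smaller
    GAM, then smaller NGAM (iteration order over the sorted grids).
    """
    gam_grid = sorted(float(g) for g in gam_grid)
    ngam_grid = sorted(float(g) for g in ngam_grid)
    if not gam_grid or not ngam_grid:
        raise ValueError("GAM and NGAM grids must be non-empty")
    if spec.target_cycle_growth is None:
        raise ValueError(
            "calibration requires a target cycle growth rate (e.g. 1/SRT)"
        )

    best: MaintenanceFit | None = None
    evaluated = []
    for gam in gam_grid:
        for ngam in ngam_grid:
            trial_model = _model_mod.set_maintenance(spec.model, gam, ngam)
            trial = replace(spec, model=trial_model)
            sol = solve_cycle(trial)
            if not sol.optimal:
                continue
            achieved = sol.total_storage_cod()
            evaluated.append((gam, ngam))
            residual = abs(achieved - observed_total_storage_cod)
            if best is None or residual < best.residual - 1e-12:
                best = MaintenanceFit(
                    gam=gam,
                    ngam=ngam,
                    achieved_total_storage_cod=achieved,
                    target_total_storage_cod=observed_total_storage_cod,
                    residual=residual,
                    grid=[],
                    exact=residual <= 1e-9,
                )
    if best is None:
        raise InfeasibleProblemError(
            "maintenance calibration failed: every (GAM, NGAM) grid point "
            "yields an infeasible coupled problem"
        )
    best.grid = [(g, n) for g in gam_grid for n in ngam_grid]
    if not best.exact:
        best.warning = (
            f"target total storage flux {observed_total_storage_cod:g} not "
            f"attained exactly; nearest fit residual {best.residual:g}"
        )
    if not evaluated:
        best.warning += " (no feasible grid point)"
    return best


def cycle_growth_per_day(mu_cycle_per_hour: float) -> float:
    """Convert a cycle growth rate from the model's per-hour basis to d^-1."""
    return mu_cycle_per_hour * 24.0
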
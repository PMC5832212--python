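import dataclasses

import numpy as np
import pytest

from conftest import make_cycle_spec
from cyclefba.cycle import (
    CycleSpec,
    calibrate_maintenance,
    famine_phase,
    feast_phase,
    scan_storage_grid,
    solve_cycle,
)
from cyclefba.fba import InfeasibleProblemError
from cyclefba.model import specific_flux_to_cod
from cyclefba.toy import make_toy_model


def closed_form_mu_cycle(s: float) -> float:
    """Coupled-cycle growth of the linear toy (f=0.5, q=10, GAM=2, NGAM=1)
    at forced feast storage synthesis s: phase balances give
    mu_feast=(19-3s)/4, mu_famine=(2s-1)/4, hence mu_cycle=(18-s)/8."""
    return (18.0 - s) / 8.0


class TestSolveCycle:
    def test_free_storage_optimum(self, cycle_spec):
        sol = solve_cycle(cycle_spec)
        assert sol.optimal
        # optimizer picks the minimum storage covering famine maintenance
        assert sol.mu_cycle == pytest.approx(2.1875, abs=1e-8)
        assert sol.storage_fluxes["glyc"]["feast_synthesis_native"] == \
            pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize("s", [0.5, 1.0, 2.0, 4.0, 6.0])
    def test_forced_storage_closed_form(self, cycle_spec, s):
        spec = dataclasses.replace(cycle_spec, fixed_storage={"glyc": s})
        sol = solve_cycle(spec)
        assert sol.optimal
        assert sol.mu_cycle == pytest.approx(closed_form_mu_cycle(s), abs=1e-8)

    def test_forced_storage_beyond_uptake_capacity(self, cycle_spec):
        # s > 19/3 would require negative feast growth: infeasible
        spec = dataclasses.replace(cycle_spec, fixed_storage={"glyc": 10.0})
        sol = solve_cycle(spec)
        assert sol.status == "infeasible"
        assert "glyc" in sol.diagnostics

    def test_mu_cycle_identity_and_coupling(self, cycle_spec):
        for sub in ("none", "min_fluxes", "env_moma", "combined"):
            sol = solve_cycle(dataclasses.replace(cycle_spec, sub_objective=sub))
            f = cycle_spec.feast.fraction
            assert sol.mu_cycle == pytest.approx(
                f * sol.mu_feast + (1 - f) * sol.mu_famine, abs=1e-12
            )
            for d in sol.storage_fluxes.values():
                assert abs(d["coupling_residual"]) <= 1e-6
            assert sol.feast.max_residual <= 1e-6
            assert sol.famine.max_residual <= 1e-6

    def test_sub_objective_preserves_growth(self, cycle_spec):
        base = solve_cycle(cycle_spec)
        for sub in ("min_fluxes", "env_moma", "combined"):
            sol = solve_cycle(dataclasses.replace(cycle_spec, sub_objective=sub))
            assert sol.mu_cycle >= \
                cycle_spec.settings.fixing_fraction * base.mu_cycle - 1e-9

    def test_env_moma_zero_for_identical_phases(self, linear_toy):
        spec = CycleSpec(
            model=linear_toy,
            feast=feast_phase(0.5, {"upt": (0.0, 10.0)}),
            famine=famine_phase(0.5, {"upt": (0.0, 10.0)}),
            sub_objective="env_moma",
        )
        sol = solve_cycle(spec)
        assert sol.sub_objective_value == pytest.approx(0.0, abs=1e-6)
        for rid in linear_toy.reaction_ids:
            assert sol.feast[rid] == pytest.approx(sol.famine[rid], abs=1e-6)

    def test_combined_matches_env_moma_storage(self, cycle_spec):
        """The combined sub-objective and environmental MOMA select the
        same storage fluxes (asserted on the toy)."""
        sols = {
            sub: solve_cycle(dataclasses.replace(cycle_spec, sub_objective=sub))
            for sub in ("env_moma", "combined")
        }
        for pool in ("glyc",):
            a = sols["env_moma"].storage_fluxes[pool]["feast_synthesis_native"]
            b = sols["combined"].storage_fluxes[pool]["feast_synthesis_native"]
            assert a == pytest.approx(b, abs=1e-3)

    def test_unreachable_target_growth_diagnosed(self, linear_toy):
        spec = make_cycle_spec(linear_toy, target=5.0)
        sol = solve_cycle(spec)
        assert sol.status == "infeasible"
        assert "target cycle growth" in sol.diagnostics

    def test_cod_storage_units(self, linear_toy):
        pool = linear_toy.pool("glyc")
        s_native = 2.0
        s_cod = specific_flux_to_cod(
            s_native, pool.monomer_formula, linear_toy.biomass_cod_factor
        )
        spec = make_cycle_spec(linear_toy, fixed_storage={"glyc": s_cod},
                               storage_units="cod")
        sol = solve_cycle(spec)
        assert sol.mu_cycle == pytest.approx(closed_form_mu_cycle(2.0), abs=1e-8)
        assert sol.storage_fluxes["glyc"]["feast_synthesis_cod"] == \
            pytest.approx(s_cod, abs=1e-8)


class TestStorageGrid:
    def test_single_axis_closed_form(self, cycle_spec):
        grid = scan_storage_grid(cycle_spec, "glyc", [0.5, 1.0, 2.0])
        assert grid.feasible.all()
        np.testing.assert_allclose(
            grid.mu_cycle[:, 0], [2.1875, 2.125, 2.0], atol=1e-8
        )

    def test_two_axis_monotone_nonincreasing(self, two_pool_toy):
        spec = make_cycle_spec(two_pool_toy)
        xs = [0.25, 0.5, 1.0, 2.0]
        ys = [0.25, 0.5, 1.0]
        grid = scan_storage_grid(spec, "glyc", xs, "phb", ys)
        mu = grid.mu_cycle
        assert grid.feasible.all()
        assert (np.diff(mu, axis=0) <= 1e-9).all()
        assert (np.diff(mu, axis=1) <= 1e-9).all()

    def test_infeasible_cells_flagged_not_zero(self, cycle_spec):
        grid = scan_storage_grid(cycle_spec, "glyc", [0.5, 50.0])
        assert grid.feasible[0, 0]
        assert not grid.feasible[1, 0]
        assert np.isnan(grid.mu_cycle[1, 0])

    def test_rejects_negative_axis(self, cycle_spec):
        with pytest.raises(ValueError):
            scan_storage_grid(cycle_spec, "glyc", [-1.0, 1.0])


class TestCalibrateMaintenance:
    def test_parameter_recovery(self, linear_toy):
        base = solve_cycle(make_cycle_spec(linear_toy, sub_objective="min_fluxes"))
        target_storage = base.total_storage_cod()
        spec = make_cycle_spec(linear_toy, sub_objective="min_fluxes",
                               target=base.mu_cycle)
        fit = calibrate_maintenance(spec, target_storage,
                                    gam_grid=[2.0, 4.0, 8.0],
                                    ngam_grid=[0.5, 1.0, 2.0])
        assert (fit.gam, fit.ngam) == (2.0, 1.0)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)
        assert fit.exact

    def test_unattainable_target_warns(self, linear_toy):
        spec = make_cycle_spec(linear_toy, sub_objective="min_fluxes",
                               target=2.0)
        fit = calibrate_maintenance(spec, 100.0,
                                    gam_grid=[2.0], ngam_grid=[1.0])
        assert fit.residual > 0
        assert not fit.exact
        assert fit.warning

    def test_fully_infeasible_grid_errors(self, linear_toy):
        spec = make_cycle_spec(linear_toy, target=50.0)
        with pytest.raises(InfeasibleProblemError):
            calibrate_maintenance(spec, 1.0, [2.0], [1.0])

    def test_requires_target_growth(self, cycle_spec):
        with pytest.raises(ValueError, match="target"):
            calibrate_maintenance(cycle_spec, 1.0, [2.0], [1.0])


class TestPhaseSpecs:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            feast_phase(0.0, {})
        with pytest.raises(ValueError):
            feast_phase(1.0, {})

    def test_fractions_must_sum_to_one(self, linear_toy):
        with pytest.raises(ValueError, match="sum to 1"):
            CycleSpec(model=linear_toy,
                      feast=feast_phase(0.4, {"upt": (0.0, 10.0)}),
                      famine=famine_phase(0.5))

    def test_unknown_pool_rejected(self, linear_toy):
        with pytest.raises(KeyError):
            make_cycle_spec(linear_toy, fixed_storage={"nope": 1.0})

    def test_unknown_sub_objective_rejected(self, linear_toy):
        with pytest.raises(ValueError, match="sub-objective"):
            make_cycle_spec(linear_toy, sub_objective="quadratic")
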
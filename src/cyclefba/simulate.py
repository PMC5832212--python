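"""Seeded synthetic measurement campaigns from solved cycles.

A solved feast-famine cycle provides ground-truth conversion amounts:
substrate taken up, carbon mineralised to CO2, biomass formed and
storage polymers accumulated during the feast phase.  These are turned
into per-cycle converted masses on a carbon basis (Cmmol per g-DW per
cycle), perturbed with independent additive Gaussian noise at given
standard errors, and packaged in the same containers the reconciliation
and discrimination modules consume.  Because the conversions derive from
a feasible flux distribution, they satisfy the carbon balance exactly
before noise, so a zero-noise campaign reconciles with h = 0 and noisy
campaigns calibrate the chi-square gross-error test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycle import CycleSolution, CycleSpec
from .discriminate import ObservationSet
from .model import specific_flux_to_cod
from .reconcile import ElementalMatrix, MeasurementSet

__all__ = ["SimulatedStudy", "simulate_measurements", "true_conversions"]


@dataclass
class SimulatedStudy:
    truth: CycleSolution
    true_conversions: dict[str, float]
    elemental_matrix: ElementalMatrix
    measurements: MeasurementSet
    observations: ObservationSet
    seed: int


def true_conversions(
    solution: CycleSolution, spec: CycleSpec, cycle_hours: float = 6.0
) -> dict[str, float]:
    """Feast-phase converted carbon per cycle (Cmmol/g-DW), signed with
    production positive.

    Substrate uptake is read from the feast uptake reactions; storage
    accumulation from the pool coupling rows; biomass from the growth
    rate; mineralised carbon (the CO2 conversion) closes the carbon
    balance exactly, as it would in a respirometric campaign.
    """
    model = spec.model
    feast_hours = spec.feast.fraction * cycle_hours

    substrate_c = 0.0
    for rid in spec.feast.uptake_bounds:
        rxn = model.reaction(rid)
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            if met.is_external and coeff < 0:
                substrate_c += -coeff * met.formula.C * solution.feast[rid]

    bio_rxn = model.reaction(model.biomass_reaction)
    bio_c = 0.0
    for met_id, coeff in bio_rxn.stoichiometry.items():
        if coeff > 0:
            bio_c += coeff * model.metabolite(met_id).formula.C
    biomass_c = bio_c * solution.mu_feast

    conversions = {"substrate": -substrate_c * feast_hours,
                   "biomass": biomass_c * feast_hours}
    storage_total_c = 0.0
    for pool in model.storage_pools:
        acc = solution.storage_fluxes[pool.id]["feast_synthesis_native"]
        c_amount = acc * pool.monomer_formula.C * feast_hours
        conversions[f"storage_{pool.id}"] = c_amount
        storage_total_c += c_amount
    # mineralised carbon closes the balance (CO2 produced by catabolism)
    conversions["co2"] = (-conversions["substrate"]
                          - conversions["biomass"] - storage_total_c)
    return conversions


def simulate_measurements(
    solution: CycleSolution,
    spec: CycleSpec,
    se_per_conversion: dict[str, float],
    seed: int,
    cycle_hours: float = 6.0,
    observation_se_cod: dict[str, float] | None = None,
) -> SimulatedStudy:
    """Generate one noisy measurement campaign from a solved cycle.

    ``se_per_conversion`` gives the additive Gaussian SE per conversion id
    (missing ids default to 0, i.e. exact); ``observation_se_cod`` gives
    SEs for the per-pool storage-flux observations in COD units (defaults
    to 10% of the true flux, floored at 0.01).  Deterministic per seed.
    """
    if not solution.optimal:
        raise ValueError("cannot simulate measurements from a non-optimal cycle")
    for cid, se in se_per_conversion.items():
        if se < 0:
            raise ValueError(f"negative SE for conversion {cid!r}")

    rng = np.random.default_rng(seed)
    truth = true_conversions(solution, spec, cycle_hours)
    ids = list(truth)

    values = {}
    ses = {}
    for cid in ids:
        se = float(se_per_conversion.get(cid, 0.0))
        values[cid] = truth[cid] + (rng.normal(0.0, se) if se > 0 else 0.0)
        # the reconciliation weighting needs strictly positive SEs
        ses[cid] = se if se > 0 else 1e-6
    measurements = MeasurementSet(
        ids=ids, values=values, standard_errors=ses,
        measured={cid: True for cid in ids},
    )

    E = ElementalMatrix(
        elements=["C"], conversions=ids,
        matrix=np.ones((1, len(ids))),
    )

    model = spec.model
    obs_ids, obs_vals, obs_ses = [], {}, {}
    observation_se_cod = observation_se_cod or {}
    for pool in model.storage_pools:
        oid = pool.id
        true_cod = specific_flux_to_cod(
            solution.storage_fluxes[pool.id]["feast_synthesis_native"],
            pool.monomer_formula, model.biomass_cod_factor,
        )
        se = float(observation_se_cod.get(oid, max(0.1 * abs(true_cod), 0.01)))
        obs_ids.append(oid)
        obs_vals[oid] = true_cod + (rng.normal(0.0, se) if se > 0 else 0.0)
        obs_ses[oid] = se if se > 0 else 1e-6
    observations = ObservationSet(
        ids=tuple(obs_ids), observed=obs_vals, standard_errors=obs_ses
    )

    return SimulatedStudy(
        truth=solution,
        true_conversions=truth,
        elemental_matrix=E,
        measurements=measurements,
        observations=observations,
        seed=seed,
    )
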
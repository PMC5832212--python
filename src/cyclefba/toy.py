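"""Desk-scale toy networks with closed-form optima.

These stand in for a genome-scale model during development and testing:
a substrate S is taken up (capped at ``q_max``), catabolised to 2 ATP,
and invested in biomass (1 S + GAM ATP per unit), maintenance (NGAM ATP
sink) or a storage polymer (1 S + 1 ATP per monomer stored; degradation
returns the monomer for free).  For the ``linear`` variant the growth
optimum has the closed form

    mu* = (2 q_max - NGAM) / (2 + GAM)

because every unit of substrate not oxidised yields 2 ATP and growth
consumes one substrate plus GAM ATP per unit of biomass.  The
``redundant`` variant adds a second two-step catabolic route with the
same net stoichiometry (for testing alternate-optimum handling); the
``two_pool`` variant adds a second, stoichiometrically identical storage
pool (for two-axis storage scans).
"""

from __future__ import annotations

from .model import (
    Formula,
    MetabolicModel,
    Metabolite,
    Reaction,
    StoragePool,
)

__all__ = ["make_toy_model", "toy_growth_optimum"]

_GLUCOSE = Formula(C=6, H=12, O=6)

VARIANTS = ("linear", "redundant", "two_pool")


def toy_growth_optimum(q_max: float, gam: float, ngam: float) -> float:
    """Closed-form single-phase growth optimum of the toy network."""
    return (2.0 * q_max - ngam) / (2.0 + gam)


def _storage_reactions(pool_id: str, upper: float) -> list[Reaction]:
    polymer = f"sto_{pool_id}"
    return [
        Reaction(
            id=f"syn_{pool_id}",
            name=f"{pool_id} synthesis",
            stoichiometry={"s": -1.0, "atp": -1.0, polymer: 1.0},
            lower_bound=0.0,
            upper_bound=upper,
            role=f"storage_synthesis:{pool_id}",
        ),
        Reaction(
            id=f"deg_{pool_id}",
            name=f"{pool_id} degradation",
            stoichiometry={polymer: -1.0, "s": 1.0},
            lower_bound=0.0,
            upper_bound=upper,
            role=f"storage_degradation:{pool_id}",
        ),
    ]


def make_toy_model(
    variant: str = "linear",
    q_max: float = 10.0,
    gam: float = 2.0,
    ngam: float = 1.0,
    upper: float = 1000.0,
) -> MetabolicModel:
    """Build a toy model.  ``q_max`` caps substrate uptake, in mmol/(g-DW.h)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown toy variant {variant!r}; expected one of {VARIANTS}")
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    if gam < 0 or ngam < 0:
        raise ValueError("GAM and NGAM must be non-negative")

    metabolites = [
        Metabolite("s_ext", "substrate (external)", _GLUCOSE, compartment="external"),
        Metabolite("s", "substrate", _GLUCOSE),
        Metabolite("atp", "ATP equivalent", Formula()),
        Metabolite("sto_glyc", "storage polymer (glycogen-like)", _GLUCOSE),
        Metabolite("bio", "biomass", Formula(C=1, H=2, O=1)),
        Metabolite("bio_ext", "biomass (drained)", Formula(C=1, H=2, O=1),
                   compartment="external"),
    ]
    biomass_stoich = {"s": -1.0, "bio": 1.0}
    if gam > 0:
        biomass_stoich["atp"] = -gam
    reactions = [
        Reaction("upt", {"s_ext": -1.0, "s": 1.0}, 0.0, q_max,
                 name="substrate uptake"),
        Reaction("cat", {"s": -1.0, "atp": 2.0}, 0.0, upper,
                 name="catabolism"),
        Reaction("biomass", biomass_stoich, 0.0, upper,
                 name="biomass formation", role="biomass"),
        Reaction("drain_bio", {"bio": -1.0, "bio_ext": 1.0}, 0.0, upper,
                 name="biomass drain"),
        Reaction("maint", {"atp": -1.0}, ngam, upper,
                 name="ATP maintenance", role="atp_maintenance"),
        *_storage_reactions("glyc", upper),
    ]
    pools = [
        StoragePool("glyc", "sto_glyc", _GLUCOSE, ("syn_glyc",), ("deg_glyc",)),
    ]

    if variant == "redundant":
        metabolites.append(Metabolite("x", "catabolic intermediate", _GLUCOSE))
        reactions.append(Reaction("cat_alt1", {"s": -1.0, "x": 1.0}, 0.0, upper,
                                  name="alternate catabolism step 1"))
        reactions.append(Reaction("cat_alt2", {"x": -1.0, "atp": 2.0}, 0.0, upper,
                                  name="alternate catabolism step 2"))
    elif variant == "two_pool":
        metabolites.append(
            Metabolite("sto_phb", "storage polymer (PHB-like)", _GLUCOSE)
        )
        reactions.extend(_storage_reactions("phb", upper))
        pools.append(
            StoragePool("phb", "sto_phb", _GLUCOSE, ("syn_phb",), ("deg_phb",))
        )

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        storage_pools=pools,
        gam=gam,
        ngam=ngam,
        name=f"toy-{variant}",
    )
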
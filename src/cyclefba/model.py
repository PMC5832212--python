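"""Stoichiometric model representation and COD unit conversions.

The central object is :class:`MetabolicModel`: a metabolite/reaction network
with annotated biomass, ATP-maintenance and storage-pool reactions, from
which the stoichiometric matrix ``S`` (one row per *internal* metabolite,
one column per reaction) is built.  External metabolites are boundary
species and are excluded from the balanced rows, following the usual
COBRA/SBML-FBC convention, so that the steady-state system ``S @ v = 0``
is well posed.

Chemical oxygen demand (COD) is the common currency used to compare
substrate, biomass and storage fluxes in feast-famine reactor studies.
:func:`cod_per_mmol` converts an elemental formula into oxygen equivalents
for full oxidation to CO2 and H2O with nitrogen released as NH3 (no
nitrification), which matches standard COD analytics for activated-sludge
systems.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Formula",
    "Metabolite",
    "Reaction",
    "StoragePool",
    "MetabolicModel",
    "ModelValidationError",
    "cod_per_mmol",
    "specific_flux_to_cod",
    "cod_flux_to_specific",
    "set_maintenance",
    "parse_formula",
]

#: Oxygen demand per electron-mole pair: 8 g-O2 per electron equivalent.
_G_O2_PER_ELECTRON = 8.0

#: Default biomass oxygen equivalence, g-COD per g dry weight.  The classic
#: value for the composition CH1.8O0.5N0.2; configurable on the model.
DEFAULT_BIOMASS_COD_FACTOR = 1.42


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Elemental composition; only C, H, O, N enter COD computation."""

    C: int = 0
    H: int = 0
    O: int = 0
    N: int = 0
    other: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for el, cnt in (("C", self.C), ("H", self.H), ("O", self.O), ("N", self.N)):
            if cnt < 0:
                raise ValueError(f"negative element count for {el}: {cnt}")

    def __add__(self, rhs: "Formula") -> "Formula":
        other: dict[str, int] = dict(self.other)
        for el, n in rhs.other:
            other[el] = other.get(el, 0) + n
        return Formula(
            C=self.C + rhs.C,
            H=self.H + rhs.H,
            O=self.O + rhs.O,
            N=self.N + rhs.N,
            other=tuple(sorted(other.items())),
        )

    def to_string(self) -> str:
        parts = []
        for el, n in (("C", self.C), ("H", self.H), ("O", self.O), ("N", self.N)):
            if n:
                parts.append(f"{el}{n if n != 1 else ''}")
        for el, n in self.other:
            if n:
                parts.append(f"{el}{n if n != 1 else ''}")
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``C6H12O6`` or ``CO2``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r}")
    main = {el: counts.pop(el, 0) for el in ("C", "H", "O", "N")}
    return Formula(**main, other=tuple(sorted(counts.items())))


def cod_per_mmol(formula: Formula) -> float:
    """Theoretical oxygen demand of one mmol, in g-COD.

    Electron balance for CcHhOoNn + x O2 -> c CO2 + (h-3n)/2 H2O + n NH3
    gives x = (4c + h - 2o - 3n)/4 mol O2, i.e. 8*(4c + h - 2o - 3n) g-O2
    per mol.  Fully oxidised species (CO2, H2O) and negative degenerate
    formulas return 0.
    """
    electrons = 4 * formula.C + formula.H - 2 * formula.O - 3 * formula.N
    return max(_G_O2_PER_ELECTRON * electrons / 1000.0, 0.0)


def specific_flux_to_cod(
    v: float, formula: Formula, biomass_cod_factor: float = DEFAULT_BIOMASS_COD_FACTOR
) -> float:
    """Convert mmol/(g-DW.h) to g-COD/(g-COD-biomass.d).

    Multiplies by the compound's COD content and 24 h/d, and divides by the
    biomass oxygen equivalence (g-COD per g-DW) to put the rate on a
    COD-biomass basis.
    """
    if biomass_cod_factor <= 0:
        raise ValueError("biomass_cod_factor must be positive")
    return v * cod_per_mmol(formula) * 24.0 / biomass_cod_factor


def cod_flux_to_specific(
    r: float, formula: Formula, biomass_cod_factor: float = DEFAULT_BIOMASS_COD_FACTOR
) -> float:
    """Inverse of :func:`specific_flux_to_cod` (g-COD/(g-COD.d) -> mmol/(g-DW.h))."""
    if biomass_cod_factor <= 0:
        raise ValueError("biomass_cod_factor must be positive")
    per_mmol = cod_per_mmol(formula)
    if per_mmol <= 0:
        raise ValueError(f"compound {formula.to_string()!r} carries no COD")
    return r * biomass_cod_factor / (24.0 * per_mmol)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: Formula = field(default_factory=Formula)
    charge: int = 0
    compartment: str = "internal"  # internal | external

    @property
    def is_external(self) -> bool:
        return self.compartment == "external"


# Reaction role tokens.  Storage roles carry the pool id after the colon,
# e.g. "storage_synthesis:phb".
ROLE_GENERIC = "generic"
ROLE_EXCHANGE = "exchange"
ROLE_BIOMASS = "biomass"
ROLE_MAINTENANCE = "atp_maintenance"
ROLE_STORAGE_SYNTHESIS = "storage_synthesis"
ROLE_STORAGE_DEGRADATION = "storage_degradation"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    role: str = ROLE_GENERIC

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def base_role(self) -> str:
        return self.role.split(":", 1)[0]

    @property
    def pool_id(self) -> str | None:
        if ":" in self.role:
            return self.role.split(":", 1)[1]
        return None


@dataclass(frozen=True)
class StoragePool:
    """An intracellular storage polymer (glycogen, PHB, TAG, ...).

    The polymer metabolite accumulates during feast and is consumed during
    famine; its per-phase mass balance is relaxed and replaced by the
    across-cycle coupling constraint when solving coupled cycles.
    """

    id: str
    polymer_metabolite: str
    monomer_formula: Formula
    synthesis_reactions: tuple[str, ...]
    degradation_reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.synthesis_reactions or not self.degradation_reactions:
            raise ModelValidationError(
                f"storage pool {self.id!r}: synthesis and degradation sets "
                "must both be non-empty"
            )
        if set(self.synthesis_reactions) & set(self.degradation_reactions):
            raise ModelValidationError(
                f"storage pool {self.id!r}: synthesis and degradation sets overlap"
            )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    storage_pools: list[StoragePool] = field(default_factory=list)
    biomass_reaction: str | None = None
    maintenance_reaction: str | None = None
    atp_metabolite: str = "atp"
    gam: float = 0.0
    ngam: float = 0.0
    biomass_cod_factor: float = DEFAULT_BIOMASS_COD_FACTOR
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def pool(self, pool_id: str) -> StoragePool:
        for p in self.storage_pools:
            if p.id == pool_id:
                return p
        raise KeyError(pool_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_external]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
            if rxn.base_role == ROLE_EXCHANGE:
                touched = [m for m, c in rxn.stoichiometry.items() if c != 0]
                if len(touched) != 1 or not self._met_index[touched[0]].is_external:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id!r} must touch exactly one "
                        "external metabolite"
                    )

        for role, attr in ((ROLE_BIOMASS, "biomass_reaction"),
                           (ROLE_MAINTENANCE, "maintenance_reaction")):
            flagged = [r.id for r in self.reactions if r.base_role == role]
            if len(flagged) > 1:
                raise ModelValidationError(f"multiple {role} reactions: {flagged}")
            if flagged and getattr(self, attr) is None:
                setattr(self, attr, flagged[0])
        if self.biomass_reaction is None:
            raise ModelValidationError("model has no biomass reaction")
        if self.biomass_reaction not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )

        for pool in self.storage_pools:
            for rid in (*pool.synthesis_reactions, *pool.degradation_reactions):
                if rid not in self._rxn_index:
                    raise ModelValidationError(
                        f"storage pool {pool.id!r} references unknown reaction {rid!r}"
                    )
            if pool.polymer_metabolite not in self._met_index:
                raise ModelValidationError(
                    f"storage pool {pool.id!r} references unknown metabolite "
                    f"{pool.polymer_metabolite!r}"
                )

        used = set()
        for rxn in self.reactions:
            used.update(m for m, c in rxn.stoichiometry.items() if c != 0)
        orphan = [m for m in self.internal_metabolite_ids if m not in used]
        if orphan:
            raise ModelValidationError(
                f"internal metabolites appear in no reaction: {orphan}"
            )

    # -- matrix construction ----------------------------------------------
    def stoichiometric_matrix(
        self, exclude_metabolites: set[str] | frozenset[str] = frozenset()
    ) -> tuple[np.ndarray, list[str]]:
        """Dense S over internal metabolites (rows) x reactions (columns).

        ``exclude_metabolites`` drops rows, used to relax storage-polymer
        balances in coupled-cycle problems.
        """
        rows = [m for m in self.internal_metabolite_ids if m not in exclude_metabolites]
        row_index = {m: i for i, m in enumerate(rows)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                i = row_index.get(met_id)
                if i is not None:
                    S[i, j] += coeff
        return S, rows

    def metabolite_row(self, met_id: str) -> np.ndarray:
        """Stoichiometric row of one metabolite across all reactions."""
        row = np.zeros(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            row[j] += rxn.stoichiometry.get(met_id, 0.0)
        return row

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            storage_pools=list(self.storage_pools),
            biomass_reaction=self.biomass_reaction,
            maintenance_reaction=self.maintenance_reaction,
            atp_metabolite=self.atp_metabolite,
            gam=self.gam,
            ngam=self.ngam,
            biomass_cod_factor=self.biomass_cod_factor,
            name=self.name,
        )


def set_maintenance(
    model: MetabolicModel,
    gam: float,
    ngam: float,
    ngam_as_equality: bool = False,
) -> MetabolicModel:
    """Return a copy with maintenance energies set.

    GAM (growth-associated maintenance, mmol-ATP per g-DW of biomass formed)
    becomes the ATP consumption coefficient of the biomass reaction; NGAM
    (non-growth-associated, mmol-ATP/(g-DW.h)) becomes the lower bound of the
    ATP-maintenance reaction (and its upper bound too when
    ``ngam_as_equality`` is set).
    """
    if gam < 0 or ngam < 0:
        raise ValueError("GAM and NGAM must be non-negative")
    out = model.copy()
    atp = model.atp_metabolite
    new_reactions = []
    for rxn in out.reactions:
        if rxn.id == out.biomass_reaction:
            stoich = dict(rxn.stoichiometry)
            if gam > 0:
                stoich[atp] = -gam
            else:
                stoich.pop(atp, None)
            rxn = replace(rxn, stoichiometry=stoich)
        elif out.maintenance_reaction is not None and rxn.id == out.maintenance_reaction:
            ub = ngam if ngam_as_equality else max(rxn.upper_bound, ngam)
            rxn = replace(rxn, lower_bound=ngam, upper_bound=ub)
        new_reactions.append(rxn)
    out.reactions = new_reactions
    out.gam = gam
    out.ngam = ngam
    out.validate()
    return out
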
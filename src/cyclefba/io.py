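"""Model file I/O.

Two formats are supported:

* ``native`` — a structured YAML document with ``metabolites``,
  ``reactions``, ``pools`` and ``settings`` sections (schema version 1).
  This is the only format with write support; write-then-read round-trips
  the network exactly.
* ``sbml_fbc`` — SBML Level 3 with the Flux Balance Constraints package,
  read through python-libsbml.  Flux bounds and the active objective are
  honoured; role annotations (biomass, maintenance, storage pools) that a
  plain SBML file cannot express are supplied through ``role_config``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import yaml

from .model import (
    Formula,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    StoragePool,
    parse_formula,
)

__all__ = ["load_model", "write_native", "load_native", "load_sbml"]

NATIVE_FORMAT_TAG = "cyclefba-model"
NATIVE_SCHEMA_VERSION = 1

_INF_TOKENS = {"inf", "+inf", "infinity"}


def _num(value: Any) -> float:
    if isinstance(value, str):
        token = value.strip().lower()
        if token in _INF_TOKENS:
            return math.inf
        if token in {"-inf", "-infinity"}:
            return -math.inf
    return float(value)


def load_model(path: str | Path, format: str = "native", **kwargs) -> MetabolicModel:
    """Load a model from ``path`` in the given format (``native`` | ``sbml_fbc``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    if format == "native":
        return load_native(path)
    if format == "sbml_fbc":
        return load_sbml(path, **kwargs)
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# native format
# ---------------------------------------------------------------------------

def load_native(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != NATIVE_FORMAT_TAG:
        raise ModelValidationError(
            f"{path}: not a {NATIVE_FORMAT_TAG} document (missing format tag)"
        )
    version = doc.get("version", NATIVE_SCHEMA_VERSION)
    if version != NATIVE_SCHEMA_VERSION:
        raise ModelValidationError(f"{path}: unsupported schema version {version}")

    metabolites = []
    for entry in doc.get("metabolites", []):
        metabolites.append(
            Metabolite(
                id=str(entry["id"]),
                name=str(entry.get("name", "")),
                formula=parse_formula(str(entry.get("formula", ""))),
                charge=int(entry.get("charge", 0)),
                compartment=str(entry.get("compartment", "internal")),
            )
        )

    reactions = []
    for entry in doc.get("reactions", []):
        rxn_id = str(entry["id"])
        stoich_raw = entry.get("stoichiometry", {})
        if not isinstance(stoich_raw, dict):
            raise ModelValidationError(
                f"{path}: reaction {rxn_id!r} stoichiometry must be a mapping"
            )
        reactions.append(
            Reaction(
                id=rxn_id,
                name=str(entry.get("name", "")),
                stoichiometry={str(k): float(v) for k, v in stoich_raw.items()},
                lower_bound=_num(entry.get("lower_bound", 0.0)),
                upper_bound=_num(entry.get("upper_bound", 1000.0)),
                role=str(entry.get("role", "generic")),
            )
        )

    pools = []
    for entry in doc.get("pools", []):
        pools.append(
            StoragePool(
                id=str(entry["id"]),
                polymer_metabolite=str(entry["polymer_metabolite"]),
                monomer_formula=parse_formula(str(entry["monomer_formula"])),
                synthesis_reactions=tuple(entry.get("synthesis_reactions", ())),
                degradation_reactions=tuple(entry.get("degradation_reactions", ())),
            )
        )

    settings = doc.get("settings", {}) or {}
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        storage_pools=pools,
        biomass_reaction=settings.get("biomass_reaction"),
        maintenance_reaction=settings.get("maintenance_reaction"),
        atp_metabolite=settings.get("atp_metabolite", "atp"),
        gam=float(settings.get("gam", 0.0)),
        ngam=float(settings.get("ngam", 0.0)),
        biomass_cod_factor=float(settings.get("biomass_cod_factor", 1.42)),
        name=str(doc.get("name", "")),
    )


def _bound_repr(value: float) -> Any:
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return value


def write_native(model: MetabolicModel, path: str | Path) -> None:
    doc: dict[str, Any] = {
        "format": NATIVE_FORMAT_TAG,
        "version": NATIVE_SCHEMA_VERSION,
        "name": model.name,
        "settings": {
            "biomass_reaction": model.biomass_reaction,
            "maintenance_reaction": model.maintenance_reaction,
            "atp_metabolite": model.atp_metabolite,
            "gam": model.gam,
            "ngam": model.ngam,
            "biomass_cod_factor": model.biomass_cod_factor,
        },
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula.to_string(),
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": _bound_repr(r.lower_bound),
                "upper_bound": _bound_repr(r.upper_bound),
                "role": r.role,
            }
            for r in model.reactions
        ],
        "pools": [
            {
                "id": p.id,
                "polymer_metabolite": p.polymer_metabolite,
                "monomer_formula": p.monomer_formula.to_string(),
                "synthesis_reactions": list(p.synthesis_reactions),
                "degradation_reactions": list(p.degradation_reactions),
            }
            for p in model.storage_pools
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

_EXTERNAL_COMPARTMENTS = {"e", "ext", "extracellular", "external", "e0"}


def _clip(sid: str, prefix: str) -> str:
    # SBML-FBC identifier convention prefixes species with "M_" and
    # reactions with "R_"; strip them so ids match the native format.
    if sid.startswith(prefix) and len(sid) > len(prefix):
        return sid[len(prefix):]
    return sid


def load_sbml(
    path: str | Path,
    role_config: dict[str, Any] | None = None,
) -> MetabolicModel:
    """Read an SBML L3+FBC model.

    ``role_config`` may carry keys ``biomass`` (reaction id; defaults to the
    maximised reaction of the active FBC objective), ``maintenance``
    (reaction id), ``atp_metabolite``, ``biomass_cod_factor`` and ``pools``
    (a list of native-format pool mappings).  Species with
    ``boundaryCondition=true`` or living in an extracellular compartment are
    treated as external.
    """
    import libsbml

    role_config = role_config or {}
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"{path}: SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: SBML document contains no model")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        fbc_sp = sp.getPlugin("fbc")
        formula = Formula()
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = parse_formula(fbc_sp.getChemicalFormula())
        charge = 0
        if fbc_sp is not None and fbc_sp.isSetCharge():
            charge = fbc_sp.getCharge()
        external = (
            sp.getBoundaryCondition()
            or sp.getCompartment().lower() in _EXTERNAL_COMPARTMENTS
        )
        metabolites.append(
            Metabolite(
                id=_clip(sp.getId(), "M_"),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment="external" if external else "internal",
            )
        )

    def _parameter_value(pid: str, default: float) -> float:
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else default

    fbc_model = sbml_model.getPlugin("fbc")
    biomass_id = role_config.get("biomass")
    objective_sense = 1.0
    if biomass_id is None and fbc_model is not None:
        objective = fbc_model.getActiveObjective()
        if objective is not None and objective.getNumFluxObjectives() > 0:
            flux_obj = objective.getFluxObjective(0)
            biomass_id = _clip(flux_obj.getReaction(), "R_")
            if objective.getType() == "minimize":
                objective_sense = -1.0

    reactions = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            sid = _clip(ref.getSpecies(), "M_")
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            sid = _clip(ref.getSpecies(), "M_")
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        fbc_rx = rx.getPlugin("fbc")
        if fbc_rx is not None and fbc_rx.isSetLowerFluxBound():
            lb = _parameter_value(fbc_rx.getLowerFluxBound(), -math.inf)
            ub = _parameter_value(fbc_rx.getUpperFluxBound(), math.inf)
        else:
            lb = -1000.0 if rx.getReversible() else 0.0
            ub = 1000.0
        role = "generic"
        rxn_id = _clip(rx.getId(), "R_")
        if rxn_id == biomass_id:
            role = "biomass"
        elif rxn_id == role_config.get("maintenance"):
            role = "atp_maintenance"
        else:
            touched = [m for m, c in stoich.items() if c != 0]
            if len(touched) == 1 and any(
                m.id == touched[0] and m.is_external for m in metabolites
            ):
                role = "exchange"
        reactions.append(
            Reaction(
                id=rxn_id,
                name=rx.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                role=role,
            )
        )
    del objective_sense  # sense is normalised away: biomass is always maximised

    pools = [
        StoragePool(
            id=str(entry["id"]),
            polymer_metabolite=str(entry["polymer_metabolite"]),
            monomer_formula=parse_formula(str(entry["monomer_formula"])),
            synthesis_reactions=tuple(entry.get("synthesis_reactions", ())),
            degradation_reactions=tuple(entry.get("degradation_reactions", ())),
        )
        for entry in role_config.get("pools", [])
    ]

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        storage_pools=pools,
        biomass_reaction=biomass_id,
        maintenance_reaction=role_config.get("maintenance"),
        atp_metabolite=role_config.get("atp_metabolite", "atp"),
        biomass_cod_factor=float(role_config.get("biomass_cod_factor", 1.42)),
        name=sbml_model.getId() or sbml_model.getName(),
    )
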
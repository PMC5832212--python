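import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyclefba.fba import maximize_growth
from cyclefba.io import load_model, load_native, write_native
from cyclefba.model import (
    Formula,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    cod_per_mmol,
    parse_formula,
    set_maintenance,
    specific_flux_to_cod,
)
from cyclefba.toy import make_toy_model, toy_growth_optimum


class TestFormula:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("C6H12O6", Formula(C=6, H=12, O=6)),
            ("CO2", Formula(C=1, O=2)),
            ("C2H4O2", Formula(C=2, H=4, O=2)),
            ("NH3", Formula(H=3, N=1)),
            ("CH1O1", Formula(C=1, H=1, O=1)),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_formula(text) == expected

    def test_parse_keeps_other_elements(self):
        f = parse_formula("C10H12N5O13P3")
        assert f.other == (("P", 3),)
        assert parse_formula(f.to_string()) == f

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_formula("C6H12O6!")


class TestCOD:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            # glucose: C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O, 192 g-O2/mol
            (Formula(C=6, H=12, O=6), 0.192),
            # acetate: 2 O2 per mol, 64 g/mol
            (Formula(C=2, H=4, O=2), 0.064),
            (Formula(C=1, O=2), 0.0),      # CO2, fully oxidised
            (Formula(H=2, O=1), 0.0),      # water
            (Formula(N=1, H=3), 0.0),      # ammonia is the N reference state
        ],
    )
    def test_reference_compounds(self, formula, expected):
        assert cod_per_mmol(formula) == pytest.approx(expected, abs=1e-12)

    @given(
        st.integers(0, 20), st.integers(0, 40), st.integers(0, 20),
        st.integers(0, 5), st.integers(0, 20), st.integers(0, 40),
        st.integers(0, 20), st.integers(0, 5),
    )
    def test_additive_over_formula_sums(self, c1, h1, o1, n1, c2, h2, o2, n2):
        f1, f2 = Formula(c1, h1, o1, n1), Formula(c2, h2, o2, n2)
        if cod_per_mmol(f1) > 0 and cod_per_mmol(f2) > 0:
            assert cod_per_mmol(f1 + f2) == pytest.approx(
                cod_per_mmol(f1) + cod_per_mmol(f2), abs=1e-12
            )

    def test_specific_flux_conversion(self):
        glc = Formula(C=6, H=12, O=6)
        assert specific_flux_to_cod(1.0, glc, 1.42) == pytest.approx(
            0.192 * 24 / 1.42
        )
        assert specific_flux_to_cod(0.0, glc, 1.42) == 0.0
        assert specific_flux_to_cod(2.0, glc, 1.42) == pytest.approx(
            2 * specific_flux_to_cod(1.0, glc, 1.42)
        )
        with pytest.raises(ValueError):
            specific_flux_to_cod(1.0, glc, 0.0)


class TestMaintenance:
    def test_values_land_in_network(self, linear_toy):
        m = set_maintenance(linear_toy, gam=475.0, ngam=7.0)
        assert m.reaction("biomass").stoichiometry["atp"] == -475.0
        assert m.reaction("maint").lower_bound == 7.0

    def test_zero_removes_atp_term(self, linear_toy):
        m = set_maintenance(linear_toy, 0.0, 0.0)
        assert "atp" not in m.reaction("biomass").stoichiometry
        assert m.reaction("maint").lower_bound == 0.0

    def test_negative_rejected(self, linear_toy):
        with pytest.raises(ValueError):
            set_maintenance(linear_toy, -1.0, 5.0)

    def test_other_stoichiometry_untouched(self, linear_toy):
        m = set_maintenance(linear_toy, 475.0, 7.0)
        assert m.reaction("cat").stoichiometry == linear_toy.reaction("cat").stoichiometry
        assert m.reaction("biomass").stoichiometry["s"] == -1.0


class TestNativeRoundTrip:
    def test_roundtrip_identity(self, linear_toy, tmp_path):
        path = tmp_path / "toy.yaml"
        write_native(linear_toy, path)
        reloaded = load_model(path)
        assert len(reloaded.reactions) == 7
        assert len(reloaded.internal_metabolite_ids) == 4
        S0, rows0 = linear_toy.stoichiometric_matrix()
        S1, rows1 = reloaded.stoichiometric_matrix()
        assert rows0 == rows1
        assert (S0 == S1).all()
        assert reloaded.bounds() == linear_toy.bounds()
        assert [r.role for r in reloaded.reactions] == [
            r.role for r in linear_toy.reactions
        ]
        assert [p.id for p in reloaded.storage_pools] == ["glyc"]

    def test_roundtrip_preserves_infinite_bounds(self, tmp_path):
        model = make_toy_model("linear", upper=math.inf)
        path = tmp_path / "toy.yaml"
        write_native(model, path)
        assert load_native(path).bounds() == model.bounds()

    def test_unknown_metabolite_names_reaction(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "format: cyclefba-model\nversion: 1\n"
            "metabolites:\n- {id: a, compartment: internal}\n"
            "reactions:\n"
            "- {id: biomass, role: biomass, stoichiometry: {a: -1, X_missing: 1}}\n"
        )
        with pytest.raises(ModelValidationError, match="biomass.*X_missing"):
            load_model(path)

    def test_missing_biomass_is_validation_error(self):
        with pytest.raises(ModelValidationError, match="biomass"):
            MetabolicModel(
                metabolites=[Metabolite("a")],
                reactions=[Reaction("r", {"a": -1.0}, -1.0, 1.0)],
            )

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.yaml")


class TestSBML:
    def test_cross_format_equality(self, linear_toy, tmp_path):
        """An SBML-FBC encoding of the toy loads to the same network."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("toy")
        mets = {}
        for met in linear_toy.metabolites:
            cmet = cobra.Metabolite(
                met.id,
                formula=met.formula.to_string() or None,
                compartment="e" if met.is_external else "c",
            )
            mets[met.id] = cmet
        for rxn in linear_toy.reactions:
            cr = cobra.Reaction(rxn.id)
            cm.add_reactions([cr])
            cr.add_metabolites(
                {mets[m]: c for m, c in rxn.stoichiometry.items()}
            )
            cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        cm.objective = "biomass"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cm, str(path))

        loaded = load_model(
            path, format="sbml_fbc",
            role_config={
                "maintenance": "maint",
                "pools": [{
                    "id": "glyc", "polymer_metabolite": "sto_glyc",
                    "monomer_formula": "C6H12O6",
                    "synthesis_reactions": ["syn_glyc"],
                    "degradation_reactions": ["deg_glyc"],
                }],
            },
        )
        assert loaded.biomass_reaction == "biomass"
        s_native = {
            (m, r.id): c
            for r in linear_toy.reactions
            for m, c in r.stoichiometry.items()
        }
        s_sbml = {
            (m, r.id): c
            for r in loaded.reactions
            for m, c in r.stoichiometry.items()
        }
        assert s_native == s_sbml
        assert dict(zip(loaded.reaction_ids, loaded.bounds())) == dict(
            zip(linear_toy.reaction_ids, linear_toy.bounds())
        )
        assert maximize_growth(loaded).objective == pytest.approx(4.75, abs=1e-8)


class TestToyModel:
    def test_closed_form_reference_point(self):
        assert toy_growth_optimum(10, 2, 1) == pytest.approx(4.75)

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            make_toy_model("bogus")

    @pytest.mark.parametrize("variant", ["linear", "redundant", "two_pool"])
    def test_storage_roles_flagged(self, variant):
        model = make_toy_model(variant)
        for pool in model.storage_pools:
            for rid in pool.synthesis_reactions:
                assert model.reaction(rid).role == f"storage_synthesis:{pool.id}"
            for rid in pool.degradation_reactions:
                assert model.reaction(rid).role == f"storage_degradation:{pool.id}"
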
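"""Network structure, flux-law arithmetic and stoichiometric assembly."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raavmet as rm
from raavmet.model import ModelValidationError, Parameter

from conftest import TOY_AB


class TestShippedStructure:
    def test_network_census(self, shipped_model):
        m = shipped_model
        assert m.n_species == 53
        assert m.n_fluxes == 32
        assert len(m.km_names) == 52
        assert len(m.vmax_names) == 37
        assert len(m.auxiliary_outputs) == 3

    def test_parameter_counts(self, shipped_model):
        counts = rm.count_parameters(shipped_model)
        assert counts == {
            "n_Km": 52,
            "n_vmax": 37,
            "n_kinetic": 89,
            "n_initial": 53,
            "n_total": 142,
        }

    def test_observed_species(self, shipped_model):
        observed = [s.id for s in shipped_model.species if s.observed]
        assert sorted(observed) == ["Glc", "Gln", "GluAc", "Lac", "NH4"]
        assert shipped_model.observation_order == ["Gln", "GluAc", "Glc", "Lac", "NH4"]
        # the measured species' t=0 values come from data, hence not fittable
        assert all(
            s.fixed_initial for s in shipped_model.species if s.observed
        )

    def test_reversible_laws(self, shipped_model):
        rev = sorted(l.id for l in shipped_model.flux_laws if l.reversible)
        assert rev == ["FH", "LDH", "PGK", "SD", "TPI"]

    def test_stoichiometric_matrix_shape(self, shipped_model):
        S = shipped_model.stoichiometric_matrix
        assert S.shape == (53 + 3, 32)
        # every flux law drives exactly one reaction column with entries
        assert np.all(np.any(S != 0, axis=0))

    def test_initial_observed_concentrations(self, shipped_model, shipped_params):
        got = [shipped_params[f"c0_{s}"] for s in shipped_model.observation_order]
        assert got == pytest.approx([4.7, 3.59, 28.23, 13.91, 0.97])

    def test_glutamic_acid_only_feeds_viral_proteins(self, shipped_model):
        consumers = [
            r.flux
            for r in shipped_model.reactions
            if r.stoichiometry.get("GluAc", 0) < 0
        ]
        assert sorted(consumers) == ["Cep", "Rep"]


class TestLoadValidation:
    def _broken(self, mutate):
        raw = copy.deepcopy(TOY_AB)
        mutate(raw)
        return raw

    def test_dangling_species_reference(self):
        raw = self._broken(
            lambda r: r["flux_laws"][0]["forward"]["terms"].append(["FOO", "Km_A"])
        )
        with pytest.raises(ModelValidationError, match="FOO"):
            rm.load_model(raw)

    def test_dangling_parameter_reference(self):
        raw = self._broken(
            lambda r: r["flux_laws"][0]["forward"].update(vmax="vmax_MISSING")
        )
        with pytest.raises(ModelValidationError, match="vmax_MISSING"):
            rm.load_model(raw)

    def test_duplicate_species(self):
        raw = self._broken(lambda r: r["species"].append({"id": "A", "c0": 1.0}))
        with pytest.raises(ModelValidationError, match="duplicate"):
            rm.load_model(raw)

    def test_negative_initial_concentration(self):
        raw = self._broken(lambda r: r["species"][0].update(c0=-1.0))
        with pytest.raises(ModelValidationError, match="negative"):
            rm.load_model(raw)

    def test_km_used_as_vmax(self):
        raw = self._broken(
            lambda r: r["flux_laws"][0]["forward"].update(vmax="Km_A")
        )
        with pytest.raises(ModelValidationError, match="kind"):
            rm.load_model(raw)

    def test_reaction_without_law(self):
        raw = self._broken(
            lambda r: r["reactions"].append({"flux": "NOPE", "stoich": {"A": -1}})
        )
        with pytest.raises(ModelValidationError, match="NOPE"):
            rm.load_model(raw)

    def test_parameter_kind_and_value_guards(self):
        with pytest.raises(ModelValidationError, match="kind"):
            Parameter("p", "velocity", 1.0)
        with pytest.raises(ModelValidationError):
            Parameter("p", "Km", -0.1)


class TestEvaluateFlux:
    def test_single_substrate_value(self, shipped_model, shipped_params):
        # PGI at the shipped G6P level: one saturation fraction
        law = shipped_model.flux_law("PGI")
        v = rm.evaluate_flux(law, {"G6P": 1.255}, shipped_params)
        assert v == pytest.approx(2.283 * 1.255 / (2.165 + 1.255), rel=1e-12)

    def test_zero_substrate_gives_zero_flux(self, shipped_model, shipped_params):
        law = shipped_model.flux_law("HK")
        assert rm.evaluate_flux(law, {"Glc": 0.0, "ATP": 5.0}, shipped_params) == 0.0

    def test_half_saturation_identity(self, toy_model):
        params = toy_model.parameter_set()
        law = toy_model.flux_law("AB")
        v = rm.evaluate_flux(law, {"A": params["Km_A"]}, params)
        assert v == pytest.approx(params["vmax_AB"] / 2, rel=1e-12)

    def test_reversible_balance_point(self, shipped_model, shipped_params):
        # symmetric reversible law: equal forward and reverse products cancel
        law = shipped_model.flux_law("TPI")
        p = shipped_params.updated(
            {"vmax_f_TPI": 1.0, "vmax_r_TPI": 1.0, "Km_DHAP": 0.5, "Km_GAP": 0.5}
        )
        assert rm.evaluate_flux(law, {"DHAP": 2.0, "GAP": 2.0}, p) == pytest.approx(0.0)

    def test_missing_concentration_names_species(self, shipped_model, shipped_params):
        law = shipped_model.flux_law("HK")
        with pytest.raises(KeyError, match="ATP"):
            rm.evaluate_flux(law, {"Glc": 1.0}, shipped_params)

    def test_negative_concentration_rejected(self, shipped_model, shipped_params):
        law = shipped_model.flux_law("PGI")
        with pytest.raises(ValueError, match="G6P"):
            rm.evaluate_flux(law, {"G6P": -0.5}, shipped_params)

    @settings(max_examples=60, deadline=None)
    @given(
        conc=st.floats(0.0, 1e3, allow_nan=False),
        atp=st.floats(0.0, 1e3, allow_nan=False),
    )
    def test_irreversible_flux_bounded_by_vmax(self, shipped_model, conc, atp):
        """0 <= v <= vmax: every saturation term lies in [0, 1]."""
        params = shipped_model.parameter_set()
        law = shipped_model.flux_law("HK")
        v = rm.evaluate_flux(law, {"Glc": conc, "ATP": atp}, params)
        assert 0.0 <= v <= params["vmax_HK"] + 1e-12

    @settings(max_examples=40, deadline=None)
    @given(
        lo=st.floats(0.0, 50.0, allow_nan=False),
        bump=st.floats(0.0, 50.0, allow_nan=False),
    )
    def test_flux_monotone_in_substrate(self, shipped_model, lo, bump):
        params = shipped_model.parameter_set()
        law = shipped_model.flux_law("HK")
        v1 = rm.evaluate_flux(law, {"Glc": lo, "ATP": 2.0}, params)
        v2 = rm.evaluate_flux(law, {"Glc": lo + bump, "ATP": 2.0}, params)
        assert v2 >= v1 - 1e-12


class TestAssembleRates:
    def test_zero_vmax_gives_zero_rates(self, shipped_model, shipped_params):
        p = shipped_params.updated({n: 0.0 for n in shipped_model.vmax_names})
        conc = {s.id: s.initial_concentration for s in shipped_model.species}
        rates = rm.assemble_rates(shipped_model, conc, p)
        assert all(v == 0.0 for v in rates.values())

    def test_toy_conservation(self, toy_model):
        params = toy_model.parameter_set()
        rates = rm.assemble_rates(toy_model, {"A": 4.0, "B": 1.0}, params)
        flux = rm.evaluate_flux(toy_model.flux_law("AB"), {"A": 4.0}, params)
        assert rates["A"] == pytest.approx(-flux)
        assert rates["B"] == pytest.approx(+flux)

    def test_glucose_only_consumed(self, shipped_model, shipped_params):
        rng = np.random.default_rng(0)
        base = {s.id: s.initial_concentration for s in shipped_model.species}
        for _ in range(5):
            conc = {k: v * rng.uniform(0.0, 2.0) for k, v in base.items()}
            rates = rm.assemble_rates(shipped_model, conc, shipped_params)
            assert rates["Glc"] <= 0.0

    def test_matches_bruteforce_accumulation(self, shipped_model, shipped_params):
        """S @ v equals a per-reaction accumulation loop (independent oracle)."""
        rng = np.random.default_rng(42)
        base = {s.id: s.initial_concentration for s in shipped_model.species}
        conc = {k: v * rng.uniform(0.2, 1.8) for k, v in base.items()}
        fast = rm.assemble_rates(shipped_model, conc, shipped_params)
        brute = {sid: 0.0 for sid in shipped_model.state_ids}
        for rxn in shipped_model.reactions:
            v = rm.evaluate_flux(
                shipped_model.flux_law(rxn.flux), conc, shipped_params
            )
            for sid, coef in rxn.stoichiometry.items():
                brute[sid] += coef * v
        for sid in shipped_model.state_ids:
            assert fast[sid] == pytest.approx(brute[sid], rel=1e-10, abs=1e-14)

    def test_shared_km_touches_only_atp_laws(self, shipped_model, shipped_params):
        """Km_ATP is shared via the registry: bumping it moves exactly the
        fluxes whose law contains an ATP saturation term."""
        conc = {s.id: max(s.initial_concentration, 0.1) for s in shipped_model.species}
        bumped = shipped_params.updated({"Km_ATP": shipped_params["Km_ATP"] * 2})
        changed = set()
        atp_laws = set()
        for law in shipped_model.flux_laws:
            terms = list(law.forward_terms) + list(law.reverse_terms)
            if any(km == "Km_ATP" for _, km in terms):
                atp_laws.add(law.id)
            v0 = rm.evaluate_flux(law, conc, shipped_params)
            v1 = rm.evaluate_flux(law, conc, bumped)
            if v0 != v1:
                changed.add(law.id)
        assert changed == atp_laws
        assert atp_laws == {"HK", "PFK", "PGK", "PC", "Glu", "Growth", "Rep", "Cep"}


def test_count_parameters_empty_model():
    m = rm.MetabolicModel([], [], [], [])
    assert rm.count_parameters(m) == {
        "n_Km": 0, "n_vmax": 0, "n_kinetic": 0, "n_initial": 0, "n_total": 0,
    }


def test_parameter_set_updates_are_copies(shipped_params):
    p2 = shipped_params.updated({"vmax_HK": 1.0})
    assert shipped_params["vmax_HK"] != 1.0
    assert p2["vmax_HK"] == 1.0
    with pytest.raises(KeyError):
        shipped_params.updated({"nope": 1.0})
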
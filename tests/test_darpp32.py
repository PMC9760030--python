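"""The DARPP-32 model library: variants, structure, aggregation."""

import numpy as np
import pytest

from sitesim.combinatorics import BindingStep, MultisiteScheme, expand_multisite_binding
from sitesim.core import Species, rule_errors, validate_rule
from sitesim.darpp32 import (
    COMPONENTS,
    ModelVariant,
    aggregate_by_name,
    build_model,
    component_of_rule,
    load_default_params,
)
from sitesim.engine import generate_network
from sitesim.kappa_io import format_rule, normalize_rule
from sitesim.model import SetRate
from sitesim.simulate import ode_run


@pytest.fixture(scope="module")
def wild_obs():
    return build_model(ModelVariant("wild", "oBS"))


class TestVariants:
    def test_all_rules_validate(self, wild_obs):
        for rule in wild_obs.rules:
            assert rule_errors(validate_rule(rule, wild_obs.signatures)) == []

    def test_eight_components_present(self, wild_obs):
        comps = set(component_of_rule(wild_obs).values())
        assert comps == set(COMPONENTS)

    def test_mutation_is_single_zeroed_constant(self, wild_obs):
        """Each in-silico mutation changes exactly one rate constant; the
        rule inventory is identical to wild type."""
        for mutation, expected_rule in (
            ("ser137ala", "CK1_D_s137_cat"),
            ("constser137", "PP2C_D_s137_cat"),
        ):
            mut = build_model(ModelVariant(mutation, "oBS"))
            assert [r.name for r in mut.rules] == [r.name for r in wild_obs.rules]
            diffs = [
                (a.name, a.rate, b.rate)
                for a, b in zip(wild_obs.rules, mut.rules)
                if a.rate != b.rate
            ]
            assert len(diffs) == 1
            name, wild_rate, mut_rate = diffs[0]
            assert name == expected_rule and mut_rate == 0.0 and wild_rate > 0

    def test_binding_variants_same_rule_count(self, wild_obs):
        """Adding independent binding sites (noncompetitive tBS) requires the
        same number of rules; only the DARPP-32 signature changes."""
        tbs = build_model(ModelVariant("wild", "tBS"))
        assert len(tbs.rules) == len(wild_obs.rules)
        assert set(tbs.signatures["D"].sites) == {
            "t34", "t75", "s137", "b1", "b2", "b3",
        }
        assert set(wild_obs.signatures["D"].sites) == {"t34", "t75", "s137", "b"}

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant("superman", "oBS")
        with pytest.raises(ValueError):
            ModelVariant("wild", "xyz")

    def test_missing_rates_listed(self):
        params = load_default_params()
        del params["rates"]["pka_d_cat"]
        del params["rates"]["ca_leak"]
        with pytest.raises(ValueError) as err:
            build_model(ModelVariant(), params)
        assert "pka_d_cat" in str(err.value) and "ca_leak" in str(err.value)

    def test_pp2b_component_is_expander_output(self, wild_obs):
        """The PP2B activation component equals the combinatorial-binding
        expansion of the four-site two-step scheme, rule for rule."""
        params = load_default_params()["rates"]
        scheme = MultisiteScheme(
            "PP2B",
            4,
            "Ca",
            (
                BindingStep(2, params["pp2b_ca_on1"], params["pp2b_ca_off1"]),
                BindingStep(2, params["pp2b_ca_on2"], params["pp2b_ca_off2"]),
            ),
        )
        expected = {
            r.name: format_rule(normalize_rule(r))
            for r in expand_multisite_binding(scheme)
        }
        comp = component_of_rule(wild_obs)
        got = {
            r.name: format_rule(normalize_rule(r))
            for r in wild_obs.rules
            if comp[r.name] == "PP2B activation"
        }
        assert len(got) == 24

        def strip_rate_id(text):
            return text.split("{")[0]

        assert {k: strip_rate_id(v) for k, v in got.items()} == {
            k: strip_rate_id(v) for k, v in expected.items()
        }

    def test_stimulus_protocol_is_event_schedule(self, wild_obs):
        assert len(wild_obs.events) == 21  # one pulse + 20 spikes
        times = [e.time for e in wild_obs.events]
        assert times == sorted(times)


class TestSteadyStateProperties:
    def _prestimulus(self, variant):
        model = build_model(variant)
        seeds = [Species.from_graph(g, model.signatures) for _, g in model.init]
        net = generate_network(model.rules, seeds, model.signatures)
        from sitesim.core import Mixture

        init = Mixture()
        for (n, g), sp in zip(model.init, seeds):
            init.add(sp, n)
        for sp in net.species:
            if init.count(sp) == 0:
                init.add(sp, 0)
        # no stimulus events: pre-stimulus relaxation only
        return ode_run(
            net, init, t_end=50.0, record_dt=10.0, observables=model.observables
        )

    def test_mutants_match_wild_before_stimulus(self):
        """Without the cAMP/Ca stimulus the Ser137 mutations leave the Thr34
        and Thr75 observables at the wild-type baseline."""
        wild = self._prestimulus(ModelVariant("wild", "oBS"))
        for mutation in ("ser137ala", "constser137"):
            mut = self._prestimulus(ModelVariant(mutation, "oBS"))
            for obs in ("D34", "D75", "all_cAMP*"):
                assert mut.values[obs][-1] == pytest.approx(
                    wild.values[obs][-1], rel=0.02, abs=1.0
                )

    def test_obs_vs_tbs_trajectories_agree(self):
        """Competitive (oBS) and noncompetitive (tBS) binding variants give
        matching deterministic trajectories for the shared observables when
        partner pools are far from saturating DARPP-32."""
        a = self._prestimulus(ModelVariant("wild", "oBS"))
        b = self._prestimulus(ModelVariant("wild", "tBS"))
        for obs in ("D34", "D75", "D137", "CK1u"):
            ref = np.maximum(np.abs(a.values[obs]), 1.0)
            assert np.all(np.abs(a.values[obs] - b.values[obs]) / ref < 0.05)


class TestAggregateByName:
    NAMES = {"s1": "CaA", "s2": "B", "s3": "PP2BinactiveCa2", "s4": "D34_PP2B"}

    def test_substring_selection(self):
        matched, definition = aggregate_by_name(self.NAMES, ["Ca"])
        assert set(matched) == {"s1", "s3"}
        assert definition["warnings"] == []

    def test_exclusions(self):
        matched, _ = aggregate_by_name(self.NAMES, ["Ca"], exclusions=["inactive"])
        assert matched == ["s1"]

    def test_empty_patterns_empty_observable(self):
        matched, definition = aggregate_by_name(self.NAMES, [])
        assert matched == [] and definition["matched_species"] == []

    def test_zero_match_warns_not_errors(self):
        matched, definition = aggregate_by_name(self.NAMES, ["XYZ"])
        assert matched == []
        assert any("XYZ" in w for w in definition["warnings"])
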
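"""Reaction -> rule condensation: grouping criterion and round-trip."""

import pytest

from sitesim.condense import condense_reactions, write_report_tsv
from sitesim.core import (
    AgentSignature,
    Reaction,
    SignatureSet,
    Species,
)
from sitesim.engine import expand_rules_over_species, generate_network
from sitesim.fixtures import make_random_rule_system, make_toy
from sitesim.kappa_io import parse_pattern, pattern_to_graph


def _multiset(reactions):
    out = {}
    for r in reactions:
        key = (
            tuple(sorted(s.canonical_id for s in r.reactants)),
            tuple(sorted(s.canonical_id for s in r.products)),
            r.rate,
        )
        out[key] = out.get(key, 0) + 1
    return out


class TestSpectatorCriterion:
    def test_equal_rates_collapse_to_one_rule(self):
        toy = make_toy("phospho_spectator", equal_rates=True)
        rules, report = condense_reactions(toy.reactions)
        assert len(rules) == 1
        assert report.by_component()["phosphorylation"] == (2, 1, 1)
        # the emitted rule is decontextualised: the spectator site is gone
        (rule,) = rules
        assert rule.lhs.agents[0].site("s") is None

    def test_unequal_rates_stay_separate(self):
        toy = make_toy("phospho_spectator", equal_rates=False)
        rules, report = condense_reactions(toy.reactions)
        assert len(rules) == 2
        assert report.by_component()["phosphorylation"] == (2, 2, 2)

    def test_rate_tolerance_groups_near_equal(self):
        toy = make_toy("phospho_spectator", equal_rates=True)
        r1, r2 = toy.reactions
        r2 = Reaction(r2.reactants, r2.products, r1.rate * (1 + 1e-9), r2.rate_id)
        assert len(condense_reactions([r1, r2])[0]) == 2
        assert len(condense_reactions([r1, r2], rate_tolerance=1e-6)[0]) == 1


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2, 5, 9])
    def test_condense_then_expand_is_identity(self, seed):
        """Re-expanding the condensed rules over the original species universe
        regenerates exactly the input reaction multiset (rates included)."""
        toy = make_random_rule_system(seed, n_agents=4, n_rules=5)
        net = generate_network(toy.model.rules, toy.seed_species(), toy.model.signatures)
        if not net.reactions:
            pytest.skip("degenerate random system without reactions")
        rules, _ = condense_reactions(net.reactions)
        universe = [s for s in net.species]
        regenerated = expand_rules_over_species(rules, universe)
        assert _multiset(regenerated) == _multiset(net.reactions)

    def test_catalytic_group_with_bond_context(self):
        """Catalysis on a bound substrate keeps the enzyme bond in the rule
        but drops the spectator phosphosite."""
        sigs = SignatureSet(
            [
                AgentSignature("E", ("b",)),
                AgentSignature("S", ("b", "m", "o"), {"m": ("u", "p"), "o": ("u", "p")}),
            ]
        )

        def sp(expr):
            return Species.from_graph(pattern_to_graph(parse_pattern(expr), sigs), sigs)

        reactions = [
            Reaction(
                (sp(f"E(b!1),S(b!1,m~u,o~{o})"),),
                (sp(f"E(b)"), sp(f"S(b,m~p,o~{o})")),
                0.5,
                "kcat",
                f"cat_{o}",
                "catalysis",
            )
            for o in ("u", "p")
        ]
        rules, report = condense_reactions(reactions)
        assert len(rules) == 1
        (rule,) = rules
        site_names = {spat.site for ap in rule.lhs.agents for spat in ap.sites}
        assert "o" not in site_names
        assert report.by_component()["catalysis"] == (2, 1, 1)


class TestErrorsAndReport:
    def test_unresolvable_species_named(self):
        r = Reaction((Species("mystery", None),), (Species("other", None),), 1.0)
        with pytest.raises(ValueError, match="mystery"):
            condense_reactions([r])

    def test_composition_map_resolves_imported_names(self):
        sigs = SignatureSet([AgentSignature("A", ("x",), {"x": ("u", "p")})])
        comp = {
            "s_u": pattern_to_graph(parse_pattern("A(x~u)"), sigs),
            "s_p": pattern_to_graph(parse_pattern("A(x~p)"), sigs),
        }
        r = Reaction((Species("s_u", None),), (Species("s_p", None),), 0.1, "k")
        rules, _ = condense_reactions([r], composition=comp)
        assert len(rules) == 1

    def test_report_tsv_layout(self, tmp_path):
        toy = make_toy("phospho_spectator", equal_rates=True)
        _, report = condense_reactions(toy.reactions)
        out = tmp_path / "report.tsv"
        write_report_tsv(report, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t") == [
            "component",
            "reactions",
            "rules",
            "unique_rate_constants",
        ]
        assert lines[-1].startswith("total\t2\t1\t1")
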
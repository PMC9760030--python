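"""Embedding search, rule application, and network generation, checked
against brute-force oracles."""

import random

import pytest

from helpers import brute_closure, naive_embeddings

from sitesim.core import (
    AgentSignature,
    Mixture,
    SignatureSet,
    Species,
)
from sitesim.engine import (
    NetworkTooLarge,
    apply_rule,
    find_embeddings,
    generate_network,
)
from sitesim.fixtures import make_random_rule_system, make_toy
from sitesim.kappa_io import parse_pattern, parse_rule_line, pattern_to_graph


D_SIGS = SignatureSet(
    [AgentSignature("D", ("t34", "t75"), {"t34": ("u", "p"), "t75": ("u", "p")})]
)


def _sp(expr, sigs):
    return Species.from_graph(pattern_to_graph(parse_pattern(expr), sigs), sigs)


class TestFindEmbeddings:
    def test_empty_mixture(self):
        assert find_embeddings(parse_pattern("D(t34~p)"), Mixture()) == []

    def test_wildcard_on_unmentioned_site(self):
        """D(t34~p) leaves t75 unspecified: it matches regardless of t75."""
        mix = Mixture()
        for expr in ("D(t34~p,t75~u)", "D(t34~p,t75~p)", "D(t34~u,t75~u)"):
            mix.add(_sp(expr, D_SIGS), 1)
        assert len(find_embeddings(parse_pattern("D(t34~p)"), mix)) == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_counts_match_naive_oracle(self, seed):
        """Embedding counts equal the all-injections brute-force matcher on
        random systems (including symmetric patterns)."""
        toy = make_random_rule_system(seed, n_agents=4, n_rules=5)
        species = {}
        for _, g in toy.model.init:
            sp = Species.from_graph(g)
            species[sp.canonical_id] = sp
        net = generate_network(
            toy.model.rules, list(species.values()), toy.model.signatures
        )
        for rule in toy.model.rules:
            for comp in rule.lhs.components():
                sub = rule.lhs.subpattern(comp)
                for sp in net.species:
                    mine = len(find_embeddings(sub, sp))
                    oracle = len(naive_embeddings(sub, sp.graph))
                    assert mine == oracle, (rule.name, sp.canonical_id)

    def test_symmetric_pattern_counts(self):
        """Two identical monomer patterns embed into a 2-agent mixture in
        ordered fashion — no hidden symmetry deduplication."""
        sigs = SignatureSet([AgentSignature("A", ("x",))])
        dimer = _sp("A(x!1),A(x!1)", sigs)
        embs = find_embeddings(parse_pattern("A(x!1),A(x!1)"), dimer)
        oracle = naive_embeddings(parse_pattern("A(x!1),A(x!1)"), dimer.graph)
        assert len(embs) == len(oracle) == 2


class TestApplyRule:
    def test_state_flip_preserves_complex(self):
        rule = parse_rule_line("'p' D(t34~u?) -> D(t34~p?) @ 1.0")
        mix = Mixture()
        s = _sp("D(t34~u,t75~p)", D_SIGS)
        mix.add(s, 3)
        emb = find_embeddings(rule.lhs, s)[0]
        out = apply_rule(rule, emb, mix, D_SIGS)
        assert out.count(s) == 2
        assert out.count(_sp("D(t34~p,t75~p)", D_SIGS)) == 1
        assert out.total_agents("D") == 3

    def test_degradation_decreases_agent_count(self):
        sigs = SignatureSet([AgentSignature("cAMP", ("b",))])
        rule = parse_rule_line("'deg' cAMP(b) -> . @ 1.0")
        mix = Mixture()
        c = _sp("cAMP(b)", sigs)
        mix.add(c, 5)
        out = apply_rule(rule, find_embeddings(rule.lhs, c)[0], mix, sigs)
        assert out.total_agents("cAMP") == 4

    def test_bind_then_exact_unbind_restores_mixture(self, ab_signatures):
        bind = parse_rule_line("'b' A(x),B(y) -> A(x!1),B(y!1) @ 1.0")
        unbind = parse_rule_line("'u' A(x!1),B(y!1) -> A(x),B(y) @ 1.0")
        mix = Mixture()
        a, b = _sp("A(x)", ab_signatures), _sp("B(y)", ab_signatures)
        mix.add(a, 2)
        mix.add(b, 2)
        ea = find_embeddings(parse_pattern("A(x)"), a)[0]
        eb = find_embeddings(parse_pattern("B(y)"), b)[0]
        bound = apply_rule(bind, [ea, eb], mix, ab_signatures)
        ab = _sp("A(x!1),B(y!1)", ab_signatures)
        assert bound.count(ab) == 1
        e2 = find_embeddings(unbind.lhs, ab)[0]
        restored = apply_rule(unbind, e2, bound, ab_signatures)
        assert restored == mix

    def test_stale_embedding_rejected(self, ab_signatures):
        bind = parse_rule_line("'b' A(x),B(y) -> A(x!1),B(y!1) @ 1.0")
        a, b = _sp("A(x)", ab_signatures), _sp("B(y)", ab_signatures)
        empty = Mixture()
        ea = find_embeddings(parse_pattern("A(x)"), a)[0]
        eb = find_embeddings(parse_pattern("B(y)"), b)[0]
        with pytest.raises(ValueError, match="stale"):
            apply_rule(bind, [ea, eb], empty, ab_signatures)


class TestGenerateNetwork:
    def test_reversible_dimerisation(self, ab_signatures):
        toy = make_toy("dimerisation")
        net = generate_network(
            toy.model.rules, toy.seed_species(), toy.model.signatures
        )
        assert net.n_species == 3
        assert net.n_reactions == 2

    def test_pp2b_ladder_species_census(self, pp2b_scheme):
        from sitesim.combinatorics import expand_multisite_binding, scheme_signatures

        sigs = SignatureSet(scheme_signatures(pp2b_scheme))
        rules = expand_multisite_binding(pp2b_scheme)
        seeds = [_sp("PP2B(ca1,ca2,ca3,ca4)", sigs), _sp("Ca(b)", sigs)]
        net = generate_network(rules, seeds, sigs)
        pp2b = [s for s in net.species if s.agent_count("PP2B")]
        assert len(pp2b) == 8
        by_ca = {}
        for s in pp2b:
            by_ca.setdefault(s.agent_count("Ca"), []).append(s)
        assert {k: len(v) for k, v in by_ca.items()} == {0: 1, 2: 6, 4: 1}

    def test_order_independence(self, seed=3):
        toy = make_random_rule_system(seed, n_agents=4, n_rules=6)
        seeds = toy.seed_species()
        net1 = generate_network(toy.model.rules, seeds, toy.model.signatures)
        rules = list(toy.model.rules)
        random.Random(0).shuffle(rules)
        net2 = generate_network(rules, list(reversed(seeds)), toy.model.signatures)
        assert [s.canonical_id for s in net1.species] == [
            s.canonical_id for s in net2.species
        ]
        assert [r.key() for r in net1.reactions] == [r.key() for r in net2.reactions]

    def test_species_cap_raises(self, ab_signatures):
        rules = [parse_rule_line("'b' A(x),B(y) -> A(x!1),B(y!1) @ 1.0")]
        seeds = [_sp("A(x)", ab_signatures), _sp("B(y)", ab_signatures)]
        with pytest.raises(NetworkTooLarge, match="too large"):
            generate_network(rules, seeds, ab_signatures, species_cap=2)

    @pytest.mark.parametrize("seed", range(10))
    def test_closure_matches_brute_force(self, seed):
        """Reachable species set equals an independent breadth-first oracle."""
        toy = make_random_rule_system(seed, n_agents=3, n_rules=4)
        seeds = toy.seed_species()
        net = generate_network(toy.model.rules, seeds, toy.model.signatures)
        oracle = brute_closure(toy.model.rules, [g for _, g in toy.model.init])
        assert {s.canonical_id for s in net.species} == oracle

    def test_self_binding_rate_doubling(self):
        """A+A self-binding: the generated reaction constant absorbs the two
        component-to-instance assignments, so the propensity with n(n-1)/2
        combinations reproduces embedding counting (k*n*(n-1))."""
        sigs = SignatureSet([AgentSignature("A", ("x",))])
        rules = [parse_rule_line("'dim' A(x),A(x) -> A(x!1),A(x!1) @ 0.5")]
        net = generate_network(rules, [_sp("A(x)", sigs)], sigs)
        (rxn,) = net.reactions
        assert rxn.rate == pytest.approx(1.0)
        assert rxn.multiplicity == 2
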
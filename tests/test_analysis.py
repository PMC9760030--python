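"""Observables, snapshot censuses, replicate summaries, comparison metrics."""

import math

import numpy as np
import pytest

from sitesim.analysis import (
    compare_trajectories,
    census_frame,
    evaluate_observable,
    species_census,
    species_containing,
    summarize_replicates,
)
from sitesim.combinatorics import expand_multisite_binding, scheme_signatures
from sitesim.core import AgentSignature, Mixture, SignatureSet, Species
from sitesim.engine import generate_network
from sitesim.fixtures import make_toy
from sitesim.kappa_io import parse_pattern, pattern_to_graph
from sitesim.model import PatternObservable
from sitesim.simulate import Trajectory, ssa_run


def _sp(expr, sigs):
    return Species.from_graph(pattern_to_graph(parse_pattern(expr), sigs), sigs)


class TestObservables:
    def test_counting_modes(self, pp2b_scheme):
        """A species carrying four ligands contributes 4 per copy in
        agent-instances mode but 1 per copy in species-copies mode."""
        sigs = SignatureSet(scheme_signatures(pp2b_scheme))
        full = _sp(
            "PP2B(ca1!1,ca2!2,ca3!3,ca4!4),Ca(b!1),Ca(b!2),Ca(b!3),Ca(b!4)", sigs
        )
        mix = Mixture()
        mix.add(full, 5)
        ca_pat = parse_pattern("Ca()")
        agents = evaluate_observable(PatternObservable("ca", ca_pat), mix)
        copies = evaluate_observable(
            PatternObservable("ca", ca_pat, "species-copies"), mix
        )
        assert agents == 20
        assert copies == 5
        assert copies <= agents


class TestSnapshots:
    def test_every_event_snapshotted_plus_final(self):
        toy = make_toy("decay", a0=3, k=1.0)
        net = generate_network(toy.model.rules, toy.seed_species(), toy.model.signatures)
        res = ssa_run(
            net, toy.init_mixture(), t_end=100.0, record_dt=10.0, seed=1,
            snapshot_period=1,
        )
        assert res.n_events == 3
        assert len(res.snapshots) == 4  # 3 events + final state
        assert [s.event_index for s in res.snapshots[:-1]] == [1, 2, 3]

    def test_snapshot_conservation(self):
        """Every snapshot of a reversible dimerisation run conserves the
        total copies of each agent."""
        toy = make_toy("dimerisation")
        net = generate_network(toy.model.rules, toy.seed_species(), toy.model.signatures)
        init = toy.init_mixture()
        res = ssa_run(net, init, t_end=20.0, record_dt=1.0, seed=5, snapshot_period=10)
        assert res.snapshots
        for snap in res.snapshots:
            total_a = total_b = 0
            for cid, n in snap.counts.items():
                sp = net.species_by_id(cid)
                total_a += n * sp.agent_count("A")
                total_b += n * sp.agent_count("B")
            assert total_a == 100 and total_b == 80

    def test_census_nondecreasing_in_simulation_length(self):
        """With a common seed the event sequence of the shorter run is a
        prefix of the longer one, so the sampled census can only grow."""
        toy = make_toy("dimerisation")
        net = generate_network(toy.model.rules, toy.seed_species(), toy.model.signatures)
        init = toy.init_mixture()
        short = ssa_run(net, init, t_end=2.0, record_dt=1.0, seed=9, snapshot_period=5)
        long = ssa_run(net, init, t_end=30.0, record_dt=1.0, seed=9, snapshot_period=5)
        assert species_census(short.snapshots) <= species_census(long.snapshots)


class TestSpeciesContaining:
    def test_toy_mixture_query(self, ab_signatures):
        toy_net = generate_network(
            [],
            [_sp("A(x)", ab_signatures), _sp("A(x!1),B(y!1)", ab_signatures)],
            ab_signatures,
        )
        from sitesim.simulate import Snapshot

        snaps = [Snapshot(0, 0.0, {"A(x)": 2, "A(x!1),B(y!1)": 1})]
        out = species_containing(snaps, "B", toy_net)
        assert out == {"A(x!1),B(y!1)": 1}
        with pytest.raises(ValueError, match="unknown agent"):
            species_containing(snaps, "Zz", toy_net)

    def test_ladder_calcium_census(self, pp2b_scheme):
        """On the four-site ladder, the sampled bound forms carry 2 or 4
        ligands (6 + 1 variants) next to free ligand (closure oracle)."""
        sigs = SignatureSet(scheme_signatures(pp2b_scheme))
        rules = expand_multisite_binding(pp2b_scheme)
        seeds = [_sp("PP2B(ca1,ca2,ca3,ca4)", sigs), _sp("Ca(b)", sigs)]
        net = generate_network(rules, seeds, sigs)
        from sitesim.simulate import Snapshot

        # exhaustive "snapshot": every reachable species present once
        snaps = [Snapshot(0, 0.0, {s.canonical_id: 1 for s in net.species})]
        out = species_containing(snaps, "Ca", net)
        per_count = {}
        for cid, k in out.items():
            per_count.setdefault(k, 0)
            per_count[k] += 1
        # 6 half-bound + 1 fully-bound targets, plus free Ca itself
        assert per_count == {1: 1, 2: 6, 4: 1}
        df = census_frame(snaps, net)
        assert len(df) == net.n_species


class TestSummaries:
    def test_identical_replicates_zero_sd(self):
        t = np.arange(5.0)
        tr = Trajectory(t, {"x": np.ones(5)})
        out = summarize_replicates([tr, Trajectory(t, {"x": np.ones(5)})])
        assert np.all(out.sd["x"] == 0)
        assert out.n_replicates == 2

    def test_two_point_mean_and_sd(self):
        t = np.array([0.0])
        out = summarize_replicates(
            [Trajectory(t, {"x": np.array([0.0])}), Trajectory(t, {"x": np.array([2.0])})]
        )
        assert out.values["x"][0] == pytest.approx(1.0)
        assert out.sd["x"][0] == pytest.approx(math.sqrt(2.0))

    def test_mismatched_grids_rejected(self):
        a = Trajectory(np.arange(3.0), {"x": np.zeros(3)})
        b = Trajectory(np.arange(4.0), {"x": np.zeros(4)})
        with pytest.raises(ValueError, match="grid"):
            summarize_replicates([a, b])

    def test_birth_death_stationary_dispersion(self):
        """Poisson stationary law: across-replicate variance tracks the mean."""
        toy = make_toy("birth_death", b=10.0, d=0.1)
        net = generate_network(toy.model.rules, toy.seed_species(), toy.model.signatures)
        init = toy.init_mixture()
        finals = [
            ssa_run(net, init, t_end=80.0, record_dt=80.0, seed=100 + i,
                    observables=toy.model.observables).trajectory.values["X"][-1]
            for i in range(60)
        ]
        mean, var = np.mean(finals), np.var(finals, ddof=1)
        # variance/mean ratio near 1 (loose band; 60 replicates)
        assert 0.5 < var / mean < 2.0


class TestCompare:
    def test_self_comparison_zero_divergence(self):
        t = np.linspace(0, 10, 11)
        tr = Trajectory(t, {"x": np.sin(t)})
        df = compare_trajectories(tr, tr, {"x": "x"})
        row = df.iloc[0]
        assert row["max_abs_delta"] == 0.0
        assert row["area_between"] == 0.0

    def test_constant_offset_area(self):
        t = np.linspace(0, 1, 101)
        a = Trajectory(t, {"x": np.zeros_like(t)})
        b = Trajectory(t, {"x": np.ones_like(t)})
        row = compare_trajectories(a, b, {"x": "x"}).iloc[0]
        assert row["area_between"] == pytest.approx(1.0, rel=1e-6)

    def test_unpairable_observable_reported(self):
        t = np.linspace(0, 1, 5)
        a = Trajectory(t, {"x": np.zeros(5)})
        b = Trajectory(t, {"y": np.zeros(5)})
        df = compare_trajectories(a, b, {"x": "z"})
        assert df.iloc[0]["status"] == "unpaired"
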
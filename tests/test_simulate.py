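"""Unit conversion, SSA and ODE backends, and the event engine."""

import itertools
import math

import numpy as np
import pytest

from sitesim.core import AgentSignature, Mixture, SignatureSet, Species, UnitContext
from sitesim.engine import ReactionNetwork, generate_network
from sitesim.fixtures import make_toy
from sitesim.kappa_io import parse_pattern, parse_rule_line, pattern_to_graph
from sitesim.model import AddCopies, Event, EventSchedule, SetRate
from sitesim.simulate import (
    SimulationState,
    apply_event,
    concentration_to_copies,
    convert_units,
    ode_run,
    run_replicates,
    ssa_run,
)


def _toy_net(toy):
    net = generate_network(toy.model.rules, toy.seed_species(), toy.model.signatures)
    init = toy.init_mixture()
    for sp in net.species:
        if init.count(sp) == 0:
            init.add(sp, 0)
    return net, init, toy.model.observables


class TestUnits:
    CTX = UnitContext(volume=1e-15)

    def test_first_order_unchanged(self):
        assert convert_units(0.5, 1, self.CTX) == 0.5

    def test_micromolar_copies(self):
        assert concentration_to_copies(1e-6, self.CTX) == 602

    def test_bimolecular_conversion(self):
        k = convert_units(1e6, 2, self.CTX)
        assert k == pytest.approx(1e6 / (self.CTX.avogadro * 1e-15))
        assert k == pytest.approx(1.661e-3, rel=1e-3)

    def test_zero_order(self):
        assert convert_units(1e-6, 0, self.CTX) == pytest.approx(
            1e-6 * self.CTX.avogadro * 1e-15
        )

    def test_higher_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            convert_units(1.0, 3, self.CTX)


class TestSSA:
    def test_no_reactions_constant_trajectory(self, ab_signatures, make_species):
        a = make_species("A(x)", ab_signatures)
        net = ReactionNetwork([a], [])
        init = Mixture()
        init.add(a, 7)
        res = ssa_run(net, init, t_end=5.0, record_dt=1.0, seed=0)
        assert np.all(res.trajectory.values["A(x)"] == 7)
        assert res.n_events == 0

    def test_decay_replicate_mean_matches_closed_form(self):
        """SSA mean of first-order decay vs A0 exp(-kt) within 3 SE
        (per-replicate variance of a pure-death process is binomial)."""
        toy = make_toy("decay", k=0.1, a0=1000)
        net, init, obs = _toy_net(toy)
        finals = [
            r.trajectory.values["A"][-1]
            for r in run_replicates(
                net, init, 100, 1000, t_end=10.0, record_dt=10.0, observables=obs
            )
        ]
        expected = toy.expectations["mean_A"][0](10.0)
        p = expected / 1000
        se = math.sqrt(1000 * p * (1 - p) / len(finals))
        assert abs(np.mean(finals) - expected) < 3 * se

    def test_single_replicate_values_are_integers(self):
        toy = make_toy("decay")
        net, init, obs = _toy_net(toy)
        res = ssa_run(net, init, t_end=5.0, record_dt=0.5, seed=3, observables=obs)
        vals = res.trajectory.values["A"]
        assert np.all(vals == np.round(vals))

    def test_same_seed_bit_identical_different_seeds_differ(self):
        toy = make_toy("birth_death")
        net, init, obs = _toy_net(toy)
        r1 = ssa_run(net, init, t_end=30.0, record_dt=1.0, seed=11, observables=obs)
        r2 = ssa_run(net, init, t_end=30.0, record_dt=1.0, seed=11, observables=obs)
        r3 = ssa_run(net, init, t_end=30.0, record_dt=1.0, seed=12, observables=obs)
        assert np.array_equal(r1.trajectory.values["X"], r2.trajectory.values["X"])
        assert not np.array_equal(r1.trajectory.values["X"], r3.trajectory.values["X"])

    def test_identical_reactant_combinations(self):
        """Propensity of A+A uses n(n-1)/2 combinations; oracle: exhaustive
        micro-state (unordered pair) count for n <= 5."""
        from sitesim.simulate import _combinations

        for n in range(6):
            assert _combinations(n, 2) == len(
                list(itertools.combinations(range(n), 2))
            )
            assert _combinations(n, 3) == len(
                list(itertools.combinations(range(n), 3))
            )

    def test_invalid_arguments(self):
        toy = make_toy("decay")
        net, init, obs = _toy_net(toy)
        with pytest.raises(ValueError):
            ssa_run(net, init, t_end=-1.0, record_dt=0.5, seed=0)
        with pytest.raises(ValueError):
            ssa_run(net, init, t_end=1.0, record_dt=0.0, seed=0)


class TestODE:
    def test_decay_closed_form(self):
        toy = make_toy("decay", k=0.1, a0=1000)
        net, init, obs = _toy_net(toy)
        tr = ode_run(net, init, t_end=10.0, record_dt=1.0, observables=obs)
        for t, v in zip(tr.times, tr.values["A"]):
            assert v == pytest.approx(1000 * math.exp(-0.1 * t), rel=1e-4)

    def test_dimerisation_equilibrium_quadratic(self):
        toy = make_toy("dimerisation")
        net, init, obs = _toy_net(toy)
        tr = ode_run(net, init, t_end=500.0, record_dt=50.0)
        ab_eq = toy.expectations["equilibrium_AB"][0]
        dimer = [s.canonical_id for s in net.species if s.agent_count("A") and s.agent_count("B")][0]
        assert tr.values[dimer][-1] == pytest.approx(ab_eq, rel=1e-3)

    def test_conserved_totals(self):
        """Total copies of each conserved agent stay constant."""
        toy = make_toy("dimerisation")
        net, init, obs = _toy_net(toy)
        tr = ode_run(net, init, t_end=50.0, record_dt=5.0)
        dimer = [s for s in net.species if s.agent_count("A") and s.agent_count("B")][0]
        total_a = tr.values["A(x)"] + tr.values[dimer.canonical_id]
        total_b = tr.values["B(y)"] + tr.values[dimer.canonical_id]
        assert np.allclose(total_a, 100, atol=1e-6)
        assert np.allclose(total_b, 80, atol=1e-6)

    def test_ssa_mean_converges_to_ode_for_linear_network(self):
        """Replicate mean of a linear (birth-death) network approaches the
        ODE solution (3-SE band)."""
        toy = make_toy("birth_death", b=5.0, d=0.2)
        net, init, obs = _toy_net(toy)
        t_end, dt = 20.0, 5.0
        ode = ode_run(net, init, t_end=t_end, record_dt=dt, observables=obs)
        reps = run_replicates(net, init, 200, 7000, t_end=t_end, record_dt=dt, observables=obs)
        stack = np.vstack([r.trajectory.values["X"] for r in reps])
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
        for k in range(1, len(ode.times)):
            assert abs(mean[k] - ode.values["X"][k]) < 3 * se[k] + 1e-9


class TestEvents:
    def _bd(self):
        toy = make_toy("birth_death", b=10.0, d=0.1)
        return _toy_net(toy)

    def test_set_rate_zero_silences_all_reactions(self):
        net, init, obs = self._bd()
        ev = EventSchedule([Event(0.0, SetRate("k_birth", 0.0)), Event(0.0, SetRate("k_death", 0.0))])
        res = ssa_run(net, init, events=ev, t_end=50.0, record_dt=5.0, seed=2, observables=obs)
        assert res.n_events == 0  # no propensity left anywhere

    def test_add_copies_applied_exactly_once_any_grid(self):
        net, init, obs = self._bd()
        ev = EventSchedule(
            [
                Event(1.0, SetRate("k_birth", 0.0)),
                Event(1.0, SetRate("k_death", 0.0)),
                Event(7.0, AddCopies("X()", 500)),
            ]
        )
        for dt in (0.3, 1.0, 4.0):
            res = ssa_run(net, init, events=ev, t_end=20.0, record_dt=dt, seed=4, observables=obs)
            x = res.trajectory.values["X"]
            t = res.trajectory.times
            frozen_before = x[(t >= 1.0) & (t < 7.0)]
            # dynamics frozen from t=1, so the jump at t=7 isolates the event
            assert np.all(frozen_before == frozen_before[0])
            assert x[-1] == frozen_before[0] + 500

    def test_event_updates_every_reaction_sharing_rate_id(self, ab_signatures, make_species):
        rules = [
            parse_rule_line("'b1' A(x),B(y) -> A(x!1),B(y!1) @ 0.5 {shared}"),
        ]
        net = generate_network(
            rules,
            [make_species("A(x)", ab_signatures), make_species("B(y)", ab_signatures)],
            ab_signatures,
        )
        state = SimulationState(
            net,
            np.zeros(net.n_species, dtype=np.int64),
            np.array([r.rate for r in net.reactions]),
        )
        apply_event(SetRate("shared", 0.0), state)
        assert np.all(state.rates == 0.0)
        with pytest.raises(KeyError):
            apply_event(SetRate("nope", 1.0), state)
        with pytest.raises(KeyError):
            apply_event(AddCopies("nope", 1), state)

    def test_ode_event_discontinuity(self):
        net, init, obs = self._bd()
        ev = EventSchedule([Event(10.0, AddCopies("X()", 1000))])
        tr = ode_run(net, init, events=ev, t_end=20.0, record_dt=1.0, observables=obs)
        assert tr.values["X"][11] - tr.values["X"][9] > 900
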
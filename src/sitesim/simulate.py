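"""Stochastic (Gillespie direct method) and deterministic (mass-action ODE)
simulation of a reaction network, with timed perturbation events.

Both backends work in copy-number units on the same :class:`ReactionNetwork`.
The propensity of reaction *j* is ``a_j = k_j * (number of distinct reactant
combinations)``: ``n`` for one reactant copy, ``n(n-1)/2`` for a doubly
consumed species, ``n(n-1)(n-2)/6`` for a triply consumed one.  The ODE
backend uses the large-copy-number limit of the same combination counts
(``n^r / r!``), so SSA replicate means converge to the ODE solution for
linear networks.

Timed events interrupt the jump clock: simulated time is advanced to the
trigger, the action applied (copy-number addition/assignment or rate-constant
update), propensities refreshed, and — the exponential waiting time being
memoryless — a fresh jump is drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .core import Mixture, Species, UnitContext
from .engine import ReactionNetwork, find_embeddings
from .model import (
    AddCopies,
    Event,
    EventSchedule,
    PatternObservable,
    SetCopies,
    SetRate,
)

__all__ = [
    "convert_units",
    "concentration_to_copies",
    "Trajectory",
    "Snapshot",
    "SimulationState",
    "apply_event",
    "ssa_run",
    "ode_run",
    "run_replicates",
]


def convert_units(k_det: float, reaction_order: int, ctx: UnitContext) -> float:
    """Deterministic (molar, per-second) to stochastic (per-second, per
    reactant combination) rate constant.

    Zero order: ``k * N_A * V``; first order: unchanged; second order:
    ``k / (N_A * V)``.  Higher orders are rejected.
    """
    nav = ctx.avogadro * ctx.volume
    if reaction_order == 0:
        return k_det * nav
    if reaction_order == 1:
        return k_det
    if reaction_order == 2:
        return k_det / nav
    raise ValueError(f"reaction order {reaction_order} unsupported (max 2)")


def concentration_to_copies(c: float, ctx: UnitContext) -> int:
    """Molar concentration to an integer copy number in the context volume."""
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    return round(c * ctx.avogadro * ctx.volume)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Observable time series on a fixed grid.

    ``values[name]`` has shape ``(n_times,)``.  ``sd`` is populated for
    replicate aggregates (then ``n_replicates > 1``).
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    sd: Optional[dict[str, np.ndarray]] = None
    n_replicates: int = 1
    seed: Optional[int] = None

    def observable_names(self) -> list[str]:
        return list(self.values)

    def to_frame(self):
        """Tidy DataFrame: time, observable, value [, sd, n]."""
        import pandas as pd

        rows = []
        for name, series in self.values.items():
            df = pd.DataFrame({"time": self.times, "observable": name, "value": series})
            if self.sd is not None:
                df["sd"] = self.sd[name]
                df["n"] = self.n_replicates
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class Snapshot:
    """Event-indexed dump of the full mixture state."""

    event_index: int
    time: float
    counts: dict[str, int]  # canonical_id -> copies (zero entries omitted)


@dataclass
class SimulationState:
    """Live state mutated by perturbation events."""

    network: ReactionNetwork
    counts: np.ndarray  # per species, copy numbers
    rates: np.ndarray  # effective per-reaction constants

    def rate_index(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j, r in enumerate(self.network.reactions):
            if r.rate_id is not None:
                out.setdefault(r.rate_id, []).append(j)
        return out


def apply_event(action, state: SimulationState) -> SimulationState:
    """Apply one perturbation action in place and return the state.

    ``SetRate`` updates every reaction sharing the rate id (each rescaled by
    its own embedding multiplicity); ``AddCopies``/``SetCopies`` change one
    species count.  Nothing else changes.
    """
    net = state.network
    if isinstance(action, SetRate):
        idx = [
            j for j, r in enumerate(net.reactions) if r.rate_id == action.rate_id
        ]
        if not idx:
            raise KeyError(f"unknown rate_id {action.rate_id!r}")
        for j in idx:
            state.rates[j] = action.value * net.reactions[j].multiplicity
    elif isinstance(action, (AddCopies, SetCopies)):
        if action.species not in net.index:
            raise KeyError(f"unknown species {action.species!r}")
        i = net.index[action.species]
        if isinstance(action, AddCopies):
            state.counts[i] += action.n
        else:
            state.counts[i] = action.n
    else:
        raise TypeError(f"unknown event action {action!r}")
    return state


# ---------------------------------------------------------------------------
# Observable resolution
# ---------------------------------------------------------------------------


ObservableSpec = Union[PatternObservable, tuple[str, np.ndarray]]


def resolve_observables(
    network: ReactionNetwork,
    observables: Optional[Sequence[ObservableSpec]],
) -> tuple[list[str], np.ndarray]:
    """Weight matrix W (n_obs x n_species) such that obs = W @ counts.

    Pattern observables weight each species by its embedding count
    (agent-instances mode) or by 1 if it matches at all (species-copies mode).
    Precomputed ``(name, weights)`` pairs pass through (used for name-matched
    aggregation over imported networks).  ``None`` tracks every species.
    """
    n = network.n_species
    if observables is None:
        names = [s.canonical_id for s in network.species]
        return names, np.eye(n)
    names, rows = [], []
    for spec in observables:
        if isinstance(spec, PatternObservable):
            w = np.zeros(n)
            for i, sp in enumerate(network.species):
                if sp.graph is None:
                    continue
                m = len(find_embeddings(spec.pattern, sp))
                if m:
                    w[i] = m if spec.mode == "agent-instances" else 1
            names.append(spec.name)
            rows.append(w)
        else:
            name, w = spec
            names.append(name)
            rows.append(np.asarray(w, dtype=float))
    return names, np.vstack(rows) if rows else np.zeros((0, n))


def _mixture_to_counts(network: ReactionNetwork, init: Mixture) -> np.ndarray:
    counts = np.zeros(network.n_species, dtype=np.int64)
    for cid, n in init.counts().items():
        if n == 0:
            continue
        if cid not in network.index:
            raise ValueError(f"initial species {cid!r} not in network")
        counts[network.index[cid]] = n
    return counts


def _reaction_arrays(network: ReactionNetwork):
    """Per reaction: list of (species index, consumed stoich); net stoich
    matrix; dependency structure for incremental propensity updates."""
    reac = []
    n = network.n_species
    stoich = np.zeros((n, network.n_reactions), dtype=np.int64)
    for j, r in enumerate(network.reactions):
        cons: dict[int, int] = {}
        for s in r.reactants:
            cons[network.index[s.canonical_id]] = (
                cons.get(network.index[s.canonical_id], 0) + 1
            )
        for i, c in cons.items():
            stoich[i, j] -= c
        for s in r.products:
            stoich[network.index[s.canonical_id], j] += 1
        reac.append(tuple(cons.items()))
    depends_on: list[list[int]] = [[] for _ in range(n)]
    for j, cons in enumerate(reac):
        for i, _ in cons:
            depends_on[i].append(j)
    changed: list[np.ndarray] = [
        np.nonzero(stoich[:, j])[0] for j in range(network.n_reactions)
    ]
    affected: list[list[int]] = []
    for j in range(network.n_reactions):
        deps: set[int] = set()
        for i in changed[j]:
            deps.update(depends_on[i])
        affected.append(sorted(deps))
    return reac, stoich, affected


def _combinations(n: int, c: int) -> float:
    if c == 1:
        return float(n)
    if c == 2:
        return n * (n - 1) / 2.0
    if c == 3:
        return n * (n - 1) * (n - 2) / 6.0
    return float(math.comb(int(n), c))


def _propensity_of(j: int, reac, rates, counts) -> float:
    a = rates[j]
    for i, c in reac[j]:
        a *= _combinations(counts[i], c)
        if a == 0.0:
            break
    return a


def _propensities(reac, rates: np.ndarray, counts: np.ndarray) -> np.ndarray:
    a = rates.copy()
    for j, cons in enumerate(reac):
        for i, c in cons:
            a[j] *= _combinations(counts[i], c)
    return a


# ---------------------------------------------------------------------------
# Stochastic simulation (direct method)
# ---------------------------------------------------------------------------


@dataclass
class SSAResult:
    trajectory: Trajectory
    snapshots: list[Snapshot] = field(default_factory=list)
    event_log: list[tuple[float, str]] = field(default_factory=list)
    n_events: int = 0
    final_counts: Optional[dict[str, int]] = None


def ssa_run(
    network: ReactionNetwork,
    init: Mixture,
    events: Optional[EventSchedule] = None,
    t_end: float = 1.0,
    record_dt: float = 0.1,
    seed: int = 0,
    observables: Optional[Sequence[ObservableSpec]] = None,
    snapshot_period: Optional[int] = None,
    max_steps: int = 50_000_000,
) -> SSAResult:
    """Exact stochastic simulation with Gillespie's direct method.

    Two uniform variates per step (waiting time, channel); observables
    recorded on a fixed ``record_dt`` grid (last value carried forward between
    jumps); scheduled events applied exactly once at their trigger times; a
    snapshot of the full mixture taken every ``snapshot_period``-th reaction
    event plus at the final state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if record_dt <= 0:
        raise ValueError("record_dt must be positive")
    rng = np.random.default_rng(seed)
    counts = _mixture_to_counts(network, init)
    if (counts < 0).any():
        raise ValueError("negative initial copy numbers")
    rates = np.array([r.rate for r in network.reactions], dtype=float)
    state = SimulationState(network, counts, rates)
    reac, stoich, affected = _reaction_arrays(network)
    names, W = resolve_observables(network, observables)

    grid = np.arange(0.0, t_end + record_dt / 2, record_dt)
    recorded = np.zeros((len(names), len(grid)))
    gi = 0  # next grid index to fill

    pending = list(events) if events is not None else []
    pending = [e for e in pending if e.time <= t_end]
    ei = 0
    event_log: list[tuple[float, str]] = []
    snapshots: list[Snapshot] = []

    ids = [s.canonical_id for s in network.species]

    def snap(n_events: int, t: float) -> None:
        snapshots.append(
            Snapshot(
                n_events,
                t,
                {ids[i]: int(c) for i, c in enumerate(state.counts) if c},
            )
        )

    t = 0.0
    n_events = 0
    a = _propensities(reac, state.rates, state.counts)
    for _ in range(max_steps):
        a0 = float(a.sum())
        assert a0 >= 0.0, "negative total propensity"
        if a0 == 0.0:
            t_next = math.inf
        else:
            u1 = rng.random()
            t_next = t - math.log(u1) / a0

        # any events scheduled before the next jump fire first
        if ei < len(pending) and pending[ei].time <= min(t_next, t_end):
            ev = pending[ei]
            ei += 1
            while gi < len(grid) and grid[gi] < ev.time:
                recorded[:, gi] = W @ state.counts
                gi += 1
            t = ev.time
            apply_event(ev.action, state)
            event_log.append((ev.time, repr(ev.action)))
            a = _propensities(reac, state.rates, state.counts)
            continue

        if t_next > t_end:
            break
        # record grid points passed before the jump
        while gi < len(grid) and grid[gi] < t_next:
            recorded[:, gi] = W @ state.counts
            gi += 1
        t = t_next
        u2 = rng.random()
        j = int(np.searchsorted(np.cumsum(a), u2 * a0, side="right"))
        j = min(j, len(a) - 1)
        state.counts += stoich[:, j]
        n_events += 1
        if snapshot_period and n_events % snapshot_period == 0:
            snap(n_events, t)
        for r in affected[j]:  # only reactions touching changed species
            a[r] = _propensity_of(r, reac, state.rates, state.counts)
    else:  # pragma: no cover
        raise RuntimeError(f"SSA exceeded max_steps={max_steps}")

    while gi < len(grid):
        recorded[:, gi] = W @ state.counts
        gi += 1
    if snapshot_period:
        snap(n_events, min(t, t_end))

    traj = Trajectory(
        times=grid,
        values={name: recorded[k] for k, name in enumerate(names)},
        seed=seed,
    )
    return SSAResult(
        trajectory=traj,
        snapshots=snapshots,
        event_log=event_log,
        n_events=n_events,
        final_counts={ids[i]: int(c) for i, c in enumerate(state.counts) if c},
    )


def run_replicates(
    network: ReactionNetwork,
    init: Mixture,
    n_replicates: int,
    base_seed: int,
    **kwargs,
) -> list[SSAResult]:
    """Replicate ``i`` uses seed ``base_seed + i``."""
    return [
        ssa_run(network, init, seed=base_seed + i, **kwargs)
        for i in range(n_replicates)
    ]


# ---------------------------------------------------------------------------
# Deterministic simulation
# ---------------------------------------------------------------------------


def ode_run(
    network: ReactionNetwork,
    init: Mixture,
    events: Optional[EventSchedule] = None,
    t_end: float = 1.0,
    record_dt: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    observables: Optional[Sequence[ObservableSpec]] = None,
) -> Trajectory:
    """Mass-action rate equations in copy-number units, integrated with a
    stiff-capable adaptive method (LSODA); events enter as discontinuities in
    the state or the rate vector at their trigger times."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    counts = _mixture_to_counts(network, init).astype(float)
    rates = np.array([r.rate for r in network.reactions], dtype=float)
    state = SimulationState(network, counts, rates)
    reac, stoich, _ = _reaction_arrays(network)
    names, W = resolve_observables(network, observables)
    stoich_f = stoich.astype(float)

    # vectorized mass-action flux: up to 3 reactant slots per reaction, a
    # trailing dummy species pinned at 1.0 fills unused slots
    n_sp = network.n_species
    max_order = max((sum(c for _, c in cons) for cons in reac), default=0)
    slots = max(max_order, 1)
    idx = np.full((network.n_reactions, slots), n_sp, dtype=np.int64)
    divisor = np.ones(network.n_reactions)
    for j, cons in enumerate(reac):
        k = 0
        for i, c in cons:
            for _ in range(c):
                idx[j, k] = i
                k += 1
            divisor[j] *= math.factorial(c)

    def rhs(t, y):
        yy = np.concatenate([np.maximum(y, 0.0), [1.0]])
        flux = state.rates / divisor * yy[idx].prod(axis=1)
        return stoich_f @ flux

    grid = np.arange(0.0, t_end + record_dt / 2, record_dt)
    out = np.zeros((len(grid), network.n_species))
    out[0] = state.counts

    boundaries = [0.0]
    if events is not None:
        boundaries += [e.time for e in events if 0.0 < e.time <= t_end]
    boundaries.append(t_end)
    ev_iter = iter(events) if events is not None else iter(())
    pending = [e for e in (events or []) if 0.0 < e.time <= t_end]
    del ev_iter

    y = state.counts.astype(float)
    filled = 1 if grid[0] == 0.0 else 0
    seg_start = 0.0
    pi = 0
    seg_ends = sorted({*[e.time for e in pending], t_end})
    for seg_end in seg_ends:
        t_eval = grid[(grid > seg_start) & (grid <= seg_end)]
        if seg_end > seg_start:
            sol = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method="LSODA",
                t_eval=t_eval if len(t_eval) else None,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed in [{seg_start}, {seg_end}]: {sol.message}"
                )
            for k, tk in enumerate(t_eval):
                out[filled] = sol.y[:, k]
                filled += 1
            y = sol.y[:, -1] if sol.y.shape[1] else y
        # apply all events at this boundary (except when boundary is t_end only)
        while pi < len(pending) and pending[pi].time <= seg_end:
            state.counts = y
            apply_event(pending[pi].action, state)
            y = state.counts.astype(float)
            pi += 1
        seg_start = seg_end

    values = (W @ out.T) if len(names) else np.zeros((0, len(grid)))
    return Trajectory(times=grid, values={n: values[k] for k, n in enumerate(names)})
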
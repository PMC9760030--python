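"""Observables, snapshot censuses, replicate summaries and trajectory
comparison.

A strength of the site-graph representation is that the molecular species
emerging during a stochastic simulation can be dissected after the fact:
snapshots of the full mixture are censused for the distinct complexes sampled,
and queried for every species containing a given agent (e.g. all
calcium-containing complexes, with the number of ions each carries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Mixture, Species
from .engine import ReactionNetwork, find_embeddings
from .model import PatternObservable
from .simulate import Snapshot, SSAResult, Trajectory

__all__ = [
    "evaluate_observable",
    "record_snapshots",
    "species_census",
    "species_containing",
    "summarize_replicates",
    "compare_trajectories",
    "census_frame",
    "plot_overlay",
]


def evaluate_observable(obs: PatternObservable, mixture: Mixture) -> int:
    """Tally of an observable over a mixture.

    Agent-instances mode sums embedding counts weighted by copy numbers (the
    per-molecule tally, e.g. total cAMP including copies bound in complexes);
    species-copies mode counts copies of matching species.
    """
    total = 0
    for sp in mixture.species():
        n = mixture.count(sp)
        if not n:
            continue
        m = len(find_embeddings(obs.pattern, sp))
        if m:
            total += n * (m if obs.mode == "agent-instances" else 1)
    return total


def record_snapshots(result: SSAResult) -> list[Snapshot]:
    """Snapshots captured by an SSA run (one per period-th reaction event plus
    the final state; the period is set when launching the run)."""
    return result.snapshots


def species_census(snapshots: Sequence[Snapshot]) -> set[str]:
    """Distinct species sampled across snapshots (union; nondecreasing in
    simulation length)."""
    out: set[str] = set()
    for snap in snapshots:
        out.update(cid for cid, n in snap.counts.items() if n)
    return out


def species_containing(
    snapshots: Sequence[Snapshot],
    agent_name: str,
    network: ReactionNetwork,
) -> dict[str, int]:
    """Sampled species containing >= 1 agent of the given name, with the count
    of that agent per species (e.g. fully active PP2B carries 4 Ca)."""
    known_agents = {a for s in network.species if s.graph for a in s.graph.agents}
    if agent_name not in known_agents:
        raise ValueError(f"unknown agent {agent_name!r}")
    out: dict[str, int] = {}
    for cid in sorted(species_census(snapshots)):
        sp = network.species_by_id(cid)
        if sp.graph is None:
            continue
        k = sp.agent_count(agent_name)
        if k:
            out[cid] = k
    return out


def census_frame(
    snapshots: Sequence[Snapshot], network: ReactionNetwork
) -> pd.DataFrame:
    """Tabular census: species id, agent composition, max copies observed."""
    rows = []
    peak: dict[str, int] = {}
    for snap in snapshots:
        for cid, n in snap.counts.items():
            peak[cid] = max(peak.get(cid, 0), n)
    for cid in sorted(species_census(snapshots)):
        sp = network.species_by_id(cid)
        comp = ""
        if sp.graph is not None:
            names: dict[str, int] = {}
            for a in sp.graph.agents:
                names[a] = names.get(a, 0) + 1
            comp = ".".join(f"{a}x{c}" for a, c in sorted(names.items()))
        rows.append({"species": cid, "composition": comp, "max_copies": peak[cid]})
    return pd.DataFrame(rows)


def summarize_replicates(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Pointwise mean and sample standard deviation over replicates sharing a
    common time grid."""
    if not trajectories:
        raise ValueError("no trajectories to summarize")
    t0 = trajectories[0].times
    for tr in trajectories[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
            raise ValueError("replicates must share a common time grid")
    names = trajectories[0].observable_names()
    values, sds = {}, {}
    n = len(trajectories)
    for name in names:
        stack = np.vstack([tr.values[name] for tr in trajectories])
        values[name] = stack.mean(axis=0)
        sds[name] = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(len(t0))
    return Trajectory(times=t0, values=values, sd=sds, n_replicates=n)


def compare_trajectories(
    traj_a: Trajectory,
    traj_b: Trajectory,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Divergence report between paired observables of two trajectories.

    For each pair (name in A -> name in B): the maximum absolute difference of
    means scaled by the pooled standard deviation where available, and the
    area between the curves, after resampling onto a common grid.  Observables
    named in the pairing but missing from either trajectory are reported as
    unpaired rather than silently dropped.
    """
    t_lo = max(traj_a.times[0], traj_b.times[0])
    t_hi = min(traj_a.times[-1], traj_b.times[-1])
    grid = np.linspace(t_lo, t_hi, 201)
    rows = []
    for name_a, name_b in pairing.items():
        if name_a not in traj_a.values or name_b not in traj_b.values:
            rows.append(
                {
                    "observable_a": name_a,
                    "observable_b": name_b,
                    "status": "unpaired",
                    "max_abs_delta": np.nan,
                    "max_scaled_delta": np.nan,
                    "area_between": np.nan,
                }
            )
            continue
        ya = np.interp(grid, traj_a.times, traj_a.values[name_a])
        yb = np.interp(grid, traj_b.times, traj_b.values[name_b])
        delta = np.abs(ya - yb)
        pooled = None
        if traj_a.sd is not None and name_a in traj_a.sd:
            sa = np.interp(grid, traj_a.times, traj_a.sd[name_a])
            pooled = sa
        if traj_b.sd is not None and name_b in traj_b.sd:
            sb = np.interp(grid, traj_b.times, traj_b.sd[name_b])
            pooled = sb if pooled is None else np.sqrt((pooled**2 + sb**2) / 2)
        if pooled is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                scaled = np.where(pooled > 0, delta / pooled, np.nan)
            max_scaled = np.nanmax(scaled) if np.isfinite(scaled).any() else np.nan
        else:
            max_scaled = np.nan
        rows.append(
            {
                "observable_a": name_a,
                "observable_b": name_b,
                "status": "paired",
                "max_abs_delta": float(delta.max()),
                "max_scaled_delta": float(max_scaled) if max_scaled == max_scaled else np.nan,
                "area_between": float(np.trapezoid(delta, grid)),
            }
        )
    return pd.DataFrame(rows)


def plot_overlay(
    trajectories: dict[str, Trajectory],
    observables: Optional[Sequence[str]] = None,
    path: Optional[str] = None,
):
    """Superimposed time courses (one panel per observable, one line per
    trajectory, mean ± sd shading for replicate aggregates)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if observables is None:
        observables = sorted(
            {n for tr in trajectories.values() for n in tr.observable_names()}
        )
    n = len(observables)
    ncol = min(3, max(n, 1))
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for k, name in enumerate(observables):
        ax = axes[k // ncol][k % ncol]
        for lab, tr in trajectories.items():
            if name not in tr.values:
                continue
            ax.plot(tr.times, tr.values[name], label=lab, lw=1)
            if tr.sd is not None and name in tr.sd:
                ax.fill_between(
                    tr.times,
                    tr.values[name] - tr.sd[name],
                    tr.values[name] + tr.sd[name],
                    alpha=0.25,
                )
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("time (s)")
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    if n:
        axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
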
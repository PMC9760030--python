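"""Condensation of explicit reaction lists into decontextualised rules.

The grouping criterion: reactions of the same type (forward, backward or
catalytic — operationally, the same multiset of transformed-site operations)
between the same reactants (same agent-name multisets), whose differences lie
only in agent states (internal or binding) that do not change across the
transition, and whose rate constants have the same value, collapse into a
single rule with that context removed.  Reactions that cannot be grouped are
emitted as fully contextual rules.

The output is validated by construction: re-expanding the emitted rules over
the species universe of the input regenerates exactly the input reaction
multiset (rates included).  A candidate decontextualised rule that would
over- or under-generate falls back to progressively more context, ending at
one fully contextual rule per reaction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    FREE,
    UNSPEC,
    AgentPattern,
    ComplexPattern,
    Reaction,
    Rule,
    SiteGraph,
    Species,
    SitePattern,
)
from .engine import expand_rules_over_species

__all__ = ["CondensationReport", "condense_reactions", "write_report_tsv"]

_UNMATCHED_PENALTY = 1000


@dataclass
class CondensationReport:
    """Per model component: reaction, rule and unique-rate-constant counts."""

    rows: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (component, n_reactions, n_rules, n_unique_rates)

    def totals(self) -> tuple[int, int, int]:
        return (
            sum(r[1] for r in self.rows),
            sum(r[2] for r in self.rows),
            sum(r[3] for r in self.rows),
        )

    def by_component(self) -> dict[str, tuple[int, int, int]]:
        return {r[0]: (r[1], r[2], r[3]) for r in self.rows}


def write_report_tsv(report: CondensationReport, path) -> None:
    lines = ["component\treactions\trules\tunique_rate_constants"]
    for comp, nr, nu, nk in report.rows:
        lines.append(f"{comp}\t{nr}\t{nu}\t{nk}")
    nr, nu, nk = report.totals()
    lines.append(f"total\t{nr}\t{nu}\t{nk}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reaction transformation analysis
# ---------------------------------------------------------------------------


def _union(graphs: Sequence[SiteGraph]) -> tuple[SiteGraph, list[int]]:
    agents, states, bonds, offsets = [], [], {}, []
    off = 0
    for g in graphs:
        offsets.append(off)
        agents.extend(g.agents)
        states.extend(g.states)
        for (i, s), (j, t) in g.bonds.items():
            bonds[(i + off, s)] = (j + off, t)
        off += len(g.agents)
    return SiteGraph(agents, states, bonds), offsets


def _pair_cost(R: SiteGraph, P: SiteGraph, ri: int, pi: int, f: dict[int, int]) -> int:
    cost = 0
    for site, st in R.states[ri].items():
        if P.states[pi].get(site) != st:
            cost += 1
        rb = R.bonds.get((ri, site))
        pb = P.bonds.get((pi, site))
        if rb is None and pb is None:
            continue
        if rb is None or pb is None:
            cost += 1
        else:
            mapped = f.get(rb[0])
            if mapped is None or (mapped, rb[1]) != pb:
                cost += 1
    return cost


def _best_alignment(R: SiteGraph, P: SiteGraph) -> dict[int, int]:
    """Injective, name-preserving correspondence R-agents -> P-agents with the
    fewest site differences; unmatched agents are created/deleted.  Exhaustive
    over per-name pairings (reaction complexes are small)."""
    by_name_r: dict[str, list[int]] = {}
    by_name_p: dict[str, list[int]] = {}
    for i, n in enumerate(R.agents):
        by_name_r.setdefault(n, []).append(i)
    for i, n in enumerate(P.agents):
        by_name_p.setdefault(n, []).append(i)

    per_name_options: list[list[list[tuple[int, int]]]] = []
    for name in sorted(set(by_name_r) | set(by_name_p)):
        rs = by_name_r.get(name, [])
        ps = by_name_p.get(name, [])
        k = min(len(rs), len(ps))
        options = []
        for r_sub in itertools.combinations(rs, k):
            for p_perm in itertools.permutations(ps, k):
                options.append(list(zip(r_sub, p_perm)))
        per_name_options.append(options)

    best: Optional[dict[int, int]] = None
    best_cost = None
    for combo in itertools.product(*per_name_options):
        f: dict[int, int] = {}
        for pairs in combo:
            f.update(dict(pairs))
        cost = _UNMATCHED_PENALTY * (
            (len(R.agents) - len(f)) + (len(P.agents) - len(f))
        )
        for ri, pi in f.items():
            cost += _pair_cost(R, P, ri, pi, f)
        if best_cost is None or cost < best_cost:
            best, best_cost = f, cost
    assert best is not None
    return best


@dataclass
class _Transform:
    """Ops of one reaction, relative to the combined reactant graph ``R``."""

    R: SiteGraph
    P: SiteGraph
    f: dict[int, int]  # alignment R index -> P index
    state_ops: list[tuple[int, str, Optional[str], Optional[str]]]  # (ri, site, from, to)
    unbind_ops: list[frozenset]  # {(ri, site), (rj, site)}
    bind_ops: list[frozenset]  # endpoints: ("kept", ri, site) | ("new", pi, site)
    deleted: list[int]  # R indices
    created: list[int]  # P indices

    def signature(self) -> tuple:
        sig = []
        for ri, site, frm, to in self.state_ops:
            sig.append(("state", self.R.agents[ri], site, frm, to))
        for ends in self.unbind_ops:
            sig.append(
                ("unbind", tuple(sorted((self.R.agents[i], s) for i, s in ends)))
            )
        for ends in self.bind_ops:
            lab = []
            for kind, i, s in ends:
                nm = self.R.agents[i] if kind == "kept" else self.P.agents[i]
                lab.append((nm, s))
            sig.append(("bind", tuple(sorted(lab))))
        for ri in self.deleted:
            sig.append(("delete", self.R.agents[ri]))
        for pi in self.created:
            spec = tuple(sorted(self.P.states[pi].items()))
            sig.append(("create", self.P.agents[pi], spec))
        return tuple(sorted(sig))


def _transform(reaction: Reaction, composition: Optional[dict[str, SiteGraph]]) -> _Transform:
    def graph_of(sp: Species) -> SiteGraph:
        if sp.graph is not None:
            return sp.graph
        if composition is not None and sp.canonical_id in composition:
            return composition[sp.canonical_id]
        raise KeyError(sp.canonical_id)

    R, _ = _union([graph_of(s) for s in reaction.reactants])
    P, _ = _union([graph_of(s) for s in reaction.products])
    f = _best_alignment(R, P)
    f_inv = {pi: ri for ri, pi in f.items()}

    state_ops, unbind_ops, bind_ops = [], [], []
    for ri, pi in f.items():
        for site, st in R.states[ri].items():
            new = P.states[pi].get(site)
            if new != st:
                state_ops.append((ri, site, st, new))
    seen_r = set()
    for (ri, s), (rj, t) in R.bonds.items():
        key = frozenset({(ri, s), (rj, t)})
        if key in seen_r:
            continue
        seen_r.add(key)
        pi, pj = f.get(ri), f.get(rj)
        if pi is None or pj is None:
            continue  # endpoint deleted: severed implicitly
        if P.bonds.get((pi, s)) != (pj, t):
            unbind_ops.append(key)
    seen_p = set()
    for (pi, s), (pj, t) in P.bonds.items():
        key = frozenset({(pi, s), (pj, t)})
        if key in seen_p:
            continue
        seen_p.add(key)
        ri, rj = f_inv.get(pi), f_inv.get(pj)
        if ri is not None and rj is not None and R.bonds.get((ri, s)) == (rj, t):
            continue  # preserved
        ends = []
        for (qi, qs) in key:
            back = f_inv.get(qi)
            if back is not None:
                ends.append(("kept", back, qs))
            else:
                ends.append(("new", qi, qs))
        bind_ops.append(frozenset(ends))

    deleted = sorted(set(range(len(R.agents))) - set(f))
    created = sorted(set(range(len(P.agents))) - set(f_inv))
    return _Transform(R, P, f, sorted(state_ops), unbind_ops, bind_ops, deleted, created)


# ---------------------------------------------------------------------------
# Rule construction
# ---------------------------------------------------------------------------


def _touched_agents(tr: _Transform) -> set[int]:
    touched = {ri for ri, *_ in tr.state_ops}
    for ends in tr.unbind_ops:
        touched |= {i for i, _ in ends}
    for ends in tr.bind_ops:
        touched |= {i for kind, i, _ in ends if kind == "kept"}
    touched |= set(tr.deleted)
    return touched


def _connect_paths(R: SiteGraph, touched: set[int]) -> tuple[set[int], set[frozenset]]:
    """Agents and bonds needed so that touched agents sharing a reactant
    complex stay connected in the pattern (shortest bond paths)."""
    keep = set(touched)
    keep_bonds: set[frozenset] = set()
    comps = R.connected_components()
    for comp in comps:
        inside = [i for i in comp if i in touched]
        if len(inside) < 2:
            continue
        root = inside[0]
        # BFS tree from root; add path to each other touched agent
        prev: dict[int, tuple[int, str, str]] = {}
        order = [root]
        seen = {root}
        qi = 0
        while qi < len(order):
            u = order[qi]
            qi += 1
            for s, v, t in R.neighbours(u):
                if v not in seen:
                    seen.add(v)
                    prev[v] = (u, s, t)
                    order.append(v)
        for target in inside[1:]:
            v = target
            while v != root and v in prev:
                u, s, t = prev[v]
                keep.add(u)
                keep.add(v)
                keep_bonds.add(frozenset({(u, s), (v, t)}))
                v = u
    return keep, keep_bonds


def _build_rule(
    name: str,
    tr: _Transform,
    rate: float,
    rate_id: Optional[str],
    full_context: bool,
) -> Rule:
    """Build a rule realizing ``tr`` with minimal (ops + connectivity) or full
    reactant context."""
    R, P = tr.R, tr.P
    if full_context:
        keep = set(range(len(R.agents)))
        extra_bonds = {
            frozenset({(i, s), b})
            for (i, s), b in R.bonds.items()
        }
    else:
        touched = _touched_agents(tr)
        keep, extra_bonds = _connect_paths(R, touched)

    unbind_sites = {end for ends in tr.unbind_ops for end in ends}
    bind_kept = {
        (i, s) for ends in tr.bind_ops for kind, i, s in ends if kind == "kept"
    }
    state_sites = {(ri, site): (frm, to) for ri, site, frm, to in tr.state_ops}

    ordered = sorted(i for i in keep if i not in tr.deleted) + sorted(
        i for i in keep if i in tr.deleted
    )
    pos = {ri: k for k, ri in enumerate(ordered)}
    # assign bond labels
    label_of: dict[frozenset, int] = {}

    def label(key: frozenset) -> int:
        if key not in label_of:
            label_of[key] = len(label_of) + 1
        return label_of[key]

    lhs_agents, rhs_agents = [], []
    for ri in ordered:
        lsites, rsites = [], []
        for site in sorted(R.states[ri]):
            mentioned = False
            lint = rint = None
            lbind = rbind = UNSPEC
            if (ri, site) in state_sites:
                frm, to = state_sites[(ri, site)]
                lint, rint = frm, to
                mentioned = True
            bond = R.bonds.get((ri, site))
            bond_key = frozenset({(ri, site), bond}) if bond else None
            if (ri, site) in unbind_sites:
                lbind, rbind = label(bond_key), FREE
                mentioned = True
            elif (ri, site) in bind_kept:
                new_ends = next(
                    ends
                    for ends in tr.bind_ops
                    if ("kept", ri, site) in ends
                )
                lbind, rbind = FREE, label(new_ends)
                mentioned = True
            elif bond_key is not None and bond_key in extra_bonds:
                lb = label(bond_key)
                lbind = rbind = lb
                mentioned = True
            elif full_context:
                lint = R.states[ri][site]
                if rint is None:
                    rint = P.states[tr.f[ri]].get(site) if ri in tr.f else lint
                lbind = rbind = FREE if bond is None else lbind
                if bond is not None and bond_key not in extra_bonds:
                    lb = label(bond_key)
                    lbind = rbind = lb
                elif bond is None:
                    lbind = rbind = FREE
                mentioned = True
            if mentioned:
                lsites.append(SitePattern(site, lint, lbind))
                if ri not in tr.deleted:
                    rsites.append(SitePattern(site, rint, rbind))
        lhs_agents.append(AgentPattern(R.agents[ri], tuple(lsites)))
        if ri not in tr.deleted:
            rhs_agents.append(AgentPattern(R.agents[ri], tuple(rsites)))

    # created agents appended to the rhs, fully specified
    for pi in tr.created:
        sites = []
        for site in sorted(P.states[pi]):
            bond = P.bonds.get((pi, site))
            if bond is None:
                binding = FREE
            else:
                ends = next(
                    ends for ends in tr.bind_ops if ("new", pi, site) in ends
                )
                binding = label(ends)
            sites.append(SitePattern(site, P.states[pi][site], binding))
        rhs_agents.append(AgentPattern(P.agents[pi], tuple(sites)))

    # reorder lhs so kept agents align with rhs positions (they already do:
    # kept agents first, deleted afterwards, created at the rhs tail)
    return Rule(name, ComplexPattern(tuple(lhs_agents)), ComplexPattern(tuple(rhs_agents)), rate, rate_id)


# ---------------------------------------------------------------------------
# Main entry
# ---------------------------------------------------------------------------


def _reaction_key(r: Reaction) -> tuple:
    return (
        tuple(sorted(s.canonical_id for s in r.reactants)),
        tuple(sorted(s.canonical_id for s in r.products)),
        r.rate,
    )


def _rates_equal(a: float, b: float, rel_tol: float) -> bool:
    if rel_tol == 0:
        return a == b
    scale = max(abs(a), abs(b))
    return abs(a - b) <= rel_tol * scale


def condense_reactions(
    reactions: Sequence[Reaction],
    composition: Optional[dict[str, SiteGraph]] = None,
    rate_tolerance: float = 0.0,
) -> tuple[list[Rule], CondensationReport]:
    """Condense a mass-action reaction list into (fewer) rules.

    Species must carry site-graphs, either directly or through ``composition``
    (canonical id / imported name -> graph); unresolvable species raise a
    ``ValueError`` naming them.  ``rate_tolerance`` relaxes the rate-equality
    requirement (relative), for floating-point inputs.

    Returns the rules plus a per-component report (components taken from each
    reaction's ``component`` label; unlabelled reactions count under
    ``"(unassigned)"``).
    """
    # resolve every species to a canonical graph-backed Species, so that the
    # round-trip comparison is in canonical ids even for imported name-only
    # species
    unresolved = []
    resolved: dict[str, Species] = {}

    def resolve(sp: Species) -> Species:
        if sp.canonical_id in resolved:
            return resolved[sp.canonical_id]
        graph = sp.graph
        if graph is None and composition is not None:
            graph = composition.get(sp.canonical_id)
        if graph is None:
            raise KeyError(sp.canonical_id)
        out = Species.from_graph(graph)
        resolved[sp.canonical_id] = out
        return out

    canon_reactions: list[Reaction] = []
    for r in reactions:
        try:
            canon_reactions.append(
                Reaction(
                    tuple(sorted((resolve(s) for s in r.reactants), key=lambda s: s.canonical_id)),
                    tuple(sorted((resolve(s) for s in r.products), key=lambda s: s.canonical_id)),
                    r.rate,
                    r.rate_id,
                    r.provenance,
                    r.component,
                    r.multiplicity,
                )
            )
        except KeyError as exc:
            unresolved.append(str(exc.args[0]))
    if unresolved:
        raise ValueError(
            "species without resolvable composition: "
            + ", ".join(sorted(set(unresolved)))
        )
    reactions = canon_reactions

    transforms: list[_Transform] = [_transform(r, None) for r in reactions]

    universe: dict[str, Species] = {}
    for r in reactions:
        for sp in itertools.chain(r.reactants, r.products):
            universe.setdefault(sp.canonical_id, sp)
    universe_list = list(universe.values())

    # group by (transformation signature, rate value); the signature already
    # names the transformed agents, and spectator agents bound inside the
    # reactant complexes (e.g. ligands at other sites) must not split groups
    groups: dict[tuple, list[int]] = {}
    for idx, (r, tr) in enumerate(zip(reactions, transforms)):
        base = (tr.signature(),)
        placed = False
        for key, members in groups.items():
            if key[0] == base and _rates_equal(
                reactions[members[0]].rate, r.rate, rate_tolerance
            ):
                members.append(idx)
                placed = True
                break
        if not placed:
            groups[(base, idx)] = [idx]

    rules: list[Rule] = []
    comp_rules: dict[str, list[Rule]] = {}
    comp_reactions: dict[str, int] = {}
    for r in reactions:
        comp = r.component or "(unassigned)"
        comp_reactions[comp] = comp_reactions.get(comp, 0) + 1

    def _key(r: Reaction) -> tuple:
        # with a rate tolerance, rates were already matched at grouping time;
        # the round trip then compares channels only
        k = _reaction_key(r)
        return k if rate_tolerance == 0 else k[:2]

    def expected_of(members: list[int]) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for i in members:
            k = _key(reactions[i])
            out[k] = out.get(k, 0) + 1
        return out

    def generated_of(rule_set: list[Rule]) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for rx in expand_rules_over_species(rule_set, universe_list):
            k = _key(rx)
            out[k] = out.get(k, 0) + 1
        return out

    gidx = 0
    for key, members in sorted(groups.items(), key=lambda kv: min(kv[1])):
        gidx += 1
        rep = transforms[members[0]]
        rate = reactions[members[0]].rate
        rate_id = reactions[members[0]].rate_id or f"k_rule{gidx}"
        comp = reactions[members[0]].component or "(unassigned)"
        expected = expected_of(members)

        emitted: Optional[list[Rule]] = None
        if len(members) >= 1:
            candidate = _build_rule(f"rule{gidx}", rep, rate, rate_id, full_context=False)
            if generated_of([candidate]) == expected:
                emitted = [candidate]
        if emitted is None:
            contextual = []
            for k, i in enumerate(members):
                contextual.append(
                    _build_rule(
                        f"rule{gidx}" + (f"_{k + 1}" if len(members) > 1 else ""),
                        transforms[i],
                        reactions[i].rate,
                        reactions[i].rate_id or rate_id,
                        full_context=True,
                    )
                )
            if generated_of(contextual) != expected:
                raise RuntimeError(
                    f"condensation failed to round-trip group {gidx} "
                    f"({[reactions[i].provenance for i in members]})"
                )
            emitted = contextual
        rules.extend(emitted)
        comp_rules.setdefault(comp, []).extend(emitted)

    report = CondensationReport()
    for comp in sorted(comp_reactions):
        rs = comp_rules.get(comp, [])
        report.rows.append(
            (
                comp,
                comp_reactions[comp],
                len(rs),
                len({r.rate for r in rs}),
            )
        )
    return rules, report
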
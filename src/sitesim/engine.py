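"""Pattern embedding, rule application, and reaction-network generation.

A rule's left-hand side is a multiset of connected pattern components; an
*embedding* injects one component into a molecular species, preserving agent
names, specified internal states and bonds (unspecified fields are wildcards).
Rules are generators of reaction networks: the fixed-point closure over a seed
mixture enumerates every reachable species and one mass-action reaction per
(rule, reactant-species channel, product outcome).

Rate convention: a generated reaction's constant is the rule's stochastic
constant multiplied by the number of distinct embeddings into one fixed
combination of reactant instances that produce the given products.  For
asymmetric rules this multiplier is 1; for a self-binding rule ``A+A`` it is 2,
which together with the n(n-1)/2 combination count used by the simulators
reproduces embedding-based (Kappa-style) total propensities with no
symmetry-factor scaling of the rule constant itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .core import (
    BOUND_ANY,
    FREE,
    UNSPEC,
    AgentPattern,
    BoundTo,
    ComplexPattern,
    Mixture,
    Reaction,
    Rule,
    SignatureSet,
    SiteGraph,
    Species,
    SitePattern,
    rule_errors,
    validate_rule,
)

__all__ = [
    "Embedding",
    "NetworkTooLarge",
    "ReactionNetwork",
    "find_embeddings",
    "apply_rule",
    "generate_network",
    "expand_rules_over_species",
]


@dataclass(frozen=True)
class Embedding:
    """An injective match of a pattern component into one species."""

    species: Species
    mapping: tuple[tuple[int, int], ...]  # (pattern agent idx, graph agent idx)

    def map(self) -> dict[int, int]:
        return dict(self.mapping)


class NetworkTooLarge(RuntimeError):
    """Raised when the closure exceeds the species cap (combinatorial explosion)."""


# ---------------------------------------------------------------------------
# Embedding search
# ---------------------------------------------------------------------------


def _site_ok(sp: SitePattern, graph: SiteGraph, gi: int) -> bool:
    if sp.site not in graph.states[gi]:
        return False
    if sp.internal is not None and graph.states[gi][sp.site] != sp.internal:
        return False
    bond = graph.bonds.get((gi, sp.site))
    b = sp.binding
    if b == FREE:
        return bond is None
    if b == BOUND_ANY or isinstance(b, int):
        return bond is not None
    if isinstance(b, BoundTo):
        return (
            bond is not None
            and graph.agents[bond[0]] == b.agent
            and bond[1] == b.site
        )
    return True  # UNSPEC


def _match_component(
    pattern: ComplexPattern, indices: Sequence[int], graph: SiteGraph
) -> list[dict[int, int]]:
    """All injective embeddings of one pattern component into a concrete graph."""
    bond_ends = {
        label: ends
        for label, ends in pattern.bond_endpoints().items()
        if ends[0][0] in indices
    }
    order = list(indices)
    results: list[dict[int, int]] = []
    n = len(graph.agents)

    def backtrack(k: int, assign: dict[int, int], used: set[int]) -> None:
        if k == len(order):
            results.append(dict(assign))
            return
        pi = order[k]
        ap = pattern.agents[pi]
        for gi in range(n):
            if gi in used or graph.agents[gi] != ap.name:
                continue
            ok = all(_site_ok(sp, graph, gi) for sp in ap.sites)
            if not ok:
                continue
            # bond-label consistency with already-assigned endpoints
            for sp in ap.sites:
                if not isinstance(sp.binding, int):
                    continue
                ends = bond_ends.get(sp.binding)
                if ends is None or len(ends) != 2:
                    continue
                other = ends[0] if ends[1] == (pi, sp.site) else ends[1]
                if other[0] in assign:
                    if graph.bonds.get((gi, sp.site)) != (assign[other[0]], other[1]):
                        ok = False
                        break
            if not ok:
                continue
            assign[pi] = gi
            used.add(gi)
            backtrack(k + 1, assign, used)
            del assign[pi]
            used.discard(gi)

    backtrack(0, {}, set())
    return results


def find_embeddings(
    pattern: ComplexPattern,
    target: Union[Species, SiteGraph, Mixture],
) -> list[Embedding]:
    """Exhaustive, duplicate-free list of embeddings of ``pattern`` into
    ``target``.  For a multi-component pattern all components must embed into
    the same species, injectively overall.  For a :class:`Mixture`, embeddings
    into each distinct species present (copy numbers are not multiplied in)."""
    if isinstance(target, Mixture):
        out: list[Embedding] = []
        for sp in target.species():
            if target.count(sp) > 0:
                out.extend(find_embeddings(pattern, sp))
        return out
    if isinstance(target, SiteGraph):
        species = Species.from_graph(target)
    else:
        species = target
    graph = species.graph
    if graph is None:
        raise ValueError(f"species {species.canonical_id!r} has no graph")
    if not pattern.agents:
        return []
    comps = pattern.components()
    per_comp = [_match_component(pattern, comp, graph) for comp in comps]
    out = []
    for combo in itertools.product(*per_comp):
        merged: dict[int, int] = {}
        used: set[int] = set()
        ok = True
        for m in combo:
            for pi, gi in m.items():
                if gi in used:
                    ok = False
                    break
                merged[pi] = gi
                used.add(gi)
            if not ok:
                break
        if ok:
            out.append(
                Embedding(species, tuple(sorted(merged.items())))
            )
    return out


# ---------------------------------------------------------------------------
# Rule actions and application
# ---------------------------------------------------------------------------


def _pattern_bonds(cp: ComplexPattern) -> set[frozenset]:
    out = set()
    for ends in cp.bond_endpoints().values():
        if len(ends) == 2:
            out.add(frozenset(map(tuple, ends)))
    return out


@dataclass(frozen=True)
class _Actions:
    set_state: tuple[tuple[int, str, str], ...]  # (rhs agent idx, site, new state)
    unbind: tuple[tuple[int, str], ...]  # one endpoint per deleted bond
    bind: tuple[tuple[tuple[int, str], tuple[int, str]], ...]
    delete: tuple[int, ...]  # lhs agent indices
    create: tuple[AgentPattern, ...]  # rhs agents beyond the kept prefix
    n_keep: int


def compile_actions(rule: Rule) -> _Actions:
    """Decompose a rule into primitive rewrite actions (indices refer to lhs
    positions for kept/deleted agents; created bonds may reference created
    agents as n_keep + offset)."""
    n_keep = min(len(rule.lhs.agents), len(rule.rhs.agents))
    set_state = []
    for i in range(n_keep):
        la, ra = rule.lhs.agents[i], rule.rhs.agents[i]
        for rsp in ra.sites:
            lsp = la.site(rsp.site)
            if rsp.internal is not None and (lsp is None or lsp.internal != rsp.internal):
                set_state.append((i, rsp.site, rsp.internal))
    lhs_bonds = _pattern_bonds(rule.lhs)
    rhs_bonds = _pattern_bonds(rule.rhs)
    unbind = []
    for b in sorted(lhs_bonds - rhs_bonds, key=sorted):
        (i, s), _ = sorted(b)
        unbind.append((i, s))
    # BOUND_ANY -> FREE also severs a (wildcard) bond
    for i in range(n_keep):
        la, ra = rule.lhs.agents[i], rule.rhs.agents[i]
        for rsp in ra.sites:
            lsp = la.site(rsp.site)
            if lsp is not None and lsp.binding == BOUND_ANY and rsp.binding == FREE:
                unbind.append((i, rsp.site))
    bind = tuple(
        tuple(sorted(map(tuple, b))) for b in sorted(rhs_bonds - lhs_bonds, key=sorted)
    )
    delete = tuple(range(n_keep, len(rule.lhs.agents)))
    create = tuple(rule.rhs.agents[n_keep:])
    return _Actions(tuple(set_state), tuple(unbind), bind, delete, create, n_keep)


def _apply_to_graph(
    actions: _Actions,
    union: SiteGraph,
    lhs_to_union: dict[int, int],
    signatures: Optional[SignatureSet] = None,
) -> list[SiteGraph]:
    """Apply compiled actions to a disjoint union of reactant instances and
    return the product connected components."""
    work = union.copy()
    created_base = len(work.agents)
    for ap in actions.create:
        smap: dict[str, Optional[str]] = {}
        for sp in ap.sites:
            smap[sp.site] = sp.internal
        work.agents.append(ap.name)
        work.states.append(smap)

    def loc(idx: int) -> int:
        if idx in lhs_to_union:
            return lhs_to_union[idx]
        return created_base + (idx - actions.n_keep)

    for i, site in actions.unbind:
        gi = loc(i)
        partner = work.bonds.pop((gi, site), None)
        if partner is not None:
            work.bonds.pop(partner, None)
    for (i, si), (j, sj) in actions.bind:
        gi, gj = loc(i), loc(j)
        if (gi, si) in work.bonds or (gj, sj) in work.bonds:
            raise ValueError("binding to an occupied site")
        work.bonds[(gi, si)] = (gj, sj)
        work.bonds[(gj, sj)] = (gi, si)
    for i, site, state in actions.set_state:
        work.states[loc(i)][site] = state

    removed = {loc(i) for i in actions.delete}
    if removed:
        # deleting an agent severs its bonds (partner sites become free)
        for (gi, s), (gj, t) in list(work.bonds.items()):
            if gi in removed or gj in removed:
                work.bonds.pop((gi, s), None)
                work.bonds.pop((gj, t), None)
        keep = [i for i in range(len(work.agents)) if i not in removed]
        work = work.subgraph(keep)

    comps = work.connected_components()
    out = [work.subgraph(c) for c in comps]
    if signatures is not None:
        for g in out:
            g.validate(signatures)
    return out


def _union_graphs(graphs: Sequence[SiteGraph]) -> tuple[SiteGraph, list[int]]:
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


def _products_for(
    rule: Rule,
    actions: _Actions,
    comp_indices: list[list[int]],
    instance_graphs: Sequence[SiteGraph],
    comp_embeddings: Sequence[dict[int, int]],
    signatures: Optional[SignatureSet],
) -> list[Species]:
    union, offsets = _union_graphs(instance_graphs)
    lhs_to_union: dict[int, int] = {}
    for comp, emb, off in zip(comp_indices, comp_embeddings, offsets):
        for pi in comp:
            lhs_to_union[pi] = emb[pi] + off
    graphs = _apply_to_graph(actions, union, lhs_to_union, signatures)
    return [Species.from_graph(g) for g in graphs]


def apply_rule(
    rule: Rule,
    embeddings: Union[Embedding, Sequence[Embedding]],
    mixture: Mixture,
    signatures: Optional[SignatureSet] = None,
) -> Mixture:
    """Apply one rule instance to a mixture: reactant copies are consumed and
    product species added.  ``embeddings`` supplies one embedding per lhs
    component.  A stale embedding (reactant no longer present, or a site no
    longer matching) is rejected."""
    if isinstance(embeddings, Embedding):
        embeddings = [embeddings]
    comps = rule.lhs.components()
    if len(embeddings) != len(comps):
        raise ValueError(
            f"rule {rule.name!r} needs {len(comps)} embedding(s), got {len(embeddings)}"
        )
    needed: dict[str, int] = {}
    for emb in embeddings:
        needed[emb.species.canonical_id] = needed.get(emb.species.canonical_id, 0) + 1
    for cid, n in needed.items():
        if mixture.count(cid) < n:
            raise ValueError(f"stale embedding: {cid} not present in mixture")
    maps = []
    for comp, emb in zip(comps, embeddings):
        m = emb.map()
        if set(m) == set(range(len(comp))) and set(m) != set(comp):
            # embedding found against the standalone component pattern:
            # remap its local indices onto the rule's global agent indices
            m = {comp[k]: v for k, v in m.items()}
        if set(m) != set(comp):
            raise ValueError(
                f"embedding does not cover component agents {comp} of rule "
                f"{rule.name!r}"
            )
        # verify the embedding still matches (sites may differ from when found)
        cand = _match_component(rule.lhs, comp, emb.species.graph)
        if not any(all(c[pi] == m[pi] for pi in comp) for c in cand):
            raise ValueError(f"stale embedding for rule {rule.name!r}")
        maps.append(m)
    products = _products_for(
        rule,
        compile_actions(rule),
        comps,
        [emb.species.graph for emb in embeddings],
        maps,
        signatures,
    )
    out = mixture.copy()
    for emb in embeddings:
        out.remove(emb.species)
    for sp in products:
        out.add(sp, 1)
    return out


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


class ReactionNetwork:
    """Explicit species and mass-action reactions, generated from rules or
    imported from a reaction list (e.g. SBML)."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        self.species: list[Species] = sorted(species, key=lambda s: s.canonical_id)
        self.index: dict[str, int] = {
            s.canonical_id: i for i, s in enumerate(self.species)
        }
        if len(self.index) != len(self.species):
            raise ValueError("duplicate species ids")
        self.reactions: list[Reaction] = sorted(reactions, key=lambda r: r.key())
        for r in self.reactions:
            for s in itertools.chain(r.reactants, r.products):
                if s.canonical_id not in self.index:
                    raise ValueError(f"reaction references unknown species {s.canonical_id!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def rate_ids(self) -> list[str]:
        return sorted({r.rate_id for r in self.reactions if r.rate_id is not None})

    def species_by_id(self, cid: str) -> Species:
        return self.species[self.index[cid]]

    @staticmethod
    def from_reactions(reactions: Iterable[Reaction]) -> "ReactionNetwork":
        reactions = list(reactions)
        seen: dict[str, Species] = {}
        for r in reactions:
            for s in itertools.chain(r.reactants, r.products):
                seen.setdefault(s.canonical_id, s)
        return ReactionNetwork(seen.values(), reactions)


def _validated(rules: Sequence[Rule], signatures: Optional[SignatureSet]) -> None:
    if signatures is None:
        return
    for rule in rules:
        errs = rule_errors(validate_rule(rule, signatures))
        if errs:
            raise ValueError(
                f"invalid rule {rule.name!r}: " + "; ".join(v.message for v in errs)
            )


# outcome key -> (embedding-combination weight, product Species by id)
Outcome = dict[tuple[tuple[str, ...], tuple[str, ...]], tuple[int, dict[str, Species]]]


def _channels_for_assignment(
    rule: Rule,
    actions: _Actions,
    comps: list[list[int]],
    assignment: Sequence[Species],
    emb_cache: dict[tuple[str, int], list[dict[int, int]]],
    signatures: Optional[SignatureSet],
) -> Outcome:
    """Outcomes of one type-assignment (component j -> species assignment[j]).

    Each component acts on its own reactant instance (two components assigned
    to the same species use two distinct copies).  The weight contributed per
    embedding combination is the number of bijections of components onto
    labelled instances inducing this assignment, i.e. the product of
    factorials of the species multiplicities.
    """
    from math import factorial

    def embs(comp_idx: int, sp: Species) -> list[dict[int, int]]:
        key = (sp.canonical_id, comp_idx)
        if key not in emb_cache:
            emb_cache[key] = _match_component(rule.lhs, comps[comp_idx], sp.graph)
        return emb_cache[key]

    counts: dict[str, int] = {}
    for sp in assignment:
        counts[sp.canonical_id] = counts.get(sp.canonical_id, 0) + 1
    weight = 1
    for m in counts.values():
        weight *= factorial(m)
    r_ids = tuple(sorted(s.canonical_id for s in assignment))
    graphs = [s.graph for s in assignment]

    outcomes: Outcome = {}
    for combo in itertools.product(*(embs(j, sp) for j, sp in enumerate(assignment))):
        products = _products_for(rule, actions, comps, graphs, list(combo), signatures)
        p_ids = tuple(sorted(s.canonical_id for s in products))
        if p_ids == r_ids:
            continue  # no-op outcome
        mult, prods = outcomes.get((r_ids, p_ids), (0, {}))
        for s in products:
            prods.setdefault(s.canonical_id, s)
        outcomes[(r_ids, p_ids)] = (mult + weight, prods)
    return outcomes


def _merge_outcomes(acc: dict, ri: int, outcomes: Outcome, prods_out: dict) -> None:
    for (r_ids, p_ids), (mult, prods) in outcomes.items():
        key = (ri, r_ids, p_ids)
        acc[key] = acc.get(key, 0) + mult
        prods_out.update(prods)


def generate_network(
    rules: Sequence[Rule],
    seeds: Sequence[Species],
    signatures: Optional[SignatureSet] = None,
    species_cap: int = 10_000,
    component_of: Optional[dict[str, str]] = None,
) -> ReactionNetwork:
    """Fixed-point closure: enumerate every species reachable from ``seeds``
    under the rules, with one mass-action reaction per (rule, reactant channel,
    product outcome).  Output is independent of rule and seed ordering.

    ``component_of`` optionally labels reactions by model component, keyed by
    rule name.  Raises :class:`NetworkTooLarge` when more than ``species_cap``
    species are found — the combinatorial-explosion guard.
    """
    _validated(rules, signatures)
    compiled = []
    for rule in rules:
        comps = rule.lhs.components()
        compiled.append((rule, compile_actions(rule), comps))

    species: dict[str, Species] = {}
    queue: list[Species] = []

    def note_species(s: Species) -> None:
        if s.canonical_id not in species:
            if len(species) >= species_cap:
                raise NetworkTooLarge(
                    f"network too large: species cap {species_cap} exceeded"
                )
            species[s.canonical_id] = s
            queue.append(s)

    for s in seeds:
        note_species(s)
    # accumulator: (rule idx, reactant ids, product ids) -> multiplier
    acc: dict[tuple, int] = {}
    emb_caches: list[dict] = [dict() for _ in compiled]
    # per rule, per component: processed species with >=1 embedding
    match_lists: list[list[list[Species]]] = [
        [[] for _ in comps] for _, _, comps in compiled
    ]

    # synthesis rules fire independently of the mixture
    for ri, (rule, actions, comps) in enumerate(compiled):
        if comps:
            continue
        prods = _products_for(rule, actions, [], [], [], signatures)
        p_ids = tuple(sorted(s.canonical_id for s in prods))
        acc[(ri, (), p_ids)] = 1
        for s in prods:
            note_species(s)

    queue.sort(key=lambda s: s.canonical_id)
    while queue:
        S = queue.pop(0)
        new_products: dict[str, Species] = {}
        for ri, (rule, actions, comps) in enumerate(compiled):
            if not comps:
                continue
            cache = emb_caches[ri]
            matches_S = []
            for j in range(len(comps)):
                key = (S.canonical_id, j)
                if key not in cache:
                    cache[key] = _match_component(rule.lhs, comps[j], S.graph)
                matches_S.append(bool(cache[key]))
            if not any(matches_S):
                continue
            # enumerate type-assignments drawn from processed species that
            # involve S in at least one slot (channels without S were handled
            # when their own last member was processed)
            pools = []
            for j, lst in enumerate(match_lists[ri]):
                pool = list(lst)
                if matches_S[j]:
                    pool.append(S)
                pools.append(pool)
            for assignment in itertools.product(*pools):
                if not any(sp.canonical_id == S.canonical_id for sp in assignment):
                    continue
                outcomes = _channels_for_assignment(
                    rule, actions, comps, assignment, cache, signatures
                )
                _merge_outcomes(acc, ri, outcomes, new_products)
            for j, lst in enumerate(match_lists[ri]):
                if matches_S[j]:
                    lst.append(S)
        for s in new_products.values():
            note_species(s)

    reactions = []
    for (ri, r_ids, p_ids), mult in acc.items():
        rule = compiled[ri][0]
        reactions.append(
            Reaction(
                reactants=tuple(species[c] for c in r_ids),
                products=tuple(species[c] for c in p_ids),
                rate=rule.rate * mult,
                rate_id=rule.rate_id,
                provenance=rule.name,
                component=(component_of or {}).get(rule.name),
                multiplicity=mult,
            )
        )
    return ReactionNetwork(species.values(), reactions)


def expand_rules_over_species(
    rules: Sequence[Rule],
    universe: Sequence[Species],
    signatures: Optional[SignatureSet] = None,
) -> list[Reaction]:
    """Single-step expansion: every reaction the rules generate whose reactants
    are drawn from ``universe`` (no new reactant species are discovered;
    products may fall outside the universe, which callers can use to detect
    over-generation).  Used by the condensation round-trip check."""
    _validated(rules, signatures)
    uni = [s for s in sorted(universe, key=lambda s: s.canonical_id) if s.graph is not None]
    species = {s.canonical_id: s for s in universe}
    reactions: list[Reaction] = []
    for rule in rules:
        comps = rule.lhs.components()
        actions = compile_actions(rule)
        cache: dict = {}
        acc: dict[tuple, int] = {}
        prods_seen: dict[str, Species] = {}
        if not comps:
            prods = _products_for(rule, actions, [], [], [], signatures)
            p_ids = tuple(sorted(s.canonical_id for s in prods))
            acc[(0, (), p_ids)] = 1
            for s in prods:
                prods_seen.setdefault(s.canonical_id, s)
        else:
            match_pool = [
                [
                    s
                    for s in uni
                    if cache.setdefault(
                        (s.canonical_id, j),
                        _match_component(rule.lhs, comps[j], s.graph),
                    )
                ]
                for j in range(len(comps))
            ]
            for assignment in itertools.product(*match_pool):
                outcomes = _channels_for_assignment(
                    rule, actions, comps, assignment, cache, signatures
                )
                _merge_outcomes(acc, 0, outcomes, prods_seen)
        for (_, r_ids, p_ids), mult in acc.items():
            species.update(prods_seen)
            reactions.append(
                Reaction(
                    reactants=tuple(species[c] for c in r_ids),
                    products=tuple(species[c] for c in p_ids),
                    rate=rule.rate * mult,
                    rate_id=rule.rate_id,
                    provenance=rule.name,
                    multiplicity=mult,
                )
            )
    return reactions
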
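"""Independent oracles for engine properties.

These deliberately re-derive pattern matching and rule application with the
simplest possible algorithms (all-injections enumeration, mixture-level
breadth-first closure), sharing no search or rewrite code with the engine.
"""

from __future__ import annotations

import itertools

from sitesim.core import (
    BOUND_ANY,
    FREE,
    UNSPEC,
    BoundTo,
    ComplexPattern,
    Rule,
    SiteGraph,
    Species,
)


def naive_embeddings(pattern: ComplexPattern, graph: SiteGraph) -> list[dict[int, int]]:
    """All injective maps pattern-agent -> graph-agent satisfying every site
    condition, found by brute-force enumeration over all injections."""
    np_, ng = len(pattern.agents), len(graph.agents)
    if np_ == 0 or np_ > ng:
        return []
    # bond label -> the two endpoints
    label_ends: dict[int, list[tuple[int, str]]] = {}
    for i, ap in enumerate(pattern.agents):
        for sp in ap.sites:
            if isinstance(sp.binding, int):
                label_ends.setdefault(sp.binding, []).append((i, sp.site))
    out = []
    for combo in itertools.permutations(range(ng), np_):
        ok = True
        for pi, gi in enumerate(combo):
            ap = pattern.agents[pi]
            if graph.agents[gi] != ap.name:
                ok = False
                break
            for sp in ap.sites:
                if sp.site not in graph.states[gi]:
                    ok = False
                    break
                if sp.internal is not None and graph.states[gi][sp.site] != sp.internal:
                    ok = False
                    break
                bond = graph.bonds.get((gi, sp.site))
                b = sp.binding
                if b == FREE and bond is not None:
                    ok = False
                elif b == BOUND_ANY and bond is None:
                    ok = False
                elif isinstance(b, BoundTo):
                    if bond is None or graph.agents[bond[0]] != b.agent or bond[1] != b.site:
                        ok = False
                elif isinstance(b, int):
                    if bond is None:
                        ok = False
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        # bond-label pairing
        for ends in label_ends.values():
            if len(ends) != 2:
                continue
            (i1, s1), (i2, s2) = ends
            if graph.bonds.get((combo[i1], s1)) != (combo[i2], s2):
                ok = False
                break
        if ok:
            out.append({pi: gi for pi, gi in enumerate(combo)})
    return out


def _apply_naive(
    rule: Rule, instance_graphs: list[SiteGraph], comp_embeddings, comps
) -> list[SiteGraph]:
    """Minimal independent rewrite: union the instances, then edit according
    to the lhs/rhs site patterns position by position."""
    agents, states, bonds = [], [], {}
    offsets = []
    off = 0
    for g in instance_graphs:
        offsets.append(off)
        agents.extend(g.agents)
        states.extend(dict(s) for s in g.states)
        for (i, s), (j, t) in g.bonds.items():
            bonds[(i + off, s)] = (j + off, t)
        off += len(g.agents)

    loc = {}
    for comp, emb, o in zip(comps, comp_embeddings, offsets):
        for pi in comp:
            loc[pi] = emb[pi] + o

    n_keep = min(len(rule.lhs.agents), len(rule.rhs.agents))
    # rhs bond labels -> endpoints (pattern indices)
    rhs_ends: dict[int, list[tuple[int, str]]] = {}
    for i, ap in enumerate(rule.rhs.agents):
        for sp in ap.sites:
            if isinstance(sp.binding, int):
                rhs_ends.setdefault(sp.binding, []).append((i, sp.site))
    lhs_bond_of: dict[tuple[int, str], int] = {}
    for i, ap in enumerate(rule.lhs.agents):
        for sp in ap.sites:
            if isinstance(sp.binding, int):
                lhs_bond_of[(i, sp.site)] = sp.binding

    created_base = len(agents)
    for k, i in enumerate(range(n_keep, len(rule.rhs.agents))):
        ap = rule.rhs.agents[i]
        agents.append(ap.name)
        states.append({sp.site: sp.internal for sp in ap.sites})
        loc[i] = created_base + k

    def unbond(gi, site):
        p = bonds.pop((gi, site), None)
        if p is not None:
            bonds.pop(p, None)

    # state edits and wildcard unbinds on kept agents
    for i in range(n_keep):
        la, ra = rule.lhs.agents[i], rule.rhs.agents[i]
        gi = loc[i]
        for rsp in ra.sites:
            lsp = la.site(rsp.site)
            if rsp.internal is not None:
                states[gi][rsp.site] = rsp.internal
            lb = lsp.binding if lsp else UNSPEC
            if rsp.binding == FREE and lb == BOUND_ANY:
                unbond(gi, rsp.site)
    # remove lhs bonds not present (same label+endpoints) on rhs
    lhs_pairs = {}
    for i, ap in enumerate(rule.lhs.agents):
        for sp in ap.sites:
            if isinstance(sp.binding, int):
                lhs_pairs.setdefault(sp.binding, []).append((i, sp.site))
    rhs_pairs_set = set()
    for ends in rhs_ends.values():
        if len(ends) == 2:
            rhs_pairs_set.add(frozenset(ends))
    for label, ends in lhs_pairs.items():
        if len(ends) == 2 and frozenset(ends) not in rhs_pairs_set:
            i, s = ends[0]
            if i < n_keep:
                unbond(loc[i], s)
    # add rhs bonds not on lhs
    lhs_pairs_set = {frozenset(e) for e in lhs_pairs.values() if len(e) == 2}
    for ends in rhs_ends.values():
        if len(ends) != 2 or frozenset(ends) in lhs_pairs_set:
            continue
        (i1, s1), (i2, s2) = ends
        bonds[(loc[i1], s1)] = (loc[i2], s2)
        bonds[(loc[i2], s2)] = (loc[i1], s1)

    # deletions
    removed = {loc[i] for i in range(n_keep, len(rule.lhs.agents))}
    for (gi, s), (gj, t) in list(bonds.items()):
        if gi in removed or gj in removed:
            bonds.pop((gi, s), None)
            bonds.pop((gj, t), None)
    keep = [i for i in range(len(agents)) if i not in removed]
    remap = {old: new for new, old in enumerate(keep)}
    g = SiteGraph(
        [agents[i] for i in keep],
        [states[i] for i in keep],
        {
            (remap[i], s): (remap[j], t)
            for (i, s), (j, t) in bonds.items()
            if i in remap and j in remap
        },
    )
    comps_idx = g.connected_components()
    return [g.subgraph(c) for c in comps_idx]


def brute_closure(rules: list[Rule], seed_graphs: list[SiteGraph]) -> set[str]:
    """Exhaustive breadth-first enumeration of reachable species ids, using
    the naive matcher and the independent rewrite above."""
    species: dict[str, SiteGraph] = {}
    frontier = []
    for g in seed_graphs:
        sp = Species.from_graph(g)
        if sp.canonical_id not in species:
            species[sp.canonical_id] = g
            frontier.append(sp.canonical_id)

    changed = True
    while changed:
        changed = False
        current = list(species.items())
        for rule in rules:
            comps = rule.lhs.components()
            if not comps:
                prods = _apply_naive(rule, [], [], [])
                for pg in prods:
                    pid = Species.from_graph(pg).canonical_id
                    if pid not in species:
                        species[pid] = pg
                        changed = True
                continue
            pools = []
            for comp in comps:
                sub_matches = []
                for cid, g in current:
                    for emb in naive_embeddings(rule.lhs.subpattern(comp), g):
                        # re-index embedding to pattern's global indices
                        remapped = {comp[k]: v for k, v in emb.items()}
                        sub_matches.append((cid, remapped))
                pools.append(sub_matches)
            for combo in itertools.product(*pools):
                graphs = [species[cid] for cid, _ in combo]
                embs = [emb for _, emb in combo]
                prods = _apply_naive(rule, graphs, embs, comps)
                for pg in prods:
                    pid = Species.from_graph(pg).canonical_id
                    if pid not in species:
                        species[pid] = pg
                        changed = True
    return set(species)
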
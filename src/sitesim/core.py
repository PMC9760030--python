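"""Core domain types for rule-based (site-graph) models.

Molecules are *agents*: typed nodes carrying named *sites*.  A site holds an
optional internal state (e.g. ``u``/``p`` for a phosphosite) and a binding
state (free, or bonded to one site of one other agent).  A fully specified,
connected site-graph is a *molecular species*; a partially specified one is a
*pattern*.  Rules are pattern-conditioned rewrites with stochastic rate
constants.

Canonical species identifiers are produced by :func:`canonical_species`:
iterative neighbourhood (colour) refinement followed by a lexicographically
minimal serialization, searching over the remaining colour ties.  Complexes in
the signalling models this package targets are small (~10 agents), so the
backtracking search is cheap.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "FREE",
    "BOUND_ANY",
    "UNSPEC",
    "BoundTo",
    "AgentSignature",
    "SignatureSet",
    "SiteGraph",
    "Species",
    "SitePattern",
    "AgentPattern",
    "ComplexPattern",
    "Rule",
    "Reaction",
    "Mixture",
    "UnitContext",
    "Violation",
    "canonical_species",
    "validate_rule",
]

# Binding-state markers used in patterns.  In concrete graphs a site is either
# free (bond is None) or bonded (bond is a (partner_index, partner_site) pair).
FREE = "."
BOUND_ANY = "_"
UNSPEC = "?"


@dataclass(frozen=True)
class BoundTo:
    """Pattern binding condition: bonded to site ``site`` of an agent ``agent``
    whose partner is not itself part of the pattern."""

    agent: str
    site: str


Binding = Union[str, int, BoundTo]  # FREE | BOUND_ANY | UNSPEC | bond label | BoundTo


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentSignature:
    """Declaration of an agent type: its sites and their allowed internal states.

    Sites without internal states (pure binding sites) map to an empty tuple.
    """

    name: str
    sites: tuple[str, ...]
    internal_states: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError(f"duplicate site names in agent {self.name!r}")
        for s in self.internal_states:
            if s not in self.sites:
                raise ValueError(
                    f"internal states declared for unknown site {s!r} of {self.name!r}"
                )

    def states(self, site: str) -> tuple[str, ...]:
        return tuple(self.internal_states.get(site, ()))


class SignatureSet:
    """A set of agent signatures, indexed by agent name."""

    def __init__(self, signatures: Iterable[AgentSignature]):
        self._by_name: dict[str, AgentSignature] = {}
        for sig in signatures:
            if sig.name in self._by_name:
                raise ValueError(f"duplicate agent signature {sig.name!r}")
            self._by_name[sig.name] = sig

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AgentSignature:
        return self._by_name[name]

    def __iter__(self):
        return iter(self._by_name.values())

    def names(self) -> list[str]:
        return list(self._by_name)


# ---------------------------------------------------------------------------
# Concrete site-graphs and species
# ---------------------------------------------------------------------------


class SiteGraph:
    """A concrete site-graph: agents with fully specified site states and bonds.

    ``agents`` is a list of agent names.  ``states[i]`` maps each site of agent
    ``i`` to its internal state (``None`` for stateless sites).  ``bonds`` maps
    ``(i, site)`` to ``(j, site')`` symmetrically; absent keys are free sites.
    """

    __slots__ = ("agents", "states", "bonds")

    def __init__(
        self,
        agents: Sequence[str],
        states: Sequence[Mapping[str, Optional[str]]],
        bonds: Mapping[tuple[int, str], tuple[int, str]],
    ):
        self.agents: list[str] = list(agents)
        self.states: list[dict[str, Optional[str]]] = [dict(s) for s in states]
        self.bonds: dict[tuple[int, str], tuple[int, str]] = {}
        for a, b in bonds.items():
            self.bonds[a] = tuple(b)
            self.bonds[tuple(b)] = tuple(a)

    def copy(self) -> "SiteGraph":
        g = SiteGraph.__new__(SiteGraph)
        g.agents = list(self.agents)
        g.states = [dict(s) for s in self.states]
        g.bonds = dict(self.bonds)
        return g

    def __len__(self) -> int:
        return len(self.agents)

    def neighbours(self, i: int) -> list[tuple[str, int, str]]:
        """(site, partner index, partner site) for every bond of agent ``i``."""
        out = []
        for site in self.states[i]:
            p = self.bonds.get((i, site))
            if p is not None:
                out.append((site, p[0], p[1]))
        return out

    def connected_components(self) -> list[list[int]]:
        seen: set[int] = set()
        comps: list[list[int]] = []
        for start in range(len(self.agents)):
            if start in seen:
                continue
            comp = [start]
            seen.add(start)
            stack = [start]
            while stack:
                i = stack.pop()
                for _, j, _ in self.neighbours(i):
                    if j not in seen:
                        seen.add(j)
                        comp.append(j)
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    def is_connected(self) -> bool:
        return len(self.agents) <= 1 or len(self.connected_components()) == 1

    def subgraph(self, indices: Sequence[int]) -> "SiteGraph":
        remap = {old: new for new, old in enumerate(indices)}
        agents = [self.agents[i] for i in indices]
        states = [self.states[i] for i in indices]
        bonds = {}
        for (i, s), (j, t) in self.bonds.items():
            if i in remap and j in remap:
                bonds[(remap[i], s)] = (remap[j], t)
        return SiteGraph(agents, states, bonds)

    def validate(self, signatures: SignatureSet) -> None:
        for i, name in enumerate(self.agents):
            if name not in signatures:
                raise ValueError(f"unknown agent {name!r}")
            sig = signatures[name]
            if set(self.states[i]) != set(sig.sites):
                raise ValueError(
                    f"agent {name!r} must specify all sites {sig.sites}, "
                    f"got {tuple(self.states[i])}"
                )
            for site, state in self.states[i].items():
                allowed = sig.states(site)
                if allowed and state not in allowed:
                    raise ValueError(
                        f"state {state!r} not allowed on {name}.{site} ({allowed})"
                    )
                if not allowed and state is not None:
                    raise ValueError(f"site {name}.{site} carries no internal state")


def _initial_colours(graph: SiteGraph) -> list[tuple]:
    cols = []
    for i, name in enumerate(graph.agents):
        sites = tuple(
            (s, graph.states[i][s], (i, s) in graph.bonds)
            for s in sorted(graph.states[i])
        )
        cols.append((name, sites))
    return cols


def _refine(graph: SiteGraph, cols: list) -> list[int]:
    """Weisfeiler–Lehman-style colour refinement; returns integer colours."""
    n = len(graph.agents)
    colours = {c: k for k, c in enumerate(sorted(set(cols)))}
    cur = [colours[c] for c in cols]
    for _ in range(n):
        nxt_raw = []
        for i in range(n):
            nb = sorted((s, t, cur[j]) for s, j, t in graph.neighbours(i))
            nxt_raw.append((cur[i], tuple(nb)))
        mapping = {c: k for k, c in enumerate(sorted(set(nxt_raw)))}
        nxt = [mapping[c] for c in nxt_raw]
        if nxt == cur:
            break
        cur = nxt
    return cur


def _serialize(graph: SiteGraph, order: Sequence[int]) -> str:
    pos = {old: new for new, old in enumerate(order)}
    bond_labels: dict[frozenset, int] = {}
    next_label = 1
    parts = []
    for old in order:
        site_parts = []
        for site in sorted(graph.states[old]):
            token = site
            st = graph.states[old][site]
            if st is not None:
                token += f"~{st}"
            partner = graph.bonds.get((old, site))
            if partner is not None:
                key = frozenset({(old, site), partner})
                if key not in bond_labels:
                    bond_labels[key] = next_label
                    next_label += 1
                token += f"!{bond_labels[key]}"
            site_parts.append(token)
        parts.append(f"{graph.agents[old]}({','.join(site_parts)})")
    return ",".join(parts)


_PERMUTATION_CAP = 100_000


def canonical_species(graph: SiteGraph, signatures: Optional[SignatureSet] = None) -> str:
    """Canonical identifier of a connected, fully specified site-graph.

    The id is invariant under agent relabelling and distinguishes any two
    non-isomorphic graphs (distinct site occupancy always yields distinct ids).
    """
    if signatures is not None:
        graph.validate(signatures)
    if len(graph.agents) == 0:
        raise ValueError("empty graph has no canonical id")
    if not graph.is_connected():
        raise ValueError("canonical_species requires a connected graph")

    n = len(graph.agents)
    if n == 1:
        return _serialize(graph, [0])

    colours = _refine(graph, _initial_colours(graph))
    # group agents by refined colour; search orderings that sort by colour and
    # permute only within ties, taking the lexicographically minimal string.
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(colours):
        groups.setdefault(c, []).append(i)
    ordered_groups = [groups[c] for c in sorted(groups)]
    n_perm = math.prod(math.factorial(len(g)) for g in ordered_groups)
    if n_perm > _PERMUTATION_CAP:  # pragma: no cover - guard for pathological input
        raise ValueError(
            f"canonicalization search too large ({n_perm} orderings); "
            "complex exceeds supported symmetry"
        )
    best: Optional[str] = None
    for perm_combo in itertools.product(
        *(itertools.permutations(g) for g in ordered_groups)
    ):
        order = [i for grp in perm_combo for i in grp]
        s = _serialize(graph, order)
        if best is None or s < best:
            best = s
    assert best is not None
    return best


@dataclass(frozen=True)
class Species:
    """A canonicalized connected molecular species.

    ``graph`` is ``None`` for name-only species imported from reaction lists
    (e.g. SBML) whose site-graph composition has not been declared.
    """

    canonical_id: str
    graph: Optional[SiteGraph] = None

    @staticmethod
    def from_graph(graph: SiteGraph, signatures: Optional[SignatureSet] = None) -> "Species":
        return Species(canonical_species(graph, signatures), graph)

    def agent_count(self, agent_name: str) -> int:
        if self.graph is None:
            raise ValueError(
                f"species {self.canonical_id!r} has no site-graph composition"
            )
        return sum(1 for a in self.graph.agents if a == agent_name)

    def __eq__(self, other) -> bool:
        return isinstance(other, Species) and self.canonical_id == other.canonical_id

    def __hash__(self) -> int:
        return hash(self.canonical_id)

    def __repr__(self) -> str:
        return f"Species({self.canonical_id!r})"


# ---------------------------------------------------------------------------
# Patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SitePattern:
    """Condition on one site.  ``internal=None`` and ``binding=UNSPEC`` mean the
    condition is absent (decontextualised), not unknown."""

    site: str
    internal: Optional[str] = None
    binding: Binding = UNSPEC


@dataclass(frozen=True)
class AgentPattern:
    name: str
    sites: tuple[SitePattern, ...] = ()

    def site(self, name: str) -> Optional[SitePattern]:
        for sp in self.sites:
            if sp.site == name:
                return sp
        return None

    def site_names(self) -> tuple[str, ...]:
        return tuple(sp.site for sp in self.sites)


@dataclass(frozen=True)
class ComplexPattern:
    """A multiset of agent patterns with bond labels pairing bound sites.

    May be disconnected (e.g. the left-hand side of a binding rule).
    """

    agents: tuple[AgentPattern, ...] = ()

    def bond_endpoints(self) -> dict[int, list[tuple[int, str]]]:
        """bond label -> [(agent index, site), ...]"""
        out: dict[int, list[tuple[int, str]]] = {}
        for i, ap in enumerate(self.agents):
            for sp in ap.sites:
                if isinstance(sp.binding, int):
                    out.setdefault(sp.binding, []).append((i, sp.site))
        return out

    def components(self) -> list[list[int]]:
        """Connected components (lists of agent indices) via shared bond labels."""
        n = len(self.agents)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ends in self.bond_endpoints().values():
            if len(ends) == 2:
                a, b = find(ends[0][0]), find(ends[1][0])
                parent[a] = b
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        return sorted(comps.values())

    def subpattern(self, indices: Sequence[int]) -> "ComplexPattern":
        return ComplexPattern(tuple(self.agents[i] for i in indices))

    def validate(self, signatures: SignatureSet) -> list[str]:
        problems: list[str] = []
        for i, ap in enumerate(self.agents):
            if ap.name not in signatures:
                problems.append(f"unknown agent {ap.name!r}")
                continue
            sig = signatures[ap.name]
            seen_sites: set[str] = set()
            for sp in ap.sites:
                if sp.site in seen_sites:
                    problems.append(f"duplicate site {ap.name}.{sp.site}")
                seen_sites.add(sp.site)
                if sp.site not in sig.sites:
                    problems.append(f"unknown site {ap.name}.{sp.site}")
                    continue
                if sp.internal is not None and sp.internal not in sig.states(sp.site):
                    problems.append(
                        f"undeclared state {sp.internal!r} on {ap.name}.{sp.site}"
                    )
                if isinstance(sp.binding, BoundTo):
                    if sp.binding.agent not in signatures:
                        problems.append(
                            f"bond type references unknown agent {sp.binding.agent!r}"
                        )
                    elif sp.binding.site not in signatures[sp.binding.agent].sites:
                        problems.append(
                            f"bond type references unknown site "
                            f"{sp.binding.agent}.{sp.binding.site}"
                        )
        for label, ends in self.bond_endpoints().items():
            if len(ends) != 2:
                problems.append(
                    f"bond label {label} occurs {len(ends)} time(s), expected 2"
                )
        return problems


# ---------------------------------------------------------------------------
# Rules, reactions, mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """A pattern-conditioned rewrite with a stochastic rate constant.

    Agents of ``lhs`` and ``rhs`` correspond positionally: agent ``i`` of the
    left-hand side is transformed into agent ``i`` of the right-hand side.
    Surplus lhs agents are degraded; surplus rhs agents are synthesized.  The
    rate constant is in stochastic units: per second for unary rules, per
    second per reactant combination for binary ones.  Rules parameterised by
    the same constant share a ``rate_id``.
    """

    name: str
    lhs: ComplexPattern
    rhs: ComplexPattern
    rate: float
    rate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rule {self.name!r}: rate must be nonnegative")

    @property
    def arity(self) -> int:
        return len(self.lhs.components()) if self.lhs.agents else 0


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction between canonical species.

    ``rate`` is the effective stochastic constant of this channel.  For
    reactions generated from rules it equals the rule constant times
    ``multiplicity`` (the embedding-combination count of the channel), so that
    re-parameterising a shared ``rate_id`` during a simulation rescales every
    generated reaction consistently.
    """

    reactants: tuple[Species, ...]  # sorted by canonical_id
    products: tuple[Species, ...]
    rate: float
    rate_id: Optional[str] = None
    provenance: Optional[str] = None  # generating rule name or SBML reaction id
    component: Optional[str] = None  # model-component label (for reports)
    multiplicity: int = 1

    def key(self) -> tuple:
        return (
            tuple(s.canonical_id for s in self.reactants),
            tuple(s.canonical_id for s in self.products),
            self.rate,
            self.rate_id,
        )


class Mixture:
    """Multiset of molecular species with nonnegative integer copy numbers."""

    def __init__(self) -> None:
        self._counts: dict[str, int] = {}
        self._species: dict[str, Species] = {}

    def add(self, species: Species, n: int = 1) -> None:
        if n < 0:
            raise ValueError("copy numbers must be nonnegative")
        self._species[species.canonical_id] = species
        self._counts[species.canonical_id] = self._counts.get(species.canonical_id, 0) + n

    def remove(self, species: Species, n: int = 1) -> None:
        cur = self._counts.get(species.canonical_id, 0)
        if cur < n:
            raise ValueError(f"cannot remove {n} copies of {species.canonical_id}")
        self._counts[species.canonical_id] = cur - n

    def count(self, species_or_id) -> int:
        cid = species_or_id if isinstance(species_or_id, str) else species_or_id.canonical_id
        return self._counts.get(cid, 0)

    def species(self) -> list[Species]:
        return [self._species[cid] for cid in sorted(self._species)]

    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def copy(self) -> "Mixture":
        m = Mixture()
        m._counts = dict(self._counts)
        m._species = dict(self._species)
        return m

    def total_agents(self, agent_name: str) -> int:
        return sum(
            n * self._species[cid].agent_count(agent_name)
            for cid, n in self._counts.items()
            if n
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Mixture):
            return NotImplemented
        a = {k: v for k, v in self._counts.items() if v}
        b = {k: v for k, v in other._counts.items() if v}
        return a == b

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}: {v}" for k, v in sorted(self._counts.items()) if v)
        return f"Mixture({{{inner}}})"


AVOGADRO = 6.02214076e23  # per mole (2019 SI exact value)


@dataclass(frozen=True)
class UnitContext:
    """Reaction volume and Avogadro constant, used to convert deterministic
    (concentration-based) constants and concentrations to stochastic ones."""

    volume: float = 1e-15  # litres; typical subcellular compartment scale
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")


# ---------------------------------------------------------------------------
# Rule validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: {self.message}"


def _binding_kind(b: Binding) -> str:
    if isinstance(b, int):
        return "bond"
    if isinstance(b, BoundTo):
        return "typed"
    return {FREE: "free", BOUND_ANY: "any", UNSPEC: "unspec"}[b]


def validate_rule(rule: Rule, signatures: SignatureSet) -> list[Violation]:
    """Check a rule against signatures; empty error list means the rule is sound.

    Flags (as errors) unknown agents/sites/states, dangling bond labels,
    incoherent lhs/rhs correspondence, and ring formation: a rule must not bind
    two sites that already lie in the same connected component of its own
    left-hand side (closed rings are not representable in the target models and
    make molecularity ambiguous).  A rule whose two sides are identical is
    accepted but flagged with a warning (no-op).
    """
    out: list[Violation] = []
    for side_name, side in (("lhs", rule.lhs), ("rhs", rule.rhs)):
        for msg in side.validate(signatures):
            out.append(Violation("error", f"{rule.name} {side_name}: {msg}"))
    if any(v.severity == "error" for v in out):
        return out

    n_keep = min(len(rule.lhs.agents), len(rule.rhs.agents))
    for i in range(n_keep):
        la, ra = rule.lhs.agents[i], rule.rhs.agents[i]
        if la.name != ra.name:
            out.append(
                Violation(
                    "error",
                    f"{rule.name}: agent {i} changes type {la.name} -> {ra.name}; "
                    "use degradation + synthesis instead",
                )
            )
            continue
        if set(la.site_names()) != set(ra.site_names()):
            out.append(
                Violation(
                    "error",
                    f"{rule.name}: agent {i} ({la.name}) mentions different sites "
                    "on the two sides",
                )
            )
    # synthesized agents must be fully specified
    sig_ok = True
    for i in range(n_keep, len(rule.rhs.agents)):
        ap = rule.rhs.agents[i]
        sig = signatures[ap.name]
        mentioned = set(ap.site_names())
        if mentioned != set(sig.sites):
            out.append(
                Violation(
                    "error",
                    f"{rule.name}: synthesized agent {ap.name} must specify all sites",
                )
            )
            sig_ok = False
        for sp in ap.sites:
            if sig.states(sp.site) and sp.internal is None:
                out.append(
                    Violation(
                        "error",
                        f"{rule.name}: synthesized agent {ap.name}.{sp.site} "
                        "needs an internal state",
                    )
                )
                sig_ok = False
    if not sig_ok or any(v.severity == "error" for v in out):
        return out

    # ring formation: a bond created on the rhs whose two endpoints belong to
    # the same lhs connected component (or the same agent).
    lhs_comp_of: dict[int, int] = {}
    for ci, comp in enumerate(rule.lhs.components()):
        for i in comp:
            lhs_comp_of[i] = ci
    lhs_bonds = {
        frozenset(map(tuple, ends)) for ends in rule.lhs.bond_endpoints().values()
    }
    for label, ends in rule.rhs.bond_endpoints().items():
        key = frozenset(map(tuple, ends))
        if key in lhs_bonds:
            continue  # bond preserved, not created
        (i, si), (j, sj) = ends
        if i >= n_keep or j >= n_keep:
            continue  # bond involving a synthesized agent cannot close a ring
        if i == j:
            out.append(
                Violation(
                    "error",
                    f"{rule.name}: bond {label} ties two sites of one agent "
                    "(ring formation)",
                )
            )
        elif lhs_comp_of.get(i) == lhs_comp_of.get(j):
            out.append(
                Violation(
                    "error",
                    f"{rule.name}: bond {label} joins agents already connected "
                    "on the lhs (ring formation)",
                )
            )
    if rule.lhs == rule.rhs:
        out.append(Violation("warning", f"{rule.name}: lhs equals rhs (no-op rule)"))
    return out


def rule_errors(violations: Iterable[Violation]) -> list[Violation]:
    return [v for v in violations if v.severity == "error"]


# identifier used by parsers and builders
IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_\-+*']*")
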
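r"""Reader and writer for a restricted Kappa-like model text format.

This dialect covers agent signatures, rules, initial copies, pattern
observables, timed perturbation directives and the snapshot period.  It is a
small, documented subset of its own — not claimed compatible with any KaSim
release (no tokens, counters, algebraic rates or hybrid rules).

Grammar (EBNF; ``#`` starts a comment, blank lines ignored)::

    model      = { line } ;
    line       = signature | init | obs | event | snapshot | rule ;
    signature  = "%agent:" agent-decl ;
    agent-decl = NAME "(" [ site-decl { "," site-decl } ] ")" ;
    site-decl  = NAME { "~" NAME } ;                (* states listed inline *)
    init       = "%init:" INT pattern ;
    obs        = ("%obs:" | "%obs-species:") "'" NAME "'" pattern ;
    event      = "%event:" FLOAT ( "add" INT pattern
                                 | "set" INT pattern
                                 | "rate" NAME FLOAT ) ;
    snapshot   = "%snapshot_period:" INT ;
    rule       = "'" NAME "'" pattern "->" pattern "@" FLOAT [ "{" NAME "}" ] ;
    pattern    = [ agent { "," agent } ] ;
    agent      = NAME "(" [ site { "," site } ] ")" ;
    site       = NAME [ "~" NAME ] [ binding ] ;
    binding    = "!" ( INT | "_" | NAME "." NAME ) | "?" ;

Site binding shorthand: a bare site is **free**; ``x!1`` carries bond label 1;
``x!_`` is bound to an unspecified partner; ``x!s.B`` is bound to site ``s`` of
some agent ``B`` outside the pattern; ``x?`` leaves the binding state
unspecified.  An omitted site is fully unspecified (decontextualised).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

from .core import (
    BOUND_ANY,
    FREE,
    UNSPEC,
    AgentPattern,
    AgentSignature,
    BoundTo,
    ComplexPattern,
    Rule,
    SignatureSet,
    SiteGraph,
    SitePattern,
)
from .model import (
    AddCopies,
    Event,
    EventSchedule,
    ModelDefinition,
    PatternObservable,
    SetCopies,
    SetRate,
)

__all__ = [
    "parse_pattern",
    "pattern_to_graph",
    "graph_to_pattern",
    "format_pattern",
    "parse_rule_line",
    "format_rule",
    "normalize_rule",
    "read_kappa",
    "write_kappa",
    "KappaSyntaxError",
]


class KappaSyntaxError(ValueError):
    pass


_NAME = r"[A-Za-z_][A-Za-z0-9_'+]*"
_AGENT_RE = re.compile(rf"\s*({_NAME})\s*\(([^()]*)\)\s*")
_SITE_RE = re.compile(
    rf"^({_NAME})(?:~({_NAME}))?(?:!(\d+|_|{_NAME}\.{_NAME})|(\?))?$"
)


def _split_top(text: str) -> list[str]:
    """Split a pattern expression on commas that separate agents (i.e. commas
    outside parentheses)."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if cur:
        parts.append("".join(cur))
    return [p.strip() for p in parts if p.strip()]


def parse_pattern(text: str) -> ComplexPattern:
    """Parse a (possibly empty, possibly disconnected) complex pattern."""
    text = text.strip()
    if not text or text == ".":
        return ComplexPattern(())
    agents = []
    for chunk in _split_top(text):
        m = _AGENT_RE.fullmatch(chunk)
        if not m:
            raise KappaSyntaxError(f"cannot parse agent expression {chunk!r}")
        name, inner = m.group(1), m.group(2).strip()
        sites = []
        if inner:
            for stext in (s.strip() for s in inner.split(",")):
                sm = _SITE_RE.match(stext)
                if not sm:
                    raise KappaSyntaxError(f"cannot parse site expression {stext!r}")
                sname, state, bind, quest = sm.groups()
                if quest:
                    binding = UNSPEC
                elif bind is None:
                    binding = FREE
                elif bind == "_":
                    binding = BOUND_ANY
                elif bind.isdigit():
                    binding = int(bind)
                else:
                    psite, pagent = bind.split(".")
                    binding = BoundTo(pagent, psite)
                sites.append(SitePattern(sname, state, binding))
        agents.append(AgentPattern(name, tuple(sites)))
    return ComplexPattern(tuple(agents))


def _format_site(sp: SitePattern) -> str:
    out = sp.site
    if sp.internal is not None:
        out += f"~{sp.internal}"
    b = sp.binding
    if b == UNSPEC:
        out += "?"
    elif b == BOUND_ANY:
        out += "!_"
    elif isinstance(b, int):
        out += f"!{b}"
    elif isinstance(b, BoundTo):
        out += f"!{b.site}.{b.agent}"
    # FREE: no marker
    return out


def format_pattern(cp: ComplexPattern) -> str:
    if not cp.agents:
        return "."
    return ",".join(
        f"{ap.name}({','.join(_format_site(sp) for sp in ap.sites)})"
        for ap in cp.agents
    )


def _relabel_bonds(cp: ComplexPattern) -> ComplexPattern:
    """Renumber bond labels 1.. in order of first appearance."""
    mapping: dict[int, int] = {}
    agents = []
    for ap in cp.agents:
        sites = []
        for sp in ap.sites:
            if isinstance(sp.binding, int):
                if sp.binding not in mapping:
                    mapping[sp.binding] = len(mapping) + 1
                sp = SitePattern(sp.site, sp.internal, mapping[sp.binding])
            sites.append(sp)
        agents.append(AgentPattern(ap.name, tuple(sites)))
    return ComplexPattern(tuple(agents))


def normalize_rule(rule: Rule) -> Rule:
    """Canonical textual form of a rule: bond labels renumbered by first
    appearance on each side."""
    return Rule(
        rule.name, _relabel_bonds(rule.lhs), _relabel_bonds(rule.rhs), rule.rate, rule.rate_id
    )


_RULE_RE = re.compile(
    r"^'([^']+)'\s*(.*?)\s*->\s*(.*?)\s*@\s*([-+0-9.eE]+)\s*(?:\{(\S+)\})?\s*$"
)


def parse_rule_line(line: str) -> Rule:
    m = _RULE_RE.match(line.strip())
    if not m:
        raise KappaSyntaxError(f"cannot parse rule line {line!r}")
    name, lhs, rhs, rate, rate_id = m.groups()
    return Rule(name, parse_pattern(lhs), parse_pattern(rhs), float(rate), rate_id)


def format_rule(rule: Rule) -> str:
    rule = normalize_rule(rule)
    tail = f" {{{rule.rate_id}}}" if rule.rate_id else ""
    return (
        f"'{rule.name}' {format_pattern(rule.lhs)} -> "
        f"{format_pattern(rule.rhs)} @ {rule.rate!r}{tail}"
    )


# ---------------------------------------------------------------------------
# Concrete graphs from pattern expressions
# ---------------------------------------------------------------------------


def pattern_to_graph(
    cp: ComplexPattern,
    signatures: SignatureSet,
    fill_defaults: bool = True,
) -> SiteGraph:
    """Materialize a pattern as a concrete site-graph.

    With ``fill_defaults`` every unmentioned site becomes free, stateful sites
    take the first declared state (the convention for initial-condition
    expressions); otherwise any unspecified field is an error.
    """
    agents, states, bonds = [], [], {}
    half_bonds: dict[int, tuple[int, str]] = {}
    for i, ap in enumerate(cp.agents):
        if ap.name not in signatures:
            raise ValueError(f"unknown agent {ap.name!r}")
        sig = signatures[ap.name]
        agents.append(ap.name)
        smap: dict[str, Optional[str]] = {}
        mentioned = {sp.site: sp for sp in ap.sites}
        for site in sig.sites:
            declared = sig.states(site)
            sp = mentioned.get(site)
            if sp is None:
                if not fill_defaults:
                    raise ValueError(f"site {ap.name}.{site} unspecified")
                smap[site] = declared[0] if declared else None
                continue
            if declared:
                if sp.internal is None:
                    if not fill_defaults:
                        raise ValueError(f"state of {ap.name}.{site} unspecified")
                    smap[site] = declared[0]
                else:
                    smap[site] = sp.internal
            else:
                if sp.internal is not None:
                    raise ValueError(f"site {ap.name}.{site} carries no internal state")
                smap[site] = None
            b = sp.binding
            if isinstance(b, int):
                if b in half_bonds:
                    j, jsite = half_bonds.pop(b)
                    bonds[(i, site)] = (j, jsite)
                else:
                    half_bonds[b] = (i, site)
            elif b in (BOUND_ANY, UNSPEC) or isinstance(b, BoundTo):
                if b == UNSPEC and fill_defaults:
                    pass  # defaults to free
                else:
                    raise ValueError(
                        f"binding of {ap.name}.{site} not concrete in graph expression"
                    )
        states.append(smap)
    if half_bonds:
        raise ValueError(f"dangling bond labels {sorted(half_bonds)}")
    return SiteGraph(agents, states, bonds)


def graph_to_pattern(g: SiteGraph) -> ComplexPattern:
    """Exact pattern form of a concrete graph (all sites mentioned)."""
    labels: dict[frozenset, int] = {}
    agents = []
    for i in range(len(g)):
        sites = []
        for site in sorted(g.states[i]):
            bond = g.bonds.get((i, site))
            if bond is None:
                binding = FREE
            else:
                key = frozenset({(i, site), bond})
                if key not in labels:
                    labels[key] = len(labels) + 1
                binding = labels[key]
            sites.append(SitePattern(site, g.states[i][site], binding))
        agents.append(AgentPattern(g.agents[i], tuple(sites)))
    return ComplexPattern(tuple(agents))


# ---------------------------------------------------------------------------
# Model files
# ---------------------------------------------------------------------------


def _parse_signature(decl: str) -> AgentSignature:
    m = _AGENT_RE.fullmatch(decl.strip())
    if not m:
        raise KappaSyntaxError(f"cannot parse agent declaration {decl!r}")
    name, inner = m.group(1), m.group(2).strip()
    sites, internal = [], {}
    if inner:
        for stext in (s.strip() for s in inner.split(",")):
            parts = stext.split("~")
            sites.append(parts[0])
            if len(parts) > 1:
                internal[parts[0]] = tuple(parts[1:])
    return AgentSignature(name, tuple(sites), internal)


def read_kappa(source: Union[str, Path]) -> ModelDefinition:
    """Read a model file (path or literal text) into a :class:`ModelDefinition`."""
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
        name = Path(source).stem
    else:
        text = str(source)
        name = "model"

    signatures: list[AgentSignature] = []
    rules: list[Rule] = []
    raw_inits: list[tuple[int, str]] = []
    observables: list[PatternObservable] = []
    events: list[Event] = []
    snapshot_period: Optional[int] = None

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            if line.startswith("%agent:"):
                signatures.append(_parse_signature(line[len("%agent:"):]))
            elif line.startswith("%init:"):
                rest = line[len("%init:"):].strip()
                n_str, expr = rest.split(None, 1)
                raw_inits.append((int(n_str), expr))
            elif line.startswith("%obs-species:") or line.startswith("%obs:"):
                mode = "species-copies" if line.startswith("%obs-species:") else "agent-instances"
                rest = line.split(":", 1)[1].strip()
                m = re.match(r"^'([^']+)'\s*(.*)$", rest)
                if not m:
                    raise KappaSyntaxError("observable needs a quoted name")
                observables.append(
                    PatternObservable(m.group(1), parse_pattern(m.group(2)), mode)
                )
            elif line.startswith("%event:"):
                toks = line[len("%event:"):].split(None, 2)
                t, kind, rest = float(toks[0]), toks[1], toks[2]
                if kind in ("add", "set"):
                    n_str, expr = rest.split(None, 1)
                    action_cls = AddCopies if kind == "add" else SetCopies
                    events.append(Event(t, action_cls(expr.strip(), int(n_str))))
                elif kind == "rate":
                    rid, val = rest.split()
                    events.append(Event(t, SetRate(rid, float(val))))
                else:
                    raise KappaSyntaxError(f"unknown event kind {kind!r}")
            elif line.startswith("%snapshot_period:"):
                snapshot_period = int(line.split(":", 1)[1])
            elif line.startswith("%"):
                raise KappaSyntaxError(f"unknown directive {line.split(':')[0]!r}")
            else:
                rules.append(parse_rule_line(line))
        except (KappaSyntaxError, ValueError) as exc:
            raise KappaSyntaxError(f"line {lineno}: {exc}") from exc

    sigset = SignatureSet(signatures)
    init = [
        (n, pattern_to_graph(parse_pattern(expr), sigset)) for n, expr in raw_inits
    ]
    events.sort(key=lambda e: e.time)
    return ModelDefinition(
        signatures=sigset,
        rules=rules,
        init=init,
        observables=observables,
        events=EventSchedule(events),
        snapshot_period=snapshot_period,
        name=name,
    )


def write_kappa(model: ModelDefinition) -> str:
    lines = [f"# model: {model.name}"]
    for sig in model.signatures:
        decls = []
        for site in sig.sites:
            tok = site
            for st in sig.states(site):
                tok += f"~{st}"
            decls.append(tok)
        lines.append(f"%agent: {sig.name}({','.join(decls)})")
    for rule in model.rules:
        lines.append(format_rule(rule))
    for n, graph in model.init:
        lines.append(f"%init: {n} {format_pattern(graph_to_pattern(graph))}")
    for obs in model.observables:
        directive = "%obs-species:" if obs.mode == "species-copies" else "%obs:"
        lines.append(f"{directive} '{obs.name}' {format_pattern(obs.pattern)}")
    for ev in model.events:
        a = ev.action
        if isinstance(a, AddCopies):
            lines.append(f"%event: {ev.time!r} add {a.n} {a.species}")
        elif isinstance(a, SetCopies):
            lines.append(f"%event: {ev.time!r} set {a.n} {a.species}")
        else:
            lines.append(f"%event: {ev.time!r} rate {a.rate_id} {a.value!r}")
    if model.snapshot_period is not None:
        lines.append(f"%snapshot_period: {model.snapshot_period}")
    return "\n".join(lines) + "\n"
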
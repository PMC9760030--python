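"""Synthetic model generator: small systems with known analytic behaviour or
brute-forceable structure, used to exercise every engine feature without any
external model files.

Every analytic expectation carried by a toy is documented with its derivation
in the ``expectations`` mapping (value or callable plus a ``doc`` string).
Recorded simulation output is never used as a test substrate — fixtures are
regenerated programmatically; golden files exist only for format round-trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .combinatorics import BindingStep, MultisiteScheme, expand_multisite_binding, scheme_signatures
from .core import (
    AgentSignature,
    Mixture,
    Reaction,
    Rule,
    SignatureSet,
    Species,
)
from .kappa_io import parse_pattern, parse_rule_line, pattern_to_graph
from .model import ModelDefinition, PatternObservable

__all__ = ["ToyModel", "make_toy", "make_random_rule_system"]


@dataclass
class ToyModel:
    """A self-contained model plus its documented expectations.

    ``expectations`` maps a quantity name to ``(value_or_callable, doc)``;
    callables take simulation time in seconds.
    """

    name: str
    model: ModelDefinition
    expectations: dict[str, tuple[Union[float, Callable], str]] = field(
        default_factory=dict
    )
    reactions: Optional[list[Reaction]] = None  # for condensation fixtures

    def seed_species(self) -> list[Species]:
        return [
            Species.from_graph(g, self.model.signatures) for _, g in self.model.init
        ]

    def init_mixture(self) -> Mixture:
        mix = Mixture()
        for n, g in self.model.init:
            mix.add(Species.from_graph(g, self.model.signatures), n)
        return mix


def _model(sig_decls, rule_lines, inits, obs=(), name="toy") -> ModelDefinition:
    sigs = SignatureSet(sig_decls)
    rules = [parse_rule_line(line) for line in rule_lines]
    init = [
        (n, pattern_to_graph(parse_pattern(expr), sigs)) for n, expr in inits
    ]
    observables = [PatternObservable(n, parse_pattern(p)) for n, p in obs]
    return ModelDefinition(sigs, rules, init, observables, name=name)


def make_toy(name: str, **params) -> ToyModel:
    """Built-in toys:

    - ``decay``: A -> 0 at rate k; mean A(t) = A0 exp(-k t).
    - ``birth_death``: 0 -> X at b, X -> 0 at d; stationary law Poisson(b/d),
      so mean = variance = b/d.
    - ``dimerisation``: A + B <-> AB; the equilibrium copy number solves the
      mass-action quadratic kon (A0-x)(B0-x) = koff x.
    - ``multisite``: a multisite binding ladder (defaults reproduce the
      4-site, two-step calcium activation scheme).
    - ``phospho_spectator``: two phosphorylation reactions identical except a
      spectator phosphosite — the minimal condensation fixture.
    """
    if name == "decay":
        k = params.get("k", 0.1)
        a0 = params.get("a0", 1000)
        toy = ToyModel(
            name,
            _model(
                [AgentSignature("A", ())],
                [f"'decay' A() -> . @ {k!r} {{k_decay}}"],
                [(a0, "A()")],
                obs=[("A", "A()")],
                name="decay",
            ),
        )
        toy.expectations["mean_A"] = (
            lambda t, a0=a0, k=k: a0 * math.exp(-k * t),
            "first-order decay: E[A(t)] = A0 exp(-k t)",
        )
        return toy

    if name == "birth_death":
        b = params.get("b", 10.0)
        d = params.get("d", 0.1)
        x0 = params.get("x0", 0)
        toy = ToyModel(
            name,
            _model(
                [AgentSignature("X", ())],
                [
                    f"'birth' . -> X() @ {b!r} {{k_birth}}",
                    f"'death' X() -> . @ {d!r} {{k_death}}",
                ],
                [(x0, "X()")],
                obs=[("X", "X()")],
                name="birth_death",
            ),
        )
        toy.expectations["stationary_mean"] = (
            b / d,
            "immigration-death (M/M/inf) stationary law is Poisson(b/d)",
        )
        toy.expectations["stationary_variance"] = (
            b / d,
            "Poisson stationary law: variance equals mean",
        )
        return toy

    if name == "dimerisation":
        kon = params.get("kon", 0.001)
        koff = params.get("koff", 0.1)
        a0 = params.get("a0", 100)
        b0 = params.get("b0", 80)
        toy = ToyModel(
            name,
            _model(
                [AgentSignature("A", ("x",)), AgentSignature("B", ("y",))],
                [
                    f"'bind' A(x),B(y) -> A(x!1),B(y!1) @ {kon!r} {{kon}}",
                    f"'unbind' A(x!1),B(y!1) -> A(x),B(y) @ {koff!r} {{koff}}",
                ],
                [(a0, "A(x)"), (b0, "B(y)")],
                obs=[("AB", "A(x!1),B(y!1)"), ("A_free", "A(x)"), ("B_free", "B(y)")],
                name="dimerisation",
            ),
        )
        # kon (a0-x)(b0-x) = koff x  ->  kon x^2 - (kon(a0+b0)+koff) x + kon a0 b0 = 0
        p = kon
        q = -(kon * (a0 + b0) + koff)
        r = kon * a0 * b0
        x_eq = (-q - math.sqrt(q * q - 4 * p * r)) / (2 * p)
        toy.expectations["equilibrium_AB"] = (
            x_eq,
            "smaller root of the mass-action equilibrium quadratic "
            "kon(A0-x)(B0-x) = koff x",
        )
        return toy

    if name == "multisite":
        n = params.get("n", 4)
        steps = params.get("steps", ((2, 1.0e-4, 0.5), (2, 2.0e-4, 0.25)))
        target = params.get("target", "T")
        ligand = params.get("ligand", "L")
        n_target = params.get("n_target", 100)
        n_ligand = params.get("n_ligand", 1000)
        scheme = MultisiteScheme(
            target,
            n,
            ligand,
            tuple(BindingStep(*s) for s in steps),
        )
        sigs = scheme_signatures(scheme)
        rules = expand_multisite_binding(scheme)
        sigset = SignatureSet(sigs)
        free_target = ",".join(scheme.site_names())
        init = [
            (n_target, pattern_to_graph(parse_pattern(f"{target}({free_target})"), sigset)),
            (n_ligand, pattern_to_graph(parse_pattern(f"{ligand}(b)"), sigset)),
        ]
        model = ModelDefinition(sigset, rules, init, [], name="multisite")
        toy = ToyModel(name, model)
        levels = scheme.occupancy_levels()
        toy.expectations["n_rules"] = (
            float(len(rules)),
            "one forward + one reverse rule per (entry occupancy state, step "
            "subset); for the 4-site two-ion scheme this is 24",
        )
        toy.expectations["n_target_species"] = (
            float(sum(math.comb(n, k) for k in levels)),
            "C(n, k) occupancy variants per reachable level k",
        )
        return toy

    if name == "phospho_spectator":
        k1 = params.get("k1", 0.3)
        k2 = params.get("k2", k1 if params.get("equal_rates", True) else 0.7)
        sigs = SignatureSet(
            [AgentSignature("D", ("t", "s"), {"t": ("u", "p"), "s": ("u", "p")})]
        )

        def sp(expr: str) -> Species:
            return Species.from_graph(pattern_to_graph(parse_pattern(expr), sigs), sigs)

        reactions = [
            Reaction(
                (sp("D(t~u,s~u)"),),
                (sp("D(t~p,s~u)"),),
                k1,
                "k1",
                "phos_spectator_u",
                "phosphorylation",
            ),
            Reaction(
                (sp("D(t~u,s~p)"),),
                (sp("D(t~p,s~p)"),),
                k2,
                "k1" if k1 == k2 else "k2",
                "phos_spectator_p",
                "phosphorylation",
            ),
        ]
        model = ModelDefinition(
            sigs,
            [],
            [(100, pattern_to_graph(parse_pattern("D(t~u,s~u)"), sigs)),
             (100, pattern_to_graph(parse_pattern("D(t~u,s~p)"), sigs))],
            name="phospho_spectator",
        )
        toy = ToyModel(name, model, reactions=reactions)
        toy.expectations["n_rules_after_condensation"] = (
            1.0 if k1 == k2 else 2.0,
            "spectator-state pair condenses to one rule iff rates are equal",
        )
        return toy

    raise ValueError(f"unknown toy model {name!r}")


# ---------------------------------------------------------------------------
# Random rule systems (property-test substrate)
# ---------------------------------------------------------------------------


def make_random_rule_system(
    seed: int,
    n_agents: int = 3,
    n_rules: int = 4,
    max_sites: int = 2,
    species_cap: int = 500,
) -> ToyModel:
    """Reproducible pseudo-random rule system with guaranteed-finite closure.

    Binding rules are drawn so the (agent type, site) bond graph stays acyclic
    and each site appears in at most one binding rule, which bounds every
    reachable complex by the number of agent types; state-flip and unbinding
    rules are unrestricted.  Generated rules are validator-clean by
    construction (no ring formation).
    """
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_agents)]
    sigs = []
    site_names: dict[str, list[str]] = {}
    stateful: dict[tuple[str, str], tuple[str, ...]] = {}
    for nm in names:
        k = int(rng.integers(1, max_sites + 1))
        sites = tuple(f"s{j}" for j in range(k))
        site_names[nm] = list(sites)
        internal = {}
        for s in sites:
            if rng.random() < 0.5:
                internal[s] = ("u", "p")
                stateful[(nm, s)] = ("u", "p")
        sigs.append(AgentSignature(nm, sites, internal))
    sigset = SignatureSet(sigs)

    # candidate bond endpoints; forest constraint over agent types
    endpoints = [(nm, s) for nm in names for s in site_names[nm]]
    parent = {nm: nm for nm in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used_sites: set[tuple[str, str]] = set()
    bind_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = []
    order = rng.permutation(len(endpoints))
    for _ in range(2 * n_rules):
        if len(bind_pairs) >= n_rules:
            break
        i, j = rng.integers(0, len(endpoints), size=2)
        a, b = endpoints[int(i)], endpoints[int(j)]
        if a == b or a in used_sites or b in used_sites:
            continue
        if a[0] == b[0] or find(a[0]) == find(b[0]):
            continue  # keep the type graph acyclic (finite complexes)
        parent[find(a[0])] = find(b[0])
        used_sites.add(a)
        used_sites.add(b)
        bind_pairs.append((a, b))

    rules: list[Rule] = []
    k = 0
    while len(rules) < n_rules:
        kind = rng.choice(["bind", "unbind", "flip"])
        if kind in ("bind", "unbind") and bind_pairs:
            (an, asite), (bn, bsite) = bind_pairs[int(rng.integers(len(bind_pairs)))]
            rate = float(np.round(rng.uniform(0.01, 1.0), 3))
            if kind == "bind":
                line = (
                    f"'r{k}_bind' {an}({asite}),{bn}({bsite}) -> "
                    f"{an}({asite}!1),{bn}({bsite}!1) @ {rate!r} {{k{k}}}"
                )
            else:
                line = (
                    f"'r{k}_unbind' {an}({asite}!1),{bn}({bsite}!1) -> "
                    f"{an}({asite}),{bn}({bsite}) @ {rate!r} {{k{k}}}"
                )
            rules.append(parse_rule_line(line))
            k += 1
        elif kind == "flip" and stateful:
            keys = sorted(stateful)
            nm, s = keys[int(rng.integers(len(keys)))]
            frm, to = ("u", "p") if rng.random() < 0.5 else ("p", "u")
            rate = float(np.round(rng.uniform(0.01, 1.0), 3))
            rules.append(
                parse_rule_line(
                    f"'r{k}_flip' {nm}({s}~{frm}?) -> {nm}({s}~{to}?) @ {rate!r} {{k{k}}}"
                )
            )
            k += 1
        elif not bind_pairs and not stateful:  # pragma: no cover
            break

    init = []
    for nm in names:
        expr = nm + "(" + ",".join(site_names[nm]) + ")"
        init.append((int(rng.integers(5, 20)), pattern_to_graph(parse_pattern(expr), sigset)))
    model = ModelDefinition(sigset, rules, init, name=f"random_{seed}")
    return ToyModel(f"random_{seed}", model)
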
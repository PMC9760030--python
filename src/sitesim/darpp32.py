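"""The DARPP-32 signalling model library.

DARPP-32 (PPP1R1B) integrates dopaminergic (cAMP–PKA) and glutamatergic
(Ca²⁺–PP2B) input in striatal medium spiny neurons through three
phosphosites: Thr34 (phosphorylated by PKA, dephosphorylated by the
calcium-activated phosphatase PP2B/calcineurin), Thr75 (CDK5 / PP2A) and
Ser137 (CK1 / PP2C).  This module builds the rule-based network in its
variants:

* **mutation** — ``wild``; ``ser137ala`` (Ser137 cannot be phosphorylated:
  the single CK1 catalytic rule on Ser137 is zeroed); ``constser137``
  (Ser137 permanently phosphorylated: the single PP2C dephosphorylation
  rule is zeroed).  Each mutation is one rate-constant change.
* **binding** — ``oBS`` (competitive: one DARPP-32 partner site, one
  interactor at a time); ``tBS`` (noncompetitive: three independent partner
  sites, one per phosphosite's enzyme pair).  Both variants have the same
  number of rules; only the DARPP-32 signature differs.

The model is organised in eight components (DARPP-32 phosphorylation; CK1,
PDE and PP2A phosphorylation; PP2B activation; PKA activation; cAMP & Ca²⁺
degradation; PP2A activation by Ca²⁺).  PP2B and PKA activation use the
combinatorial-binding encoding: four uniquely named ligand sites filled in
two reversible two-molecule steps.

Rate values, initial copy numbers and the stimulus protocol are data, not
code: they load from a packaged parameter table (synthetic defaults) or can
be taken from a translated SBML model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .combinatorics import BindingStep, MultisiteScheme, expand_multisite_binding
from .core import AgentSignature, Rule, SignatureSet, UnitContext
from .engine import ReactionNetwork
from .kappa_io import parse_pattern, parse_rule_line, pattern_to_graph
from .model import AddCopies, Event, EventSchedule, ModelDefinition, PatternObservable
from .sbml_io import SBMLImport, read_sbml

__all__ = [
    "ModelVariant",
    "COMPONENTS",
    "load_default_params",
    "build_model",
    "component_of_rule",
    "import_sbml",
    "aggregate_by_name",
]

MUTATIONS = ("wild", "ser137ala", "constser137")
BINDINGS = ("oBS", "tBS")

COMPONENTS = (
    "DARPP-32 phosphorylation",
    "CK1 phosphorylation",
    "PDE phosphorylation",
    "PP2A phosphorylation",
    "PP2B activation",
    "PKA activation",
    "cAMP & Ca degradation",
    "PP2A activation by Ca",
)

# the single rule zeroed by each in-silico mutation
MUTATION_RULE = {
    "ser137ala": "ck1_d_cat",  # Ser137 can no longer be phosphorylated
    "constser137": "pp2c_d_cat",  # Ser137 can no longer be dephosphorylated
}


@dataclass(frozen=True)
class ModelVariant:
    mutation: str = "wild"
    binding: str = "oBS"

    def __post_init__(self) -> None:
        if self.mutation not in MUTATIONS:
            raise ValueError(f"mutation must be one of {MUTATIONS}")
        if self.binding not in BINDINGS:
            raise ValueError(f"binding must be one of {BINDINGS}")


def load_default_params() -> dict:
    text = resources.files("sitesim").joinpath("_data/darpp32_params.yaml").read_text()
    return yaml.safe_load(text)


def _signatures(binding: str) -> SignatureSet:
    d_sites: tuple[str, ...]
    if binding == "oBS":
        d_sites = ("b",)
    else:
        d_sites = ("b1", "b2", "b3")
    return SignatureSet(
        [
            AgentSignature(
                "D",
                ("t34", "t75", "s137") + d_sites,
                {"t34": ("u", "p"), "t75": ("u", "p"), "s137": ("u", "p")},
            ),
            AgentSignature("PKAc", ("b",)),
            AgentSignature("R2C2", ("cam1", "cam2", "cam3", "cam4", "c1", "c2")),
            AgentSignature("cAMP", ("b",)),
            AgentSignature("Ca", ("b",)),
            AgentSignature("PP2B", ("ca1", "ca2", "ca3", "ca4", "b")),
            AgentSignature("CDK5", ("b",)),
            AgentSignature("CK1", ("b", "s"), {"s": ("u", "p")}),
            AgentSignature("PP2A", ("b", "ca", "s"), {"s": ("u", "p")}),
            AgentSignature("PP2C", ("b",)),
            AgentSignature("PDE", ("b", "s"), {"s": ("u", "p")}),
        ]
    )


# enzyme -> (phosphosite, from-state, to-state, tBS site on D, activity context)
_D_ENZYMES = (
    ("PKAc", "t34", "u", "p", "b1", ""),
    ("PP2B", "t34", "p", "u", "b1", "ca1!_,ca2!_,ca3!_,ca4!_,"),
    ("CDK5", "t75", "u", "p", "b2", ""),
    ("PP2A", "t75", "p", "u", "b2", "ca!_,"),
    ("CK1", "s137", "u", "p", "b3", "s~u,"),
    ("PP2C", "s137", "p", "u", "b3", ""),
)


def _d_phospho_rules(binding: str) -> list[tuple[str, str, str]]:
    """(rule text, rate_id, component) for the DARPP-32 phosphorylation
    component: bind / catalyse+release / unbind per enzyme."""
    out = []
    for enz, site, frm, to, tbs_site, ctx in _D_ENZYMES:
        dsite = "b" if binding == "oBS" else tbs_site
        pref = enz.lower().replace("pkac", "pka")
        rid_bind = f"{pref}_d_bind"
        rid_cat = f"{pref}_d_cat"
        rid_unb = f"{pref}_d_unbind"
        out.append(
            (
                f"'{enz}_D_{site}_bind' {enz}({ctx}b),D({site}~{frm},{dsite}) -> "
                f"{enz}({ctx}b!1),D({site}~{frm},{dsite}!1) @ 0 {{{rid_bind}}}",
                rid_bind,
                "DARPP-32 phosphorylation",
            )
        )
        out.append(
            (
                f"'{enz}_D_{site}_cat' {enz}(b!1),D({site}~{frm},{dsite}!1) -> "
                f"{enz}(b),D({site}~{to},{dsite}) @ 0 {{{rid_cat}}}",
                rid_cat,
                "DARPP-32 phosphorylation",
            )
        )
        out.append(
            (
                f"'{enz}_D_{site}_unbind' {enz}(b!1),D({site}~{frm},{dsite}!1) -> "
                f"{enz}(b),D({site}~{frm},{dsite}) @ 0 {{{rid_unb}}}",
                rid_unb,
                "DARPP-32 phosphorylation",
            )
        )
    return out


def _fixed_rules() -> list[tuple[str, str, str]]:
    """Rule templates independent of the binding variant."""
    ck1 = [
        ("'CK1_auto' CK1(s~u,b) -> CK1(s~p,b) @ 0 {ck1_auto}", "ck1_auto"),
        (
            "'PP2B_CK1_bind' PP2B(ca1!_,ca2!_,ca3!_,ca4!_,b),CK1(b,s~p) -> "
            "PP2B(ca1!_,ca2!_,ca3!_,ca4!_,b!1),CK1(b!1,s~p) @ 0 {pp2b_ck1_bind}",
            "pp2b_ck1_bind",
        ),
        (
            "'PP2B_CK1_cat' PP2B(b!1),CK1(b!1,s~p) -> PP2B(b),CK1(b,s~u) @ 0 "
            "{pp2b_ck1_cat}",
            "pp2b_ck1_cat",
        ),
        (
            "'PP2B_CK1_unbind' PP2B(b!1),CK1(b!1,s~p) -> PP2B(b),CK1(b,s~p) @ 0 "
            "{pp2b_ck1_unbind}",
            "pp2b_ck1_unbind",
        ),
    ]
    pde = [
        (
            "'PKAc_PDE_bind' PKAc(b),PDE(b,s~u) -> PKAc(b!1),PDE(b!1,s~u) @ 0 "
            "{pka_pde_bind}",
            "pka_pde_bind",
        ),
        (
            "'PKAc_PDE_cat' PKAc(b!1),PDE(b!1,s~u) -> PKAc(b),PDE(b,s~p) @ 0 "
            "{pka_pde_cat}",
            "pka_pde_cat",
        ),
        (
            "'PKAc_PDE_unbind' PKAc(b!1),PDE(b!1,s~u) -> PKAc(b),PDE(b,s~u) @ 0 "
            "{pka_pde_unbind}",
            "pka_pde_unbind",
        ),
        ("'PDE_dephos' PDE(s~p) -> PDE(s~u) @ 0 {pde_dephos}", "pde_dephos"),
    ]
    pp2a = [
        (
            "'PKAc_PP2A_bind' PKAc(b),PP2A(b,s~u) -> PKAc(b!1),PP2A(b!1,s~u) @ 0 "
            "{pka_pp2a_bind}",
            "pka_pp2a_bind",
        ),
        (
            "'PKAc_PP2A_cat' PKAc(b!1),PP2A(b!1,s~u) -> PKAc(b),PP2A(b,s~p) @ 0 "
            "{pka_pp2a_cat}",
            "pka_pp2a_cat",
        ),
        (
            "'PKAc_PP2A_unbind' PKAc(b!1),PP2A(b!1,s~u) -> PKAc(b),PP2A(b,s~u) @ 0 "
            "{pka_pp2a_unbind}",
            "pka_pp2a_unbind",
        ),
        ("'PP2A_dephos' PP2A(s~p) -> PP2A(s~u) @ 0 {pp2a_dephos}", "pp2a_dephos"),
    ]
    pka_release = [
        (
            "'PKA_release_c1' R2C2(cam1!_,cam2!_,cam3!_,cam4!_,c1!1),PKAc(b!1) -> "
            "R2C2(cam1!_,cam2!_,cam3!_,cam4!_,c1),PKAc(b) @ 0 {pka_release}",
            "pka_release",
        ),
        (
            "'PKA_release_c2' R2C2(cam1!_,cam2!_,cam3!_,cam4!_,c2!1),PKAc(b!1) -> "
            "R2C2(cam1!_,cam2!_,cam3!_,cam4!_,c2),PKAc(b) @ 0 {pka_release}",
            "pka_release",
        ),
        (
            "'PKA_rebind_c1' R2C2(c1),PKAc(b) -> R2C2(c1!1),PKAc(b!1) @ 0 "
            "{pka_rebind}",
            "pka_rebind",
        ),
        (
            "'PKA_rebind_c2' R2C2(c2),PKAc(b) -> R2C2(c2!1),PKAc(b!1) @ 0 "
            "{pka_rebind}",
            "pka_rebind",
        ),
    ]
    degradation = [
        ("'cAMP_synth' . -> cAMP(b) @ 0 {camp_synth}", "camp_synth"),
        ("'cAMP_deg_basal' cAMP(b) -> . @ 0 {camp_deg_basal}", "camp_deg_basal"),
        (
            "'cAMP_deg_PDE' PDE(s~u?),cAMP(b) -> PDE(s~u?) @ 0 {camp_deg_pde}",
            "camp_deg_pde",
        ),
        (
            "'cAMP_deg_PDEp' PDE(s~p?),cAMP(b) -> PDE(s~p?) @ 0 {camp_deg_pde_p}",
            "camp_deg_pde_p",
        ),
        ("'Ca_leak' . -> Ca(b) @ 0 {ca_leak}", "ca_leak"),
        ("'Ca_efflux' Ca(b) -> . @ 0 {ca_efflux}", "ca_efflux"),
    ]
    pp2a_ca = [
        (
            "'PP2A_Ca_bind' PP2A(ca,s~u),Ca(b) -> PP2A(ca!1,s~u),Ca(b!1) @ 0 "
            "{pp2a_ca_bind}",
            "pp2a_ca_bind",
        ),
        (
            "'PP2A_Ca_bind_p' PP2A(ca,s~p),Ca(b) -> PP2A(ca!1,s~p),Ca(b!1) @ 0 "
            "{pp2a_ca_bind_p}",
            "pp2a_ca_bind_p",
        ),
        (
            "'PP2A_Ca_unbind' PP2A(ca!1),Ca(b!1) -> PP2A(ca),Ca(b) @ 0 "
            "{pp2a_ca_unbind}",
            "pp2a_ca_unbind",
        ),
    ]
    out = []
    for lst, comp in (
        (ck1, "CK1 phosphorylation"),
        (pde, "PDE phosphorylation"),
        (pp2a, "PP2A phosphorylation"),
        (pka_release, "PKA activation"),
        (degradation, "cAMP & Ca degradation"),
        (pp2a_ca, "PP2A activation by Ca"),
    ):
        out.extend((text, rid, comp) for text, rid in lst)
    return out


def _observables(binding: str) -> list[PatternObservable]:
    """Observable table following three principles: activated state for
    multi-state agents; least specific form for created/degraded agents;
    bound form for constant stateless agents."""
    dsites = "b?" if binding == "oBS" else "b1?,b2?,b3?"
    specs = [
        ("D", f"D(t34~u,t75~u,s137~u,{dsites})"),
        ("D34", "D(t34~p?)"),
        ("D75", "D(t75~p?)"),
        ("D137", "D(s137~p?)"),
        ("CK1u", "CK1(s~u?)"),
        ("PP2Bactive", "PP2B(ca1!_,ca2!_,ca3!_,ca4!_)"),
        ("PP2BinactiveCa2_all", None),  # filled below: sum of six placements
        ("PKA*", "PKAc(b)"),
        ("all_cAMP*", "cAMP()"),
        ("all_Ca*", "Ca()"),
        ("_PP2C", "PP2C(b!_)"),
        ("_CDK5", "CDK5(b!_)"),
    ]
    out = []
    for name, expr in specs:
        if expr is not None:
            out.append(PatternObservable(name, parse_pattern(expr)))
    # the six half-occupied PP2B placements, summed as one observable would
    # hide them; expose each variant for dissection plus the total
    sites = ("ca1", "ca2", "ca3", "ca4")
    for combo in itertools.combinations(sites, 2):
        expr = "PP2B(" + ",".join(
            f"{s}!_" if s in combo else s for s in sites
        ) + ")"
        out.append(PatternObservable("PP2BinactiveCa2_" + "_".join(combo), parse_pattern(expr)))
    return out


def build_model(
    variant: ModelVariant = ModelVariant(),
    params: Optional[dict] = None,
) -> ModelDefinition:
    """Build the eight-component DARPP-32 rule system for a model variant.

    Mutations change exactly one rate constant (the zeroed rule stays in the
    rule set); the competitive (oBS) and noncompetitive (tBS) variants have
    identical rule counts and differ only in the DARPP-32 signature and the
    partner site named by each binding rule.

    ``params`` must provide ``rates`` (by rate id), ``initial_copies``,
    ``volume_litres`` and the stimulus protocol; missing rate ids are
    reported together in the error.
    """
    params = params or load_default_params()
    rates = dict(params["rates"])
    if variant.mutation != "wild":
        rates[MUTATION_RULE[variant.mutation]] = 0.0

    sigs = _signatures(variant.binding)
    rule_specs = _d_phospho_rules(variant.binding) + _fixed_rules()

    missing = sorted(
        {rid for _, rid, _ in rule_specs if rid not in rates}
        | {
            rid
            for rid in (
                "pp2b_ca_on1",
                "pp2b_ca_off1",
                "pp2b_ca_on2",
                "pp2b_ca_off2",
                "r2c2_camp_on1",
                "r2c2_camp_off1",
                "r2c2_camp_on2",
                "r2c2_camp_off2",
            )
            if rid not in rates
        }
    )
    if missing:
        raise ValueError("missing rate constants: " + ", ".join(missing))

    rules: list[Rule] = []
    component: dict[str, str] = {}
    for text, rid, comp in rule_specs:
        rule = parse_rule_line(text)
        rule = Rule(rule.name, rule.lhs, rule.rhs, rates[rid], rid)
        rules.append(rule)
        component[rule.name] = comp

    # combinatorial-binding components
    pp2b_scheme = MultisiteScheme(
        "PP2B",
        4,
        "Ca",
        (
            BindingStep(2, rates["pp2b_ca_on1"], rates["pp2b_ca_off1"]),
            BindingStep(2, rates["pp2b_ca_on2"], rates["pp2b_ca_off2"]),
        ),
        activation={0: "inactive", 2: "half_active", 4: "active"},
    )
    for rule in expand_multisite_binding(pp2b_scheme):
        # rename generated rate ids onto the parameter table's
        rid = (
            rule.rate_id.replace("PP2B_Ca_on", "pp2b_ca_on").replace(
                "PP2B_Ca_off", "pp2b_ca_off"
            )
        )
        rules.append(Rule(rule.name, rule.lhs, rule.rhs, rates[rid], rid))
        component[rule.name] = "PP2B activation"
    r2c2_scheme = MultisiteScheme(
        "R2C2",
        4,
        "cAMP",
        (
            BindingStep(2, rates["r2c2_camp_on1"], rates["r2c2_camp_off1"]),
            BindingStep(2, rates["r2c2_camp_on2"], rates["r2c2_camp_off2"]),
        ),
        site_prefix="cam",
    )
    for rule in expand_multisite_binding(r2c2_scheme):
        rid = (
            rule.rate_id.replace("R2C2_cAMP_on", "r2c2_camp_on").replace(
                "R2C2_cAMP_off", "r2c2_camp_off"
            )
        )
        rules.append(Rule(rule.name, rule.lhs, rule.rhs, rates[rid], rid))
        component[rule.name] = "PKA activation"

    # initial mixture (catalytic subunits start bound to the holoenzyme)
    copies = params["initial_copies"]
    init_exprs = {
        "D": "D(t34~u,t75~u,s137~u,"
        + ("b)" if variant.binding == "oBS" else "b1,b2,b3)"),
        "R2C2": "R2C2(cam1,cam2,cam3,cam4,c1!1,c2!2),PKAc(b!1),PKAc(b!2)",
        "PP2B": "PP2B(ca1,ca2,ca3,ca4,b)",
        "CDK5": "CDK5(b)",
        "CK1": "CK1(b,s~u)",
        "PP2A": "PP2A(b,ca,s~u)",
        "PP2C": "PP2C(b)",
        "PDE": "PDE(b,s~u)",
        "cAMP": "cAMP(b)",
        "Ca": "Ca(b)",
    }
    init = []
    for agent, expr in init_exprs.items():
        n = int(copies.get(agent, 0))
        if n > 0:
            init.append((n, pattern_to_graph(parse_pattern(expr), sigs)))

    # stimulus protocol: cAMP pulse then calcium spike train
    events = []
    stim = params.get("stimuli", {})
    if "camp_pulse" in stim:
        p = stim["camp_pulse"]
        events.append(Event(float(p["time"]), AddCopies("cAMP(b)", int(p["copies"]))))
    if "ca_spikes" in stim:
        s = stim["ca_spikes"]
        for k in range(int(s["count"])):
            events.append(
                Event(
                    float(s["start"]) + k * float(s["interval"]),
                    AddCopies("Ca(b)", int(s["copies"])),
                )
            )
    events.sort(key=lambda e: e.time)

    model = ModelDefinition(
        signatures=sigs,
        rules=rules,
        init=init,
        observables=_observables(variant.binding),
        events=EventSchedule(events),
        snapshot_period=10_000,
        name=f"darpp32_{variant.mutation}_{variant.binding}",
    )
    model.component_of = component  # type: ignore[attr-defined]
    model.unit_context = UnitContext(float(params.get("volume_litres", 1e-15)))  # type: ignore[attr-defined]
    return model


def component_of_rule(model: ModelDefinition) -> dict[str, str]:
    return getattr(model, "component_of", {})


def import_sbml(path, **kwargs) -> SBMLImport:
    """Import an SBML reaction network (see :func:`sitesim.sbml_io.read_sbml`):
    species, mass-action reactions with rate constants, initial amounts and
    the timed stimulus events."""
    return read_sbml(path, **kwargs)


def aggregate_by_name(
    species_names: dict[str, str],
    patterns: Sequence[str],
    exclusions: Sequence[str] = (),
    network: Optional[ReactionNetwork] = None,
):
    """Observable over an imported (name-only) network: the sum of all species
    whose display name contains any of ``patterns`` and none of
    ``exclusions``.  Returns ``(matched ids, definition dict)`` and, when a
    network is given, a weight vector usable as a simulation observable.

    A pattern matching no species produces a warning entry in the definition,
    not an error.
    """
    matched: list[str] = []
    warnings: list[str] = []
    for pat in patterns:
        hits = [
            sid
            for sid, name in species_names.items()
            if pat in name and not any(ex in name for ex in exclusions)
        ]
        if not hits:
            warnings.append(f"pattern {pat!r} matched no species")
        matched.extend(h for h in hits if h not in matched)
    definition = {
        "patterns": list(patterns),
        "exclusions": list(exclusions),
        "matched_species": matched,
        "warnings": warnings,
    }
    if network is None:
        return matched, definition
    w = np.zeros(network.n_species)
    for sid in matched:
        w[network.index[sid]] = 1.0
    return matched, definition, w
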
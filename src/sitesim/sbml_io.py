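"""SBML import/export for the mass-action subset.

The reader accepts SBML Level 2/3 models whose kinetic laws are mass-action
products (``k * S1 * ... * Sn``, optionally times a compartment size, with
``k`` a numeric literal, a global or a local parameter) and whose events
trigger at fixed times with constant assignments to species amounts or
parameters.  Anything else — Michaelis–Menten laws, assignment rules,
non-constant triggers — is rejected with the offending element named, never
silently skipped.  Reversible reactions written as ``kf*Π - kr*Π`` are split
into a forward/backward pair.

Imported species are name-only (no site-graph); their composition can be
declared separately when condensing reactions into rules.

The writer emits Level 3 Version 1 models in amount (copy-number) units and
is used to round-trip fixture models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from .core import Mixture, Reaction, Species, UnitContext
from .engine import ReactionNetwork
from .model import Event, EventSchedule, SetCopies, SetRate
from .simulate import concentration_to_copies, convert_units

__all__ = ["SBMLImport", "SBMLImportError", "read_sbml", "write_sbml"]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


class SBMLImportError(ValueError):
    pass


@dataclass
class SBMLImport:
    """Result of an SBML import: explicit network, initial copies, stimuli."""

    network: ReactionNetwork
    init: Mixture
    events: EventSchedule
    species_names: dict[str, str]  # species id -> display name
    parameters: dict[str, float] = field(default_factory=dict)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _findall(el, name: str):
    return [c for c in el.iter() if _local(c.tag) == name]


def _children(el, name: str):
    return [c for c in el if _local(c.tag) == name]


# ---------------------------------------------------------------------------
# MathML (subset) analysis
# ---------------------------------------------------------------------------


@dataclass
class _Product:
    """Symbolic product: numeric coefficient x identifiers (with powers)."""

    coeff: float = 1.0
    idents: dict[str, int] = field(default_factory=dict)

    def times(self, other: "_Product") -> "_Product":
        out = _Product(self.coeff * other.coeff, dict(self.idents))
        for k, v in other.idents.items():
            out.idents[k] = out.idents.get(k, 0) + v
        return out


def _parse_product(el) -> _Product:
    tag = _local(el.tag)
    if tag == "ci":
        return _Product(1.0, {el.text.strip(): 1})
    if tag == "cn":
        cn_type = el.get("type", "real")
        if cn_type in ("integer", "real"):
            return _Product(float(el.text.strip()), {})
        if cn_type == "e-notation":
            parts = [t for t in el.itertext()]
            nums = [p.strip() for p in parts if p.strip()]
            return _Product(float(nums[0]) * 10 ** float(nums[1]), {})
        raise SBMLImportError(f"unsupported <cn> type {cn_type!r}")
    if tag == "apply":
        children = list(el)
        op = _local(children[0].tag)
        if op == "times":
            out = _Product()
            for c in children[1:]:
                out = out.times(_parse_product(c))
            return out
        if op == "power":
            base = _parse_product(children[1])
            exp = _parse_product(children[2])
            if base.coeff != 1.0 or len(base.idents) != 1 or exp.idents:
                raise SBMLImportError("unsupported <power> form")
            (ident, _), = base.idents.items()
            return _Product(1.0, {ident: int(exp.coeff)})
        raise SBMLImportError(f"unsupported MathML operator {op!r}")
    raise SBMLImportError(f"unsupported MathML element {tag!r}")


def _parse_kinetic_terms(math_el) -> list[tuple[int, _Product]]:
    """Kinetic law as signed mass-action products: [(+1, P)] or
    [(+1, Pf), (-1, Pr)] for a reversible difference."""
    roots = list(math_el)
    if len(roots) != 1:
        raise SBMLImportError("kinetic law must contain one expression")
    el = roots[0]
    if _local(el.tag) == "apply" and _local(list(el)[0].tag) == "minus":
        ch = list(el)
        if len(ch) != 3:
            raise SBMLImportError("unary minus unsupported in kinetic law")
        return [(+1, _parse_product(ch[1])), (-1, _parse_product(ch[2]))]
    return [(+1, _parse_product(el))]


def _trigger_time(trigger_el, parameters) -> float:
    math = _findall(trigger_el, "math")
    if not math:
        raise SBMLImportError("event trigger without math")
    el = list(math[0])[0]
    if _local(el.tag) != "apply":
        raise SBMLImportError("unsupported event trigger")
    ch = list(el)
    op = _local(ch[0].tag)
    if op not in ("geq", "gt", "ge"):
        raise SBMLImportError(f"unsupported trigger comparison {op!r}")
    lhs, rhs = ch[1], ch[2]

    def is_time(e) -> bool:
        return (
            _local(e.tag) in ("ci", "csymbol")
            and (e.get("definitionURL") == TIME_CSYMBOL or (e.text or "").strip() in ("t", "time"))
        )

    def const_value(e) -> float:
        p = _parse_product(e)
        val = p.coeff
        for ident, power in p.idents.items():
            if ident not in parameters:
                raise SBMLImportError(f"non-constant trigger bound {ident!r}")
            val *= parameters[ident] ** power
        return val

    if is_time(lhs):
        return const_value(rhs)
    if is_time(rhs):
        return const_value(lhs)
    raise SBMLImportError("trigger does not compare simulation time to a constant")


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------


def read_sbml(
    path: Union[str, Path],
    unit_context: Optional[UnitContext] = None,
    assume_concentration_units: bool = False,
) -> SBMLImport:
    """Import an SBML model (mass-action subset, timed events).

    With ``assume_concentration_units`` the kinetic constants are converted
    from molar units to stochastic per-copy units and concentrations to copy
    numbers using ``unit_context`` (volume, Avogadro).  Otherwise amounts and
    constants are taken verbatim as copy-number quantities.
    """
    ctx = unit_context or UnitContext()
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SBMLImportError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLImportError(f"not an SBML document: root element {_local(root.tag)!r}")
    model_els = _children(root, "model")
    if not model_els:
        raise SBMLImportError("SBML document has no <model>")
    model = model_els[0]

    compartments: dict[str, float] = {}
    for comp in _findall(model, "compartment"):
        compartments[comp.get("id")] = float(comp.get("size", comp.get("volume", 1.0)))

    parameters: dict[str, float] = {}
    for lst in _children(model, "listOfParameters"):
        for par in _children(lst, "parameter"):
            parameters[par.get("id")] = float(par.get("value", 0.0))

    species_names: dict[str, str] = {}
    init = Mixture()
    species_objs: dict[str, Species] = {}
    for sp in _findall(model, "species"):
        sid = sp.get("id")
        species_names[sid] = sp.get("name") or sid
        obj = Species(sid, None)
        species_objs[sid] = obj
        amount = sp.get("initialAmount")
        conc = sp.get("initialConcentration")
        if amount is not None:
            # substance units are copy numbers already
            init.add(obj, round(float(amount)))
        elif conc is not None:
            if assume_concentration_units:
                init.add(obj, concentration_to_copies(float(conc), ctx))
            else:
                init.add(
                    obj,
                    round(float(conc) * compartments.get(sp.get("compartment"), 1.0)),
                )
        else:
            init.add(obj, 0)

    unsupported: list[str] = []
    reactions: list[Reaction] = []
    for rx in _findall(model, "reaction"):
        rid = rx.get("id")
        reactant_stoich: dict[str, int] = {}
        product_stoich: dict[str, int] = {}
        for lst, acc in (
            ("listOfReactants", reactant_stoich),
            ("listOfProducts", product_stoich),
        ):
            for lref in _children(rx, lst):
                for ref in _children(lref, "speciesReference"):
                    sid = ref.get("species")
                    acc[sid] = acc.get(sid, 0) + round(float(ref.get("stoichiometry", 1)))
        klaws = _children(rx, "kineticLaw")
        if not klaws:
            unsupported.append(f"{rid}: no kinetic law")
            continue
        klaw = klaws[0]
        local_params = dict(parameters)
        local_ids: list[str] = []
        for lst in list(_children(klaw, "listOfParameters")) + list(
            _children(klaw, "listOfLocalParameters")
        ):
            for par in lst:
                if _local(par.tag) not in ("parameter", "localParameter"):
                    continue
                pid = par.get("id")
                local_params[pid] = float(par.get("value", 0.0))
                local_ids.append(pid)
        math = _children(klaw, "math")
        if not math:
            unsupported.append(f"{rid}: kinetic law without math")
            continue
        try:
            terms = _parse_kinetic_terms(math[0])
        except SBMLImportError as exc:
            unsupported.append(f"{rid}: {exc}")
            continue

        def build(sign: int, prod: _Product, suffix: str) -> Optional[str]:
            """Returns an error string or appends a Reaction."""
            k = prod.coeff
            consumed: dict[str, int] = {}
            k_params: list[str] = []
            for ident, power in prod.idents.items():
                if ident in species_objs:
                    consumed[ident] = consumed.get(ident, 0) + power
                elif ident in local_params:
                    k *= local_params[ident] ** power
                    k_params.append(ident)
                elif ident in compartments:
                    k *= compartments[ident] ** power
                else:
                    return f"unknown identifier {ident!r} in kinetic law"
            expect = reactant_stoich if sign > 0 else product_stoich
            if consumed != expect:
                return (
                    "kinetic law is not mass-action over the listed "
                    f"{'reactants' if sign > 0 else 'products'}"
                )
            r_side = expect
            p_side = product_stoich if sign > 0 else reactant_stoich
            order = sum(r_side.values())
            if assume_concentration_units:
                k = convert_units(k, order, ctx)
            rate_id = k_params[0] if len(k_params) == 1 else f"{rid}{suffix}"
            reactants = tuple(
                species_objs[s]
                for s in sorted(r_side)
                for _ in range(r_side[s])
            )
            products = tuple(
                species_objs[s]
                for s in sorted(p_side)
                for _ in range(p_side[s])
            )
            reactions.append(
                Reaction(reactants, products, k, rate_id, provenance=rid + suffix)
            )
            return None

        if len(terms) == 1:
            err = build(+1, terms[0][1], "")
            if err:
                unsupported.append(f"{rid}: {err}")
        else:
            err = build(+1, terms[0][1], "_fwd")
            err2 = build(-1, terms[1][1], "_rev")
            for e in (err, err2):
                if e:
                    unsupported.append(f"{rid}: {e}")

    if unsupported:
        raise SBMLImportError(
            "unsupported kinetic laws or reactions:\n  " + "\n  ".join(unsupported)
        )

    events: list[Event] = []
    bad_events: list[str] = []
    for ev in _findall(model, "event"):
        eid = ev.get("id") or f"event{len(events)}"
        triggers = _findall(ev, "trigger")
        try:
            if not triggers:
                raise SBMLImportError("no trigger")
            t = _trigger_time(triggers[0], parameters)
            for ea in _findall(ev, "eventAssignment"):
                var = ea.get("variable")
                math = _findall(ea, "math")
                if not math:
                    raise SBMLImportError("assignment without math")
                prod = _parse_product(list(math[0])[0])
                val = prod.coeff
                for ident, power in prod.idents.items():
                    if ident not in parameters:
                        raise SBMLImportError(
                            f"non-constant assignment value {ident!r}"
                        )
                    val *= parameters[ident] ** power
                if var in species_objs:
                    n = (
                        concentration_to_copies(val, ctx)
                        if assume_concentration_units
                        else round(val)
                    )
                    events.append(Event(t, SetCopies(var, n)))
                elif var in parameters:
                    # rate parameters shared with kinetic laws act as rate ids
                    events.append(Event(t, SetRate(var, val)))
                else:
                    raise SBMLImportError(f"assignment to unknown variable {var!r}")
        except SBMLImportError as exc:
            bad_events.append(f"{eid}: {exc}")
    if bad_events:
        raise SBMLImportError("unsupported events:\n  " + "\n  ".join(bad_events))
    events.sort(key=lambda e: e.time)

    network = ReactionNetwork(species_objs.values(), reactions)
    return SBMLImport(network, init, EventSchedule(events), species_names, parameters)


# ---------------------------------------------------------------------------
# Writer (fixture round-trips)
# ---------------------------------------------------------------------------


def _math(parent, build) -> None:
    math = etree.SubElement(parent, f"{{{MATHML_NS}}}math")
    build(math)


def write_sbml(
    network: ReactionNetwork,
    init: Mixture,
    path: Union[str, Path],
    events: Optional[EventSchedule] = None,
    model_id: str = "model",
) -> None:
    """Write a network as SBML L3V1 in amount units (mass-action kinetic laws,
    one parameter per distinct rate id)."""
    nsmap = {None: SBML_L3_NS}
    root = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap, level="3", version="1")
    model = etree.SubElement(root, f"{{{SBML_L3_NS}}}model", id=model_id)
    lc = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfCompartments")
    etree.SubElement(
        lc, f"{{{SBML_L3_NS}}}compartment", id="cell", size="1", constant="true"
    )
    ls = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfSpecies")
    ids: dict[str, str] = {}
    for i, sp in enumerate(network.species):
        sid = f"s{i}"
        ids[sp.canonical_id] = sid
        etree.SubElement(
            ls,
            f"{{{SBML_L3_NS}}}species",
            id=sid,
            name=sp.canonical_id,
            compartment="cell",
            initialAmount=str(init.count(sp.canonical_id)),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )
    lp = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfParameters")
    written: set[str] = set()
    rate_params: dict[int, str] = {}
    for j, r in enumerate(network.reactions):
        pid = r.rate_id or f"k{j}"
        rate_params[j] = pid
        if pid not in written:
            written.add(pid)
            etree.SubElement(
                lp,
                f"{{{SBML_L3_NS}}}parameter",
                id=pid,
                value=repr(r.rate / r.multiplicity),
                constant="false",
            )
    lr = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfReactions")
    for j, r in enumerate(network.reactions):
        rx = etree.SubElement(
            lr, f"{{{SBML_L3_NS}}}reaction", id=f"r{j}", reversible="false", fast="false"
        )
        if r.provenance:
            rx.set("name", str(r.provenance))
        stoich_r: dict[str, int] = {}
        for sp in r.reactants:
            stoich_r[sp.canonical_id] = stoich_r.get(sp.canonical_id, 0) + 1
        stoich_p: dict[str, int] = {}
        for sp in r.products:
            stoich_p[sp.canonical_id] = stoich_p.get(sp.canonical_id, 0) + 1
        if stoich_r:
            lref = etree.SubElement(rx, f"{{{SBML_L3_NS}}}listOfReactants")
            for cid, n in sorted(stoich_r.items()):
                etree.SubElement(
                    lref,
                    f"{{{SBML_L3_NS}}}speciesReference",
                    species=ids[cid],
                    stoichiometry=str(n),
                    constant="true",
                )
        if stoich_p:
            lref = etree.SubElement(rx, f"{{{SBML_L3_NS}}}listOfProducts")
            for cid, n in sorted(stoich_p.items()):
                etree.SubElement(
                    lref,
                    f"{{{SBML_L3_NS}}}speciesReference",
                    species=ids[cid],
                    stoichiometry=str(n),
                    constant="true",
                )
        klaw = etree.SubElement(rx, f"{{{SBML_L3_NS}}}kineticLaw")

        def build(math, j=j, stoich_r=stoich_r):
            mult = network.reactions[j].multiplicity
            apply_el = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
            etree.SubElement(apply_el, f"{{{MATHML_NS}}}times")
            ci = etree.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
            ci.text = rate_params[j]
            if mult != 1:
                cn = etree.SubElement(apply_el, f"{{{MATHML_NS}}}cn", type="integer")
                cn.text = str(mult)
            for cid, n in sorted(stoich_r.items()):
                for _ in range(n):
                    ci = etree.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
                    ci.text = ids[cid]

        _math(klaw, build)
    if events is not None and len(events):
        le = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfEvents")
        for k, ev in enumerate(events):
            evel = etree.SubElement(
                le,
                f"{{{SBML_L3_NS}}}event",
                id=f"e{k}",
                useValuesFromTriggerTime="true",
            )
            trig = etree.SubElement(
                evel,
                f"{{{SBML_L3_NS}}}trigger",
                initialValue="false",
                persistent="true",
            )

            def build_trig(math, t=ev.time):
                apply_el = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
                etree.SubElement(apply_el, f"{{{MATHML_NS}}}geq")
                cs = etree.SubElement(
                    apply_el,
                    f"{{{MATHML_NS}}}csymbol",
                    encoding="text",
                    definitionURL=TIME_CSYMBOL,
                )
                cs.text = "time"
                cn = etree.SubElement(apply_el, f"{{{MATHML_NS}}}cn")
                cn.text = repr(t)

            _math(trig, build_trig)
            lea = etree.SubElement(evel, f"{{{SBML_L3_NS}}}listOfEventAssignments")
            action = ev.action
            if isinstance(action, SetCopies):
                var, val = ids[action.species], float(action.n)
            elif isinstance(action, SetRate):
                var, val = action.rate_id, action.value
            else:
                raise ValueError(
                    "SBML export supports absolute assignments only "
                    f"(got {action!r}); convert AddCopies to SetCopies first"
                )
            ea = etree.SubElement(
                lea, f"{{{SBML_L3_NS}}}eventAssignment", variable=var
            )

            def build_assign(math, val=val):
                cn = etree.SubElement(math, f"{{{MATHML_NS}}}cn")
                cn.text = repr(val)

            _math(ea, build_assign)

    tree = etree.ElementTree(root)
    tree.write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
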
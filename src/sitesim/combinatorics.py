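"""Combinatorial-binding rule generation.

When several copies of one ligand bind a target on functionally identical but
*uniquely named* sites (the site-graph convention used here gives every site
its own name), every placement of the ligand must be written out explicitly.
This module generates those site-explicit rule sets from a compact scheme
description, e.g. the calcium activation of the phosphatase PP2B
(calcineurin): four Ca²⁺ sites filled in two reversible two-ion steps,
inactive → half-active → active, which expands to 24 rules and eight distinct
PP2B-containing species (1 empty + 6 half-occupied + 1 full).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    BOUND_ANY,
    FREE,
    AgentPattern,
    AgentSignature,
    ComplexPattern,
    Rule,
    SitePattern,
)
from .model import PatternObservable

__all__ = [
    "BindingStep",
    "MultisiteScheme",
    "expand_multisite_binding",
    "count_intermediate_species",
    "scheme_signatures",
    "activity_observables",
]


@dataclass(frozen=True)
class BindingStep:
    """One reversible step of a multisite ladder: ``ions`` ligand copies bind
    together with on/off constants ``k_on``/``k_off``."""

    ions: int
    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if self.ions < 1:
            raise ValueError("each step must bind at least one ligand")
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class MultisiteScheme:
    """A target agent with ``n_sites`` uniquely named ligand sites filled in
    ordered steps; ``activation`` labels occupancy levels (e.g. 0 → inactive,
    2 → half-active, 4 → active)."""

    target: str
    n_sites: int
    ligand: str
    steps: tuple[BindingStep, ...]
    activation: dict[int, str] = field(default_factory=dict)
    site_prefix: Optional[str] = None  # default: lowercased ligand name
    ligand_site: str = "b"

    def __post_init__(self) -> None:
        if sum(s.ions for s in self.steps) != self.n_sites:
            raise ValueError(
                "step sizes must sum to n_sites "
                f"({sum(s.ions for s in self.steps)} != {self.n_sites})"
            )

    def site_names(self) -> tuple[str, ...]:
        prefix = self.site_prefix or self.ligand.lower()
        return tuple(f"{prefix}{i}" for i in range(1, self.n_sites + 1))

    def occupancy_levels(self) -> tuple[int, ...]:
        """Occupancy counts at step boundaries: 0, cum(step1), cum(step2), ..."""
        levels = [0]
        for s in self.steps:
            levels.append(levels[-1] + s.ions)
        return tuple(levels)


def scheme_signatures(scheme: MultisiteScheme) -> list[AgentSignature]:
    return [
        AgentSignature(scheme.target, scheme.site_names()),
        AgentSignature(scheme.ligand, (scheme.ligand_site,)),
    ]


def expand_multisite_binding(scheme: MultisiteScheme) -> list[Rule]:
    """Emit the site-explicit rule set of a multisite binding ladder.

    For each step *s* (binding ``m`` ligands) and each occupancy state at the
    step's entry level, one forward rule per ``m``-subset of free sites binds
    fresh ligands to exactly those sites, and one reverse rule per (state,
    step subset) unbinds them together.  Occupancy is explicit in every rule
    because rates are step-specific; all rules of a step's direction share one
    ``rate_id``.
    """
    site_names = scheme.site_names()
    levels = scheme.occupancy_levels()
    rules: list[Rule] = []
    for si, step in enumerate(scheme.steps):
        entry = levels[si]
        fwd_id = f"{scheme.target}_{scheme.ligand}_on{si + 1}"
        rev_id = f"{scheme.target}_{scheme.ligand}_off{si + 1}"
        for bound in itertools.combinations(site_names, entry):
            bound_set = frozenset(bound)
            free_sites = [s for s in site_names if s not in bound_set]
            if step.ions > len(free_sites):
                raise ValueError(
                    f"step {si + 1} binds {step.ions} ligands but only "
                    f"{len(free_sites)} sites are free"
                )
            for subset in itertools.combinations(free_sites, step.ions):
                # forward: target with `bound` occupied, `subset` free -> bonds
                lhs_sites, rhs_sites = [], []
                lig_l, lig_r = [], []
                label = 1
                for site in site_names:
                    if site in bound_set:
                        lhs_sites.append(SitePattern(site, None, BOUND_ANY))
                        rhs_sites.append(SitePattern(site, None, BOUND_ANY))
                    elif site in subset:
                        lhs_sites.append(SitePattern(site, None, FREE))
                        rhs_sites.append(SitePattern(site, None, label))
                        lig_l.append(
                            AgentPattern(
                                scheme.ligand,
                                (SitePattern(scheme.ligand_site, None, FREE),),
                            )
                        )
                        lig_r.append(
                            AgentPattern(
                                scheme.ligand,
                                (SitePattern(scheme.ligand_site, None, label),),
                            )
                        )
                        label += 1
                    else:
                        lhs_sites.append(SitePattern(site, None, FREE))
                        rhs_sites.append(SitePattern(site, None, FREE))
                state_tag = "_".join(sorted(bound_set)) or "empty"
                sub_tag = "_".join(subset)
                rules.append(
                    Rule(
                        f"{scheme.target}_bind_{scheme.ligand}_step{si + 1}"
                        f"_at_{sub_tag}_from_{state_tag}",
                        ComplexPattern(
                            (AgentPattern(scheme.target, tuple(lhs_sites)), *lig_l)
                        ),
                        ComplexPattern(
                            (AgentPattern(scheme.target, tuple(rhs_sites)), *lig_r)
                        ),
                        step.k_on,
                        fwd_id,
                    )
                )
                # reverse: target with `bound` + `subset` occupied -> unbind subset
                lhs_sites, rhs_sites = [], []
                lig_l, lig_r = [], []
                label = 1
                for site in site_names:
                    if site in bound_set:
                        lhs_sites.append(SitePattern(site, None, BOUND_ANY))
                        rhs_sites.append(SitePattern(site, None, BOUND_ANY))
                    elif site in subset:
                        lhs_sites.append(SitePattern(site, None, label))
                        rhs_sites.append(SitePattern(site, None, FREE))
                        lig_l.append(
                            AgentPattern(
                                scheme.ligand,
                                (SitePattern(scheme.ligand_site, None, label),),
                            )
                        )
                        lig_r.append(
                            AgentPattern(
                                scheme.ligand,
                                (SitePattern(scheme.ligand_site, None, FREE),),
                            )
                        )
                        label += 1
                    else:
                        lhs_sites.append(SitePattern(site, None, FREE))
                        rhs_sites.append(SitePattern(site, None, FREE))
                rules.append(
                    Rule(
                        f"{scheme.target}_unbind_{scheme.ligand}_step{si + 1}"
                        f"_at_{sub_tag}_from_{state_tag}",
                        ComplexPattern(
                            (AgentPattern(scheme.target, tuple(lhs_sites)), *lig_l)
                        ),
                        ComplexPattern(
                            (AgentPattern(scheme.target, tuple(rhs_sites)), *lig_r)
                        ),
                        step.k_off,
                        rev_id,
                    )
                )
    return rules


def count_intermediate_species(n_sites: int, k_bound: int) -> int:
    """Number of distinct species of a multisite target with exactly
    ``k_bound`` of its ``n_sites`` uniquely named sites occupied: C(n, k)."""
    if not 0 <= k_bound <= n_sites:
        raise ValueError(f"k_bound must lie in [0, {n_sites}], got {k_bound}")
    return math.comb(n_sites, k_bound)


def activity_observables(scheme: MultisiteScheme) -> list[PatternObservable]:
    """Pattern observables for each labelled occupancy level (bound sites as
    bound-any, the rest free)."""
    out = []
    site_names = scheme.site_names()
    for level, lab in sorted(scheme.activation.items()):
        # occupancy level -> sum over all C(n, level) placements
        patterns = []
        for combo in itertools.combinations(site_names, level):
            sites = tuple(
                SitePattern(s, None, BOUND_ANY if s in combo else FREE)
                for s in site_names
            )
            patterns.append(ComplexPattern((AgentPattern(scheme.target, sites),)))
        for i, cp in enumerate(patterns):
            name = f"{scheme.target}_{lab}" + (f"_{i}" if len(patterns) > 1 else "")
            out.append(PatternObservable(name, cp))
    return out
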
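"""Condensing explicit reactions into decontextualised rules.

Two phosphorylation reactions that differ only in a spectator phosphosite
state — and share a rate constant — carry no information in that state, so
they collapse into one rule with the context removed.  With different rates
the context is informative and both reactions survive as contextual rules.
"""

from sitesim import condense_reactions
from sitesim.fixtures import make_toy
from sitesim.kappa_io import format_rule

for equal in (True, False):
    toy = make_toy("phospho_spectator", equal_rates=equal)
    rules, report = condense_reactions(toy.reactions)
    label = "equal rates" if equal else "different rates"
    print(f"{label}: {len(toy.reactions)} reactions -> {len(rules)} rule(s)")
    for rule in rules:
        print("   ", format_rule(rule))
    comp, (nr, nu, nk) = next(iter(report.by_component().items()))
    print(f"    report[{comp}]: reactions={nr} rules={nu} unique_rates={nk}")

# The condensed rule 'D(t~u?) -> D(t~p?)' mentions only the transformed site;
# the '?' marks the binding state as unconditioned.  Re-expanding it over the
# original species regenerates exactly the two input reactions.
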
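"""From rules to a reaction network.

A reversible binding model written in the Kappa-subset text format is
expanded by fixed-point closure into its explicit species and mass-action
reactions — the step that turns a rule-based model into an ODE-ready network.
"""

from sitesim import Species, generate_network, read_kappa

model = read_kappa(
    """
%agent: A(x)
%agent: B(y)
'bind'   A(x),B(y) -> A(x!1),B(y!1) @ 0.001 {kon}
'unbind' A(x!1),B(y!1) -> A(x),B(y) @ 0.1   {koff}
%init: 100 A(x)
%init: 80  B(y)
"""
)

seeds = [Species.from_graph(g, model.signatures) for _, g in model.init]
network = generate_network(model.rules, seeds, model.signatures)

print(f"{len(model.rules)} rules -> {network.n_species} species, "
      f"{network.n_reactions} reactions")
for rxn in network.reactions:
    lhs = " + ".join(s.canonical_id for s in rxn.reactants)
    rhs = " + ".join(s.canonical_id for s in rxn.products)
    print(f"  {lhs} -> {rhs}   k = {rxn.rate}  ({rxn.rate_id})")

# Two rules generate two reactions here because A and B are single-state
# agents; rules over multi-state agents generate many reactions each.
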
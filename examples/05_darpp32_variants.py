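"""The DARPP-32 network: model variants and in-silico mutagenesis.

DARPP-32 integrates cAMP-PKA and Ca-PP2B signalling through three
phosphosites (Thr34, Thr75, Ser137).  Site-directed mutations are induced by
zeroing a single rule's rate constant; the competitive (one binding site,
oBS) and noncompetitive (three sites, tBS) variants keep the same rule count.
"""

from collections import Counter

from sitesim import ModelVariant, Species, build_model, generate_network
from sitesim.darpp32 import component_of_rule

wild = build_model(ModelVariant("wild", "oBS"))
mutant = build_model(ModelVariant("ser137ala", "oBS"))
tbs = build_model(ModelVariant("wild", "tBS"))

print(f"rules: wild oBS = {len(wild.rules)}, ser137ala = {len(mutant.rules)}, "
      f"wild tBS = {len(tbs.rules)}")
print("rules per component:")
for comp, n in sorted(Counter(component_of_rule(wild).values()).items()):
    print(f"  {comp:28s} {n}")

diffs = [
    (a.name, a.rate, b.rate)
    for a, b in zip(wild.rules, mutant.rules)
    if a.rate != b.rate
]
print(f"ser137ala changes {len(diffs)} constant: "
      f"{diffs[0][0]} {diffs[0][1]} -> {diffs[0][2]}")

for name, model in (("oBS", wild), ("tBS", tbs)):
    seeds = [Species.from_graph(g, model.signatures) for _, g in model.init]
    net = generate_network(model.rules, seeds, model.signatures)
    print(f"{name} network: {net.n_species} species, {net.n_reactions} reactions")

# Identical rule counts but a much larger species space for the
# noncompetitive variant: extra binding sites multiply complexes, not rules.
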
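# Methods

## Representation

A model is a set of *agent signatures* (agent name, ordered site names,
allowed internal states per site), a set of *rules*, initial copy numbers,
pattern observables and a timed event schedule. A concrete molecular
species is a connected site-graph in which every site carries a definite
internal state (where the signature declares one) and is either free or
bonded to exactly one partner site. Patterns are partial: an unmentioned
site, an omitted internal state, or the `?` binding marker mean *no
condition* — the decontextualisation that lets one rule cover many
reactions. Functionally identical sites receive distinct names (`ca1..ca4`),
so site symmetry is materialised as distinct species rather than handled by
equivalence classes; this is the convention of the Kappa family of
languages, and it is what produces the 6 half-occupied variants of a
four-site ladder.

### Canonical species identifiers

Species are keyed by a canonical string: iterative neighbourhood (colour)
refinement assigns each agent a colour from its name, site states and bonded
neighbourhood; agents are then ordered by colour, remaining ties are
resolved by exhaustive search over within-class permutations, and the
lexicographically smallest serialization wins. The search is exact (two
species get equal ids iff their graphs are isomorphic) and cheap because
complexes in the targeted models are small (≈10 agents) and refinement
leaves few ties; a guard rejects graphs whose tie structure would exceed
10⁵ orderings. Idempotence and relabelling-invariance are property-tested
against random permutations.

### Rule semantics and validation

Left- and right-hand sides correspond positionally: agent *i* maps to agent
*i*; surplus left agents are degraded (their bonds severed as a side
effect), surplus right agents synthesized (and must be fully specified).
The validator rejects unknown agents/sites/states, dangling bond labels,
changed agent types, and **ring formation**: a created bond whose endpoints
lie in one agent or one connected component of the left-hand side. The
reachable state space therefore contains only acyclic complexes, and a
binary rule is never applied to two embeddings in the same complex instance
(which would be the ambiguous-molecularity case). A rule whose two sides
are equal is accepted but flagged as a no-op.

## Reaction-network generation

Rules are generators: a breadth-first fixed-point closure over seed species
enumerates every reachable species and emits one mass-action reaction per
(rule, reactant channel, product outcome). The default species cap of
10 000 turns runaway combinatorics into an explicit "network too large"
failure rather than an unbounded enumeration.

**Rate convention.** A generated reaction's constant is
`k_rule × m`, where `m` counts the (component→instance bijection, embedding)
combinations that produce the given products from one fixed set of distinct
reactant instances. For ordinary asymmetric rules `m = 1`; for a
self-binding rule `A + A` it is 2. The simulators then count *distinct
reactant combinations* (`n` for single, `n(n−1)/2` for a doubly consumed
species, `n(n−1)(n−2)/6` for triply consumed). Together these reproduce
embedding-number propensities — `k·n(n−1)` for `A+A` — i.e. the Kappa-style
semantics in which the rule constant itself is never rescaled by symmetry
factors (unlike the BioNetGen convention of automatic division by the
multiplicity of indistinguishable product routes). Binding two ligands in
one step (the two-ion ladder steps) makes some rules trimolecular; the
engine and both simulators handle reactant multisets up to that order, while
the deterministic↔stochastic unit conversion deliberately supports orders
0–2 only (`k·N_A·V`, `k`, `k/(N_A·V)`), the orders that occur in imported
concentration-based models.

## Condensation of reactions into rules

The inverse translation groups reactions by (i) an alignment-derived
*transformation signature* — the multiset of transformed-site operations
(state flips with from/to, bond creations/deletions, agent
synthesis/degradation, each labelled with agent and site names) — and (ii)
equality of rate values (exact by default; a relative tolerance is available
for floating-point imports). The alignment between reactant and product
pools is the injective, name-preserving correspondence with the fewest site
differences, found exhaustively (reaction complexes are small). Spectator
agents inside reactant complexes (e.g. ligands parked on other sites) do not
split groups — only the transformed context matters.

For each group a candidate rule is built from the transformed sites plus the
bond paths needed to keep co-transformed agents connected; the candidate is
accepted only if single-step re-expansion over the input's species universe
regenerates the group's reaction multiset exactly (rates included).
Otherwise the group falls back to fully contextual rules, one per reaction,
which round-trip by construction. The per-component report (reactions,
rules, unique rate constants) mirrors the tabular comparison this package is
designed to reproduce. A consistency check on ladders: with one-ligand
steps and rates equal across steps, occupancy context carries no
information and the expansion re-condenses to one bind + one unbind rule
per site; with step-specific rates it does not collapse.

## Simulation

**Stochastic.** Gillespie's direct method, exactly: two uniform variates
per step (waiting time via inverse exponential, channel via cumulative
propensity search), incremental propensity updates over the reactions that
share species with the fired channel, observables recorded on a fixed
`record_dt` grid with the last value carried forward, and replicate *i*
seeded `base_seed + i` (NumPy PCG64). Snapshots of the whole mixture are
taken every *N*-th reaction event (default 10 000) plus at the final state.

**Deterministic.** Mass-action rate equations in copy-number units
(`n^r / r!` in the large-copy limit of the combination counts), integrated
with LSODA (stiff-capable; defaults rtol 1e-6, atol 1e-9 — the stimulus
spike trains make the system stiff). SSA replicate means converge to the
ODE solution for linear networks; this is tested at 200 replicates with a
3-standard-error band.

**Events.** A schedule of (time, action) pairs with actions `add_copies`,
`set_copies` (used by SBML event import, which assigns absolute amounts) and
`set_rate` (updating every reaction sharing a rate id, each rescaled by its
own multiplicity `m`). In the stochastic backend an event interrupts the
jump clock: time advances to the trigger, the action is applied,
propensities refresh, and a fresh waiting time is drawn — valid because the
exponential is memoryless. In the ODE backend events are discontinuities at
segment boundaries. Each event fires exactly once regardless of the
recording grid.

## The DARPP-32 model library

`build_model(ModelVariant(mutation, binding))` constructs the
eight-component rule system: DARPP-32 phosphorylation (bind / catalyse /
release for the three kinase–phosphatase pairs PKA/PP2B on Thr34, CDK5/PP2A
on Thr75, CK1/PP2C on Ser137); CK1, PDE and PP2A phosphorylation; PP2B and
PKA activation as combinatorial-binding ladders (four uniquely named
ligand sites, two reversible two-molecule steps; PKA additionally releases
and rebinds its two catalytic subunits once the regulatory dimer is fully
loaded); cAMP and Ca²⁺ turnover; and Ca²⁺ activation of PP2A.

* **Mutations** zero exactly one rate constant: `ser137ala` silences the
  single CK1 catalytic rule on Ser137 (the site can no longer be
  phosphorylated), `constser137` the single PP2C dephosphorylation rule
  (phosphorylation becomes permanent). The rule inventory is unchanged.
* **Binding variants**: `oBS` gives DARPP-32 one partner site (competitive —
  one interactor at a time, the assumption of the equation-based
  formulation); `tBS` gives three independent sites, one per phosphosite's
  enzyme pair. Both variants have identical rule counts; only the signature
  and the site named in each binding rule differ. The noncompetitive
  network is much larger in species (372 vs 136 with the default builder)
  at equal rule count — sites multiply complexes, not rules.

**Parameterisation is data, not code.** The published reaction system keeps
its rate constants, initial concentrations and the 21-event stimulus
protocol (a cAMP pulse followed by a Ca²⁺ spike train) inside the curated
SBML file (BioModels `BIOMD0000000153`), which `sitesim translate` can
convert. The packaged table `_data/darpp32_params.yaml` is an explicitly
synthetic stand-in chosen once so the built-in model runs self-contained:
micromolar-scale (weak) bindings, second-scale catalysis, DARPP-32 in excess
of all its interactors, reaction volume 10⁻¹⁵ L (a typical subcellular
compartment; the volume enters only through unit conversion), and a
stimulus protocol with the published shape (one pulse + 20 spikes at 2-s
intervals). Structural claims (rule counts, species censuses, one-constant
mutations, oBS/tBS equivalence) do not depend on these values; quantitative
trajectories do, so tests assert the former and only qualitative/relative
properties of the latter.

## Observables and censuses

Pattern observables default to agent-instance counting (a species
containing the motif *k* times contributes *k* per copy — the per-molecule
tally appropriate for "all cAMP including copies bound in complexes");
species-copy counting is available for censuses. Name-based aggregation
over imported networks (`aggregate_by_name`: substring inclusion minus
exclusions, with an audit record of the matched species) mirrors how
summed variables are defined in equation-based models, and a pattern that
matches nothing warns rather than errors. The sampled census is the union
of snapshot supports — a lower bound on the reachable set that grows with
simulation length; `generate_network` provides the exhaustive counterpart.
Trajectory comparison resamples both series onto a common grid and reports
max |Δmean| (scaled by pooled sd when replicate spread is available) and
the area between curves; these metrics are descriptive aids, not pass/fail
statistics.

## What the fixtures do and do not show

The synthetic generator provides systems with known answers: first-order
decay (closed-form mean), an immigration–death process (Poisson stationary
law, mean = variance = b/d), reversible dimerisation (equilibrium from the
mass-action quadratic), multisite ladders (binomial occupancy counts), a
spectator-state reaction pair (minimal condensation case), and seeded
random rule systems whose bond graph over agent types is kept acyclic so
closures stay finite and brute-force enumerable. Passing these establishes
the correctness of the machinery — matching, rewriting, closure,
propensities, unit handling — on exactly solvable cases; it does not
validate the synthetic DARPP-32 parameterisation against measured biology,
and it cannot exercise the published model's own numbers without the
curated SBML file.

## Numerical and design notes

* Copy numbers are 64-bit integers in the stochastic backend, floats in the
  ODE backend; observables are integer-valued in single stochastic
  replicates.
* Channel selection uses `searchsorted` on the propensity cumsum; ties at
  machine precision resolve to the lower index, and the index is clamped to
  the last channel to guard against `u2·a0` rounding up.
* The SBML reader covers the mass-action subset (kinetic law = constant ×
  reactant product, optionally × compartment; reversible laws written as a
  difference are split into a forward/backward pair) and constant-trigger,
  constant-assignment events; everything else is rejected with the element
  named. Imported species are name-only; condensation accepts a declared
  name → site-graph composition map.
* The text format is a restricted Kappa-like dialect, documented by EBNF in
  `sitesim.kappa_io`, and is not claimed compatible with any KaSim release.
* Known limitations: no network-free simulation (networks are enumerated in
  full, so models must stay within the species cap); no tau-leaping or
  hybrid stepping; no cooperative rate modifiers beyond step-specific
  constants in binding ladders; ring-forming rules are rejected rather than
  supported.
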
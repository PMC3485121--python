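# Methods

This note documents the models, algorithms, conventions and numerical
choices behind `rulesim`, in the order a user meets them.

## Site graphs and rules

A species or pattern is a *site graph*: molecule instances carrying typed
components; a component holds an internal state (e.g. `~U`/`~P`) and at
most one bond.  Patterns may leave states unconstrained, omit components
entirely (unconstrained), or carry bond wildcards: `!+` bound to
anything, `!?` bound or unbound.  A component written without a bond
marker is unbound — this convention is load-bearing: the
dephosphorylation pattern `R(y~P)` deliberately matches only *unbound*
phosphosites, so an adapter bound to a site shields it from
dephosphorylation.

Rules are stored operationally as reactant patterns plus a transformation
list (AddBond, DeleteBond, ChangeState, CreateMolecule, DeleteMolecule,
ChangeCompartment) derived by a positional diff of the written
reactant/product sides: the k-th occurrence of a molecule type on the
left maps to the k-th on the right, components match by name and
occurrence order.  If transposing two same-type molecules changes the
diff, the rule is rejected as ambiguous rather than guessed at.  The
defining contract, enforced for every fixture rule in the test suite, is
that applying the transformations to the reactant side reproduces the
product side up to isomorphism.  Deleting a molecule implicitly breaks
any bonds not already removed (its partners are left unbound).

Compartments (`Ex`, `M`, `C`, `En`) are attributes on molecules with
`ChangeCompartment` transformations available for transport; no
membrane-adjacency topology is enforced, matching the four-compartment
usage of the ERBB fixture without inventing richer semantics.

## Pattern matching and species identity

Embedding enumeration is backtracking search: pattern molecules are
visited most-constrained-first (explicit bonds, then size) in an order
that follows the pattern's bond structure, so partial embeddings prune
via bonds; candidates are sorted for determinism.  All symmetric
duplicates are returned; mass-action symmetry is handled separately by
dividing a rule's rate by the automorphism count of its full reactant
side (so an A+A rule is not double-counted, and a symmetric dimer
dissociates at k per dimer).  Pattern preprocessing is cached by object
identity; patterns must not be mutated between calls.

Canonical species labels use iterative neighbourhood refinement
(molecule colors refined by typed, bonded neighbourhoods) with
individualization of the smallest ambiguous color class and exhaustive
tie-breaking; the lexicographically smallest serialization wins.  This
is exponential in the worst case but species in signaling models are
short chains/trees of at most a few tens of molecules; correctness and
platform-stable determinism matter more here than asymptotics.  The test
suite checks label equality against an exhaustive isomorphism oracle on
randomized corpora that include repeated component names.

## Network-free simulation

The particle-based simulator tracks every molecule instance and keeps,
per rule reactant pattern and per observable pattern, the exact set of
current embeddings, with a reverse index from particles to embeddings.
A step: total rate Σ_r k_r/σ_r · (embedding-count product, with n(n−1)
for a rule whose two patterns are identical); exponential waiting time;
rule chosen proportionally; embeddings drawn uniformly.  A bimolecular
selection whose embeddings share a complex is a *null event* — time
advances, nothing changes — which keeps the rejection scheme exact and
excludes intramolecular binding (ring closure) by design.  After a real
event the index is repaired locally: the complexes touched by the event
are re-matched; everything else is untouched.  Complexes in these models
are small (a receptor dimer plus adapters), so complex-level re-matching
is cheap and simple; `SimState.check_index()` verifies the incremental
index against a full recompute and runs periodically in debug mode.

Determinism: one named RNG per run (`numpy.random.default_rng(seed)`),
all stochastic choices drawn from it in a fixed order; identical inputs
give identical trajectories.  Seed species copy numbers are multiplied
by the compartment scale factor (or an explicit `scale` argument) and
rounded half-to-even — deterministic and unbiased.  Equilibration is an
explicit protocol step (`Protocol(equilibrate=T)`): the system is
simulated for T seconds before t=0 without sampling; no steady-state
detection is attempted because no convergence criterion is defined for
these models.  Observables: *Molecules* = embedding count divided by the
pattern's automorphisms; *Species* = number of distinct complexes
containing a match.

The simulator also accumulates a work counter (candidate checks in the
matcher).  At signaling steady state the work per event is constant;
during the initial transient it grows with mean complex size, which is a
property of the mixture, not of the implied network.

## On-the-fly simulation

The population-based simulator interns species by canonical label and
generates reactions lazily: when a species first becomes populated it is
*expanded* — every rule is applied to it (and, for bimolecular rules, to
it paired with every previously expanded species), embedding
combinations are grouped by their product multiset, and each group
becomes a reaction channel with stochastic coefficient k·m/σ (m the
embedding multiplicity).  Propensities are c·x for unimolecular
channels, c·x₁x₂ for distinct reactants and c·x(x−1) for a species
reacting with itself — exactly the particle-level conventions, so the
two simulators are statistically interchangeable on any model both can
handle; the test suite compares their trajectory means at every grid
point and validates both against the chemical master equation.

The direct-method SSA uses a vectorized linear propensity scan; no
dependency-graph optimization, deliberately — this simulator exists as a
cross-validation oracle and to exhibit the network-explosion phenomenon.
The species cap (default 50,000) is a reportable outcome, not a crash:
the run stops gracefully, flags `truncated`, and returns partial
trajectory and census.  The census reports both currently-populated
species (population ≥ 1 at the sample instant) and the cumulative count
of species generated, since "populated" admits both readings.

## Exact state-space counting

A receptor site's local states are its unbound modification states
(1 or 2, depending on whether it is phosphorylatable) plus one state per
distinct attachable adapter complex, enumerated recursively: a binder
has modification states and child sites, each child site independently
empty or bound to one of its allowed sub-complexes, with optional
gating (a child site occupiable only in a given binder state — e.g.
GRB2 binds SHC1 only when SHC1 is phosphorylated).  Dual-specificity
sites (one physical tyrosine docking two different adapters) pool the
bound-complex sets with duplicates removed.  Monomer counts are the
product of per-site counts; a heterodimer multiplies two monomer counts;
a homodimer counts unordered pairs with repetition, n(n+1)/2, because
the two protomers are physically interchangeable — the only convention
consistent with the published dimer bounds.  All counts are exact Python
integers; no floating point enters until display.

The shipped EGFR specification (ligand site; SHC1 docks at y1148/y1173;
GRB2 at y1068/y1086/y992; dual GRB2/SHC1 at y1114) gives
2·8·6·8·12·6·6 = 331,776; ERBB3 (ligand; six PI3K docks; one SHC1 dock)
gives 2·3⁶·8 = 11,664.  Which tyrosines dock which adapter is
illustrative — the factor structure, not residue identity, determines
the counts.

## Parameter ensembles and detailed balance

Six parameter classes with feasible ranges (units per cell):
bimolecular association 10⁻⁷–10⁻⁵ (molecules/cell)⁻¹s⁻¹ (upper end
doubling as the default diffusion cap), unimolecular dissociation
10⁻²–1 s⁻¹, phosphatase-catalyzed / receptor-trafficking / endocytic-
degradation steps 10⁻³–10⁻¹ s⁻¹, protein copy numbers 10⁴–10⁶ per cell
(rounded to integers).  Values are drawn log-uniformly: the ranges span
two orders of magnitude and log-uniform is the scale-free choice.

Detailed balance is enforced on reversible *binding* equilibria only;
catalytic, trafficking and degradation steps are irreversible,
energy-consuming processes and are exempt, per standard practice.  The
constraint graph is built concretely: a one-pot closed system holding
one copy of each molecule type involved in reversible binding rules
(two copies for homotypic rules), with every modifiable component fixed
in its binding-permissive (last-listed) state; nodes are canonical
multisets of complexes, edges are reversible rule pairs, reachability is
enumerated breadth-first (capped at 2000 states).  A BFS spanning tree
keeps tree-edge equilibrium constants as sampled; each off-tree edge
contributes one fundamental cycle whose product of K^±1 must equal 1,
and its reverse rate constant is reset accordingly.  Context-free
binding rules always cancel around cycles (their free energies decompose
per bond); nontrivial constraints arise exactly from cooperative,
context-dependent rules, which the `cooperative` toy exhibits.  If the
required K cannot be realized within the class ranges, the forward rate
is redrawn inside the feasible window; if the window itself is empty the
whole parameter set is rejected and redrawn, which keeps accepted sets
log-uniform conditioned on the constraint.  An independent audit
(`cycle_products`) recomputes every fundamental-cycle product from
scratch; the tolerance is 10⁻⁹ and sampled ensembles close cycles to
~10⁻¹⁶ in practice.

Concentration inputs convert at the boundary:
copies = round(c·N_A·V_eff) with V_eff the 3-D compartment volume times
its scale factor (5 nM in 1 pL → 3,011 copies); membrane species are
specified directly as copies.

## Time-course analysis and contact maps

Phosphorylation time courses are normalized per row by their own maximum
(all-zero rows stay zero and are flagged), then ordered by agglomerative
average-linkage clustering under d = 1 − Pearson r.  The agglomeration
is implemented directly — row counts are tens, O(n³) is instant — with
explicit determinism: among equally distant pairs the one containing the
lowest original row index merges first, and at each merge the cluster
containing the lower original index becomes the left child, fixing the
leaf order.  Constant rows (Pearson undefined) are segregated up front.
scipy's implementation serves as the independent oracle in tests, never
as the implementation.  No particular heat-map renderer's leaf-ordering
heuristic is reproduced; the output is the clustered matrix a renderer
would consume.

Contact-map extraction maps every AddBond/DeleteBond rule to one
undirected binding edge per distinct component pair (contextual
refinements of one interaction collapse onto one edge with a rule
multiplicity) and every catalyzed state change to a directed
enzyme→substrate-flag edge.  The catalyst is the unique other reactant
molecule when exactly one exists; otherwise an explicit `@enzyme=Name`
suffix on the rule name supplies it (used for in-complex
transphosphorylation, where the kinase is the dimer partner implied by a
`d!+` context rather than a pattern molecule).  Rules contributing no
edge — uncatalyzed dephosphorylation, transport, degradation — are
listed as unmapped so every rule is accounted for.  Exports (GraphML via
networkx, JSON, DOT; CSV/TSV for matrices) are deterministic.

## The fixtures and what they do (and do not) emulate

The toys have closed-form or exactly enumerable behavior: `binding`
(3-species equilibrium solving the mass-action quadratic),
`isomerization` (telegraph process; symmetric rates give mean fraction
1/2), `dimerization` (exercises the symmetry factor), `multisite_phospho`
(k independent sites, 2^k phosphoforms), `chain` (head-to-tail
polymerization; unbounded implied network), `cooperative` (two ligands
with context-dependent affinities; one genuine binding cycle,
K₁K₂c = K₂K₁c).

The reduced ERBB model is an original authored artifact — *not* a
transcription of any published model file — mirroring the classic
EGF/HRG → EGFR/ERBB3 adapter-recruitment structure: ligand binding,
ligand-dependent homo/heterodimerization, transphosphorylation of the
13 receptor tyrosines in dimer context, SHC1/GRB2/SOS1/GAB1/PI3K
recruitment (tier 1); per-site dephosphorylation, Ras→RAF→MEK→ERK and
PI3K→Akt backbones with one activating site each, and ERK→SOS1 negative
feedback gating GRB2–SOS1 binding (tier 2).  Its receptor interfaces
project exactly onto the counting specifications above.  Study
conditions are desk-scale by construction: copy numbers of 2,000–10,000
per protein (the low end of the feasible copy-number range) with a
compartment scale factor of 0.2 applied at simulation time, extracellular
volume 1 pL (so a 5 nM ligand dose is 602 copies at scale 0.2), and a
nominal parameter set chosen once from within the class ranges at the
kinetically fast end (association 10⁻⁵, dissociation 10⁻², kinase 10⁻¹,
phosphatase 10⁻³) so that receptor activation and adapter recruitment
are visible within minutes of simulated time.  Kinase-catalyzed steps
have no class of their own in the six-range scheme; the fixture assigns
them the same catalytic range as the phosphatase class.

What the fixtures do **not** emulate: full cellular copy numbers (10⁶
particles), receptor trafficking and endosomal degradation rules, the
other ERBB family members, and the full several-hundred-rule inventory
of contextual refinements a complete ERBB model carries.  Passing tests
therefore demonstrate the correctness of the engine's semantics and the
qualitative phenomena (combinatorial explosion, site-specific kinetics),
not quantitative predictions about any real cell line.

## Problem sizes in the shipped checks

The packaged checks are sized for a single CPU: cross-simulator
comparisons use 200 runs per simulator on 3-species and 8-species toys;
the master-equation check solves an 11-state CME by matrix exponential
against 1,500 simulated runs (χ², α = 0.01); the equilibrium check uses
100 runs against the quadratic root (agreement within 3 combined
standard errors; the exact stochastic mean differs from the
deterministic root by ~0.1 molecule at n = 100, well inside that band);
matching equivalence uses 500+ random instances of ≤ 6 molecules against
exhaustive-search oracles; the explosion contrast runs the on-the-fly
simulator to a 40,000-species cap (~12× more species populated than
seeded, census nondecreasing) and fits the network-free events-vs-work
line over a 400 s run (R² > 0.99); detailed balance is audited over
1,000 sampled sets.

## Known limitations

* No functional (non-mass-action) rate laws, energy-based rules, or
  cBNGL compartment topology; `DeleteMolecules`-style whole-complex
  deletion is not modeled (deletion is inferred from the written diff).
* Intramolecular binding (ring closure) is excluded by the molecularity
  rule; polymers are chains, never rings.
* Rule-level detailed-balance enforcement assumes each reversible pair's
  K is a single degree of freedom; if one pair appears in conflicting
  cycles the set is rejected rather than resolved by splitting the rule.
* Canonical labelling and embedding search are exact but exponential in
  pathological dense graphs; they are intended for the short chains and
  trees that arise in signaling complexes.
* Parameter estimation against data is out of scope; ensembles express
  feasibility, not fit.
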
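# rulesim

Rule-based modeling of combinatorially complex cell-signaling networks.

Signaling proteins carry multiple binding domains and phosphorylation
sites, so even a handful of documented interactions implies an
astronomical number of distinct chemical species: an EGFR monomer whose
six tyrosines dock SHC1, GRB2 and their downstream partners already has
2·8·6·8·12·6·6 = 331,776 possible states, and a receptor dimer has
tens of billions.  Writing one ODE per species is hopeless.  Rule-based
models sidestep the explosion: the modeler writes *rules* — local graph
rewrites on molecules, components and bonds, each with a mass-action rate
constant — and the reaction network is defined implicitly.

`rulesim` is a self-contained engine for this style of modeling, aimed at
modelers who want to build, sanity-check, simulate and analyze
BNGL-style models without a large toolchain:

* **core / bngl** — an in-memory site-graph representation of molecule
  types, rules, seed species and observables, with machine-readable
  validation diagnostics, plus a reader/writer for a plain-text
  BNGL-subset dialect (grammar below).
* **matching** — site-graph pattern embedding enumeration, automorphism
  counting (mass-action symmetry factors), and canonical species labels.
* **network_free** — a particle-based stochastic simulator: rule firings
  are drawn from embedding counts, overlapping bimolecular selections are
  rejected as null events, and the cost per event is independent of the
  implied network size.
* **onthefly** — a population-based Gillespie simulator with lazy network
  generation, plus a census of populated species over time.  On
  combinatorially complex models it hits its species cap — that contrast
  with the network-free simulator is a feature, not a bug.
* **combinatorics** — exact enumeration of local site states (recursive
  adapter-complex trees with phospho-gating) and closed-form monomer and
  dimer state counts, in exact integer arithmetic.
* **ensemble** — log-uniform parameter sampling within six feasible
  ranges (association, dissociation, catalysis, trafficking, degradation,
  copy number), a diffusion cap on bimolecular rate constants, and
  detailed-balance enforcement on binding cycles (Wegscheider's
  condition: the product of K = k_f/k_r around every closed binding cycle
  equals 1).
* **analysis** — max-normalization and average-linkage/Pearson clustering
  of phosphorylation time courses; extraction of a machine-readable
  contact map (binding and enzyme-substrate edges) from any model.
* **fixtures** — programmatic toy models with known behavior and a
  reduced, original ERBB-family model (EGF/HRG ligands, EGFR/ERBB3,
  SHC1/GRB2/SOS1/GAB1/PI3K adapters, optional Ras→RAF→MEK→ERK and
  PI3K→Akt tiers with ERK→SOS1 negative feedback).

## The dialect

Block-structured plain text (`#` comments, UTF-8): `parameters`,
`compartments` (optional; `name dimension size [scale_factor]`),
`molecule types`, `seed species`, `observables`, `reaction rules`.
Molecules are written `Name(comp~state!bond,...)` with an optional
`@Compartment` tag; complexes join molecules with `.`, reaction sides
with `+`; rules use `->` or `<->` (two rates `kf, kr`; reversible rules
are stored as two linked unidirectional rules).  Bond markers: `!n`
explicit bond, `!+` bound to anything, `!?` bond unconstrained; a
component written without a bond marker is **unbound**, a component
omitted entirely is unconstrained.  `~?` (or omitting the state) leaves
the state unconstrained.  `0` denotes an empty reaction side.  Rates are
parameter names or numeric literals; no functional rate laws.

## Worked example

Count the receptor state space:

```sh
$ rulesim count-states
EGFR.ecto       2
EGFR.y1148      8
EGFR.y1068      6
EGFR.y1173      8
EGFR.y1114      12
EGFR.y1086      6
EGFR.y992       6
EGFR    331776
ERBB3.ecto      2
ERBB3.y1035     3
...
ERBB3.y1328     8
ERBB3   11664
EGFR:ERBB3      3869835264
EGFR:EGFR       55037822976
```

Each line is a site's local-state count (a SHC1 docking site has 8
states: unphosphorylated, phosphorylated, bound to SHC1 in each of its
six complex forms), then the monomer product, then the dimer counts —
the heterodimer is the product of monomer counts and the homodimer
counts unordered pairs, n(n+1)/2.

Simulate a two-protein binding equilibrium (100 A + 100 B, K such that
the mass-action quadratic predicts 50 complexes at equilibrium):

```sh
$ rulesim fixtures --out fx
$ rulesim simulate --model fx/binding.bngl --t-end 30 --sample-dt 5 --seed 7 --out demo
$ cat demo/trajectory.csv
time,AB,freeA,freeB
0.0,0,100,100
5.0,30,70,70
10.0,41,59,59
15.0,51,49,49
20.0,48,52,52
25.0,46,54,54
30.0,51,49,49
```

The complex count relaxes to and fluctuates around the deterministic
root (50).  The same model run with `--method otf` also writes
`census.csv` (populated species over time — here exactly 3).

Sample a thermodynamically consistent parameter set for a cooperative
two-ligand receptor (a genuine binding cycle):

```python
from rulesim import fixtures, ensemble
model = fixtures.build_toy("cooperative")
cmap = {p: ("bimolecular_association" if p.startswith("kon")
            else "unimolecular_dissociation") for p in model.parameters}
ens = ensemble.sample_parameters(model, cmap, n=1000, seed=1)
graph = ensemble.binding_cycle_graph(model)
ensemble.cycle_products(ens.sets[0], model, graph)   # -> [0.9999999999999998]
```

Every one of the 1000 sets closes its binding cycle to machine
precision; the `adjustments` report records which dissociation constants
were reset.

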
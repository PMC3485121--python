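"""Physically constrained parameter-ensemble sampling.

Model parameters fall into six classes, each with a feasible range spanning
two orders of magnitude:

=============================  ===========  =========================
class                          range        units
=============================  ===========  =========================
bimolecular_association       1e-7 – 1e-5   (molecules/cell)^-1 s^-1
unimolecular_dissociation     1e-2 – 1e0    s^-1
phosphatase_catalyzed         1e-3 – 1e-1   s^-1
receptor_trafficking          1e-3 – 1e-1   s^-1
endocytic_degradation         1e-3 – 1e-1   s^-1
copy_number                   1e4 – 1e6     molecules/cell
=============================  ===========  =========================

Values are drawn log-uniformly (the scale-free choice for ranges spanning
decades); bimolecular rate constants are additionally capped at the
diffusion limit; and every sampled set is post-processed so that reversible
*binding* equilibria satisfy detailed balance: the product of equilibrium
constants K = kf/kr around every closed binding cycle must equal one
(Wegscheider's condition).  Catalytic, trafficking and degradation steps are
irreversible, energy-consuming processes and are exempt.

The binding-cycle graph is built over a one-pot closed system: one copy of
each molecule type involved in reversible binding rules (two for homotypic
rules), with modifiable components held in their binding-permissive state.
Nodes are canonical multisets of complexes, edges are reversible rule
pairs; a spanning tree keeps tree-edge K's as sampled and each off-tree
edge's kr is reset so its fundamental-cycle product is exactly one.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.constants import Avogadro

from .core import (AddBond, Compartment, Component, Model, Molecule, Rule,
                   SiteGraph, connected_component_indices, subgraph,
                   union_graphs)
from .matching import canonical_label, find_embeddings

PARAM_CLASSES = {
    "bimolecular_association": (1e-7, 1e-5, "(molecules/cell)^-1 s^-1"),
    "unimolecular_dissociation": (1e-2, 1e0, "s^-1"),
    "phosphatase_catalyzed": (1e-3, 1e-1, "s^-1"),
    "receptor_trafficking": (1e-3, 1e-1, "s^-1"),
    "endocytic_degradation": (1e-3, 1e-1, "s^-1"),
    "copy_number": (1e4, 1e6, "molecules/cell"),
}

#: Default diffusion-limited ceiling for bimolecular association, equal to
#: the upper end of the feasible range in per-cell units.
DIFFUSION_CAP = 1e-5


@dataclass(frozen=True)
class ParameterClassSpec:
    class_name: str
    low: float
    high: float
    units: str

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid range for {self.class_name}: "
                             f"[{self.low}, {self.high}]")


def default_class_specs(diffusion_cap: float = DIFFUSION_CAP) \
        -> dict[str, ParameterClassSpec]:
    specs = {}
    for name, (lo, hi, units) in PARAM_CLASSES.items():
        if name == "bimolecular_association" and hi > diffusion_cap:
            hi = diffusion_cap
        specs[name] = ParameterClassSpec(name, lo, hi, units)
    return specs


@dataclass
class ParameterEnsemble:
    sets: list[dict[str, float]]
    seed: int
    class_map: dict[str, str]
    adjustments: list[list[dict]] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.sets)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_sets": len(self.sets),
            "class_map": self.class_map,
            "ranges": {k: [v.low, v.high, v.units]
                       for k, v in default_class_specs().items()},
            "n_adjusted": [len(a) for a in self.adjustments],
        }


# ---------------------------------------------------------------------------
# Binding-cycle analysis

@dataclass
class BindingCycleGraph:
    """Fundamental-cycle structure of a model's reversible binding rules.

    ``pairs`` lists (forward rule, reverse rule) with forward = the bond
    maker.  Each fundamental cycle is a list of (pair index, direction):
    detailed balance requires prod K_i^dir_i = 1 over every cycle, where
    K_i = kf_i / kr_i.  ``free_pair`` per cycle is the off-tree pair whose
    kr is adjusted during enforcement.
    """

    pairs: list[tuple[Rule, Rule]]
    cycles: list[list[tuple[int, int]]]
    free_pair: list[int]
    n_states: int


def reversible_binding_pairs(model: Model) -> list[tuple[Rule, Rule]]:
    pairs = []
    seen = set()
    for rule in model.rules:
        if rule.reversible_partner is None or rule.name in seen:
            continue
        try:
            partner = model.rule_by_name(rule.reversible_partner)
        except KeyError:
            continue
        seen.add(rule.name)
        seen.add(partner.name)
        fwd, rev = rule, partner
        if not any(isinstance(t, AddBond) for t in fwd.transformations):
            fwd, rev = rev, fwd
        if any(isinstance(t, AddBond) for t in fwd.transformations):
            pairs.append((fwd, rev))
    return pairs


def _permissive_monomer(model: Model, typename: str) -> SiteGraph:
    mt = model.molecule_types[typename]
    comps = [Component(cd.name, cd.states[-1] if cd.states else None)
             for cd in mt.components]
    return SiteGraph([Molecule(typename, comps, mt.home_compartment)])


def _apply_pair_rule(model: Model, rule: Rule,
                     complexes: list[SiteGraph]) -> list[tuple]:
    """All outcomes of applying a rule to a multiset of complexes.

    Returns (consumed indices, produced graphs) per distinct application.
    """
    out = []
    n = len(rule.reactants)
    if n == 1:
        for i, g in enumerate(complexes):
            for emb in find_embeddings(rule.reactants[0], g):
                prods = _apply_emb(model, rule, [g], [emb])
                out.append(((i,), prods))
    elif n == 2:
        for i, j in itertools.permutations(range(len(complexes)), 2):
            if i > j and canonical_label(complexes[i]) == \
                    canonical_label(complexes[j]):
                continue  # symmetric duplicate
            g0, g1 = complexes[i], complexes[j]
            for e0 in find_embeddings(rule.reactants[0], g0):
                for e1 in find_embeddings(rule.reactants[1], g1):
                    prods = _apply_emb(model, rule, [g0, g1], [e0, e1])
                    out.append(((i, j), prods))
    return out


def _apply_emb(model: Model, rule: Rule, graphs, embs) -> list[SiteGraph]:
    from .onthefly import ReactionNetwork  # reuse the species-level applier
    net = ReactionNetwork.__new__(ReactionNetwork)
    net.model = model
    net.species = {}
    net.order = []
    net.populations = []
    net.max_species = 10_000
    net.truncated = False
    labels = net._apply(rule, list(graphs), list(embs))
    return [net.species[lb].graph for lb in labels]


def binding_cycle_graph(model: Model,
                        max_states: int = 2000) -> BindingCycleGraph:
    """Enumerate the one-pot binding state graph and its fundamental cycles."""
    pairs = reversible_binding_pairs(model)
    if not pairs:
        return BindingCycleGraph(pairs, [], [], 0)

    types: dict[str, int] = {}
    for fwd, _ in pairs:
        counts: dict[str, int] = {}
        for g in fwd.reactants:
            for mol in g.molecules:
                counts[mol.typename] = counts.get(mol.typename, 0) + 1
        for t, c in counts.items():
            types[t] = max(types.get(t, 0), c)

    pot = []
    for t in sorted(types):
        for _ in range(types[t]):
            pot.append(_permissive_monomer(model, t))

    def state_key(complexes: list[SiteGraph]) -> tuple[str, ...]:
        return tuple(sorted(canonical_label(g) for g in complexes))

    init = pot
    init_key = state_key(init)
    states: dict[tuple, list[SiteGraph]] = {init_key: init}
    edges: list[tuple[tuple, tuple, int]] = []   # (u, v, pair index)
    edge_seen: set = set()
    queue = [init_key]
    qi = 0
    while qi < len(queue):
        u = queue[qi]
        qi += 1
        complexes = states[u]
        for pi, (fwd, rev) in enumerate(pairs):
            for direction, rule in ((1, fwd), (-1, rev)):
                for consumed, produced in _apply_pair_rule(model, rule,
                                                           complexes):
                    nxt = [g for i, g in enumerate(complexes)
                           if i not in consumed] + list(produced)
                    vkey = state_key(nxt)
                    if vkey not in states:
                        if len(states) >= max_states:
                            continue
                        states[vkey] = nxt
                        queue.append(vkey)
                    a, b = (u, vkey) if direction == 1 else (vkey, u)
                    ek = (a, b, pi)
                    if a != b and ek not in edge_seen:
                        edge_seen.add(ek)
                        edges.append((a, b, pi))

    # Spanning tree (BFS on the undirected multigraph), then one fundamental
    # cycle per off-tree edge.
    adjacency: dict[tuple, list[tuple]] = {}
    for a, b, pi in edges:
        adjacency.setdefault(a, []).append((b, pi, 1))
        adjacency.setdefault(b, []).append((a, pi, -1))
    parent: dict[tuple, Optional[tuple]] = {init_key: None}
    parent_edge: dict[tuple, tuple[int, int]] = {}
    tree_edges: set = set()
    bfs = [init_key]
    bi = 0
    while bi < len(bfs):
        u = bfs[bi]
        bi += 1
        for v, pi, direction in sorted(adjacency.get(u, []),
                                       key=lambda e: (e[0], e[1])):
            if v not in parent:
                parent[v] = u
                parent_edge[v] = (pi, direction)
                tree_edges.add(frozenset((u, v)) if u != v else (u, v))
                tree_edges.add((u, v, pi))
                bfs.append(v)

    def path_to_root(u: tuple) -> list[tuple[int, int]]:
        out = []
        while parent[u] is not None:
            pi, direction = parent_edge[u]
            out.append((pi, direction))
            u = parent[u]
        return out

    cycles = []
    free = []
    seen_cycle_sets = set()
    for a, b, pi in edges:
        if (a, b, pi) in tree_edges or (b, a, pi) in tree_edges:
            continue
        # constraint g(b) - g(a) = lnK_pi with g the tree potential, i.e.
        # lnK_pi + g(a) - g(b) = 0
        steps = [(pi, 1)]
        pa = path_to_root(a)
        pb = path_to_root(b)
        steps.extend(pa)                                   # + g(a)
        steps.extend((qi_, -d) for qi_, d in pb)           # - g(b)
        net_dir: dict[int, int] = {}
        for qi_, d in steps:
            net_dir[qi_] = net_dir.get(qi_, 0) + d
        reduced = sorted((q, d) for q, d in net_dir.items() if d != 0)
        if not reduced:
            continue
        key = tuple(reduced)
        if key in seen_cycle_sets:
            continue
        seen_cycle_sets.add(key)
        cycles.append(reduced)
        free.append(pi)
    return BindingCycleGraph(pairs, cycles, free, len(states))


def cycle_products(param_set: dict[str, float], model: Model,
                   graph: Optional[BindingCycleGraph] = None) -> list[float]:
    """Recompute all fundamental-cycle equilibrium products from scratch."""
    graph = graph or binding_cycle_graph(model)
    out = []
    for cyc in graph.cycles:
        prod = 1.0
        for pi, d in cyc:
            fwd, rev = graph.pairs[pi]
            K = _rate_of(param_set, model, fwd) / _rate_of(param_set, model, rev)
            prod *= K ** d
        out.append(prod)
    return out


def _rate_of(param_set: dict, model: Model, rule: Rule) -> float:
    rp = rule.rate_param
    if isinstance(rp, (int, float)):
        return float(rp)
    if rp in param_set:
        return float(param_set[rp])
    return float(model.parameters[rp].value)


def enforce_detailed_balance(param_set: dict[str, float], model: Model,
                             class_map: Optional[dict[str, str]] = None,
                             graph: Optional[BindingCycleGraph] = None,
                             rng: Optional[np.random.Generator] = None,
                             tol: float = 1e-9,
                             max_retries: int = 20) \
        -> tuple[dict[str, float], list[dict]]:
    """Adjust off-tree kr's so every fundamental-cycle product equals one.

    Returns the adjusted parameter set and a report of changed parameters.
    Raises if an adjusted value cannot be kept within its class range.
    """
    graph = graph or binding_cycle_graph(model)
    ps = dict(param_set)
    specs = default_class_specs()
    report: list[dict] = []
    adjusted: set[int] = set()
    for cyc, free_pi in zip(graph.cycles, graph.free_pair):
        fwd, rev = graph.pairs[free_pi]
        free_dir = dict(cyc)[free_pi]
        rest = 1.0
        for pi, d in cyc:
            if pi == free_pi:
                continue
            K = _rate_of(ps, model, graph.pairs[pi][0]) / \
                _rate_of(ps, model, graph.pairs[pi][1])
            rest *= K ** d
        # need K_free ** free_dir * rest == 1
        K_req = rest ** (-1.0 / free_dir)
        if free_pi in adjusted:
            K_now = _rate_of(ps, model, fwd) / _rate_of(ps, model, rev)
            if abs(K_now / K_req - 1) > tol:
                raise ValueError(
                    f"conflicting detailed-balance constraints on rule pair "
                    f"{fwd.name}/{rev.name}")
            continue
        kf_name = fwd.rate_param
        kr_name = rev.rate_param
        if not isinstance(kr_name, str):
            raise ValueError(f"rule {rev.name}: literal rate cannot be "
                             "adjusted for detailed balance")
        kf = _rate_of(ps, model, fwd)
        old_kr = _rate_of(ps, model, rev)
        new_kr = kf / K_req
        cls = (class_map or {}).get(kr_name)
        if cls and cls in specs:
            lo, hi = specs[cls].low, specs[cls].high
            tries = 0
            while not (lo <= new_kr <= hi):
                # redraw kf within the feasible window so kr lands in range
                kf_cls = (class_map or {}).get(kf_name) \
                    if isinstance(kf_name, str) else None
                if kf_cls not in specs or rng is None:
                    raise ValueError(
                        f"detailed-balance adjustment pushes {kr_name} to "
                        f"{new_kr:.3g}, outside its class range "
                        f"[{lo:.3g}, {hi:.3g}]")
                flo = max(specs[kf_cls].low, K_req * lo)
                fhi = min(specs[kf_cls].high, K_req * hi)
                if not (flo <= fhi) or tries >= max_retries:
                    raise ValueError(
                        f"cannot satisfy detailed balance for pair "
                        f"{fwd.name}/{rev.name} within class ranges")
                kf = float(np.exp(rng.uniform(np.log(flo), np.log(fhi))))
                report.append({"param": kf_name, "old": ps.get(kf_name),
                               "new": kf, "reason": "detailed_balance_redraw"})
                ps[kf_name] = kf
                new_kr = kf / K_req
                tries += 1
        report.append({"param": kr_name, "old": old_kr, "new": new_kr,
                       "reason": "detailed_balance"})
        ps[kr_name] = new_kr
        adjusted.add(free_pi)
    return ps, report


# ---------------------------------------------------------------------------
# Sampling

def sample_parameters(model: Model, class_map: dict[str, str], n: int,
                      seed: int,
                      diffusion_cap: float = DIFFUSION_CAP,
                      enforce_balance: bool = True,
                      tol: float = 1e-9) -> ParameterEnsemble:
    """Draw ``n`` parameter sets, log-uniform within each class range.

    ``class_map`` assigns every model parameter a class name or ``"fixed"``
    (kept at its model value).  Copy-number draws are rounded to integers.
    With ``enforce_balance`` every set is post-processed so all binding
    cycles satisfy detailed balance.
    """
    specs = default_class_specs(diffusion_cap)
    unassigned = [p for p in model.parameters if p not in class_map]
    if unassigned:
        raise ValueError("parameters without a class assignment: "
                         + ", ".join(sorted(unassigned)))
    bad = {c for c in class_map.values()
           if c != "fixed" and c not in specs}
    if bad:
        raise ValueError(f"unknown parameter classes: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    graph = binding_cycle_graph(model) if enforce_balance else None
    sets = []
    adjustments = []

    def draw_set() -> dict[str, float]:
        ps: dict[str, float] = {}
        for pname, param in model.parameters.items():
            cls = class_map[pname]
            if cls == "fixed":
                ps[pname] = float(param.value)
                continue
            spec = specs[cls]
            val = float(np.exp(rng.uniform(np.log(spec.low),
                                           np.log(spec.high))))
            if cls == "copy_number":
                val = float(int(round(val)))
            ps[pname] = val
        return ps

    # Rejection sampling: if the cycle-closure constraint cannot be met
    # within the class ranges for a draw (the feasible window for the
    # off-tree edge can be empty), the whole set is redrawn, which keeps the
    # accepted sets log-uniform *conditioned on* detailed balance.
    max_set_retries = 200
    for _ in range(n):
        for attempt in range(max_set_retries):
            ps = draw_set()
            if enforce_balance and graph and graph.cycles:
                try:
                    ps, report = enforce_detailed_balance(
                        ps, model, class_map, graph, rng, tol)
                except ValueError:
                    continue
            else:
                report = []
            break
        else:
            raise ValueError(
                "could not satisfy detailed balance within class ranges "
                f"after {max_set_retries} redraws")
        sets.append(ps)
        adjustments.append(report)
    return ParameterEnsemble(sets, seed, dict(class_map), adjustments)


def convert_concentration(value_molar: float,
                          compartment: Compartment) -> int:
    """Copies per cell for a molar concentration in a 3-D compartment.

    copies = round(concentration x Avogadro x effective volume), with the
    compartment's scale factor applied to its volume (litres).
    """
    if compartment.dimension != 3:
        raise ValueError(
            f"compartment {compartment.name} is {compartment.dimension}-D; "
            "membrane species must be specified as copy numbers")
    if value_molar < 0:
        raise ValueError("concentration must be nonnegative")
    return int(round(value_molar * Avogadro * compartment.effective_size))
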
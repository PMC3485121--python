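"""Population-based SSA with lazy (on-the-fly) reaction-network generation.

Species are concrete site graphs identified by canonical label; reactions
are generated by expanding rules against the species discovered so far.
Expansion is *lazy*: a species' reactions are enumerated only once it is
populated, so the network grows with the simulation — the hallmark (and,
on combinatorially complex models, the downfall) of this approach: the
generated network can explode while a network-free simulation of the same
model keeps a constant per-event cost.

Rate conventions match :mod:`rulesim.network_free` exactly (symmetry factor
= automorphisms of the full reactant side; bimolecular channels require two
distinct complexes), so the two simulators are statistically interchangeable
on any model both can handle — which the test-suite exploits.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import bngl
from .core import (AddBond, ChangeCompartment, ChangeState, CreateMolecule,
                   DeleteBond, DeleteMolecule, Component, Model, Molecule,
                   Rule, SiteGraph, connected_component_indices, subgraph,
                   union_graphs, validate_model)
from .matching import canonical_label, count_automorphisms, find_embeddings
from .trajectory import Addition, ParamSwitch, Protocol, Trajectory, sample_grid


class NetworkCapReached(RuntimeError):
    pass


@dataclass
class SpeciesRec:
    label: str
    graph: SiteGraph
    index: int
    expanded: bool = False


@dataclass
class Reaction:
    reactants: tuple[str, ...]       # 0, 1 or 2 species labels
    products: tuple[str, ...]
    c: float                         # stochastic rate coefficient
    rule: str
    multiplicity: int


class ReactionNetwork:
    """Species and reactions generated so far, plus populations."""

    def __init__(self, model: Model, params: Optional[dict] = None,
                 max_species: int = 50_000):
        diags = [d for d in validate_model(model) if d.severity == "error"]
        if diags:
            raise ValueError("model has validation errors: "
                             + "; ".join(f"{d.location}: {d.message}"
                                         for d in diags[:5]))
        self.model = model
        self.params = dict(params or {})
        self.max_species = max_species
        self.species: dict[str, SpeciesRec] = {}
        self.order: list[str] = []          # insertion order
        self.populations: list[int] = []
        self.reactions: list[Reaction] = []
        self._processed: set = set()        # (rule_idx, reactant label key)
        self._emb_cache: dict = {}          # (pattern id, species idx) -> embs
        self.truncated = False

        self._rule_sym: list[int] = []
        self._rule_k: list[float] = []
        for rule in model.rules:
            union, _ = union_graphs(rule.reactants)
            self._rule_sym.append(count_automorphisms(union)
                                  if union.molecules else 1)
            self._rule_k.append(model.rate_value(rule, self.params))

        # zero-order (synthesis) rules fire unconditionally
        for ri, rule in enumerate(model.rules):
            if not rule.reactants:
                prods = self._apply(rule, [], [])
                self.reactions.append(Reaction(
                    (), prods, self._rule_k[ri], rule.name, 1))

        for g, copies in model.seed_species:
            rec = self.intern(g)
            self.populations[rec.index] += copies

    # -- species table -------------------------------------------------------

    def intern(self, graph: SiteGraph) -> SpeciesRec:
        label = canonical_label(graph)
        rec = self.species.get(label)
        if rec is None:
            if len(self.species) >= self.max_species:
                self.truncated = True
                raise NetworkCapReached(
                    f"network cap of {self.max_species} species reached")
            rec = SpeciesRec(label, graph.copy(), len(self.order))
            self.species[label] = rec
            self.order.append(label)
            self.populations.append(0)
        return rec

    @property
    def frontier(self) -> list[str]:
        return [lb for lb in self.order if not self.species[lb].expanded]

    def populated_count(self) -> int:
        return int(sum(1 for p in self.populations if p >= 1))

    # -- rule application at species level -----------------------------------

    def _apply(self, rule: Rule, graphs: list[SiteGraph],
               embs: list) -> tuple[str, ...]:
        """Apply a rule to one embedding combination; returns product labels."""
        union, offsets = union_graphs(graphs)
        # flat rule molecule index -> union graph (mol, comp map)
        flat: dict[int, tuple[int, tuple]] = {}
        pat_off = 0
        for si, emb in enumerate(embs):
            for mi, (tmol, cmap) in enumerate(emb):
                flat[pat_off + mi] = (offsets[si] + tmol, cmap)
            pat_off += len(rule.reactants[si].molecules)
        n_r = pat_off
        g = union.copy()
        deleted: set[int] = set()
        created = 0
        for tf in rule.transformations:
            if isinstance(tf, ChangeState):
                gm, cmap = flat[tf.site[0]]
                g.molecules[gm].comps[cmap[tf.site[1]]].state = tf.state
            elif isinstance(tf, DeleteBond):
                (ga, ca) = flat[tf.a[0]][0], flat[tf.a[0]][1][tf.a[1]]
                (gb, cb) = flat[tf.b[0]][0], flat[tf.b[0]][1][tf.b[1]]
                g.delete_bond((ga, ca), (gb, cb))
            elif isinstance(tf, AddBond):
                (ga, ca) = flat[tf.a[0]][0], flat[tf.a[0]][1][tf.a[1]]
                (gb, cb) = flat[tf.b[0]][0], flat[tf.b[0]][1][tf.b[1]]
                g.add_bond((ga, ca), (gb, cb))
            elif isinstance(tf, CreateMolecule):
                mt = self.model.molecule_types[tf.typename]
                mol = Molecule(tf.typename,
                               [Component(n, s) for n, s in tf.comps],
                               tf.compartment or mt.home_compartment)
                g.molecules.append(mol)
                flat[n_r + created] = (len(g.molecules) - 1,
                                      tuple(range(len(mol.comps))))
                created += 1
            elif isinstance(tf, DeleteMolecule):
                gm = flat[tf.mol][0]
                for ci, comp in enumerate(g.molecules[gm].comps):
                    if isinstance(comp.bond, int):   # break dangling bonds
                        lbl = comp.bond
                        for mj, mol in enumerate(g.molecules):
                            for cj, c2 in enumerate(mol.comps):
                                if c2.bond == lbl:
                                    c2.bond = None
                deleted.add(gm)
            elif isinstance(tf, ChangeCompartment):
                g.molecules[flat[tf.mol][0]].compartment = tf.compartment
        g.molecules = [m for i, m in enumerate(g.molecules) if i not in deleted]
        g.renumber_bonds()
        labels = []
        for idx in connected_component_indices(g):
            labels.append(self.intern(subgraph(g, idx)).label)
        return tuple(sorted(labels))

    def _embeddings(self, pattern: SiteGraph, rec: SpeciesRec) -> list:
        key = (id(pattern), rec.index)
        hit = self._emb_cache.get(key)
        if hit is None:
            hit = find_embeddings(pattern, rec.graph)
            self._emb_cache[key] = hit
        return hit

    def expand_species(self, label: str) -> None:
        """Enumerate all reactions whose reactants are previously expanded
        species or this one; novel products join the species table.

        Idempotent: expanding twice adds nothing.
        """
        rec = self.species[label]
        if rec.expanded:
            return
        expanded_before = [lb for lb in self.order
                           if self.species[lb].expanded]
        partners = expanded_before + [label]
        for ri, rule in enumerate(self.model.rules):
            k, sym = self._rule_k[ri], self._rule_sym[ri]
            if len(rule.reactants) == 1:
                key = (ri, (label,))
                if key in self._processed:
                    continue
                self._processed.add(key)
                embs = self._embeddings(rule.reactants[0], rec)
                groups: dict[tuple, int] = {}
                for e in embs:
                    prods = self._apply(rule, [rec.graph], [e])
                    groups[prods] = groups.get(prods, 0) + 1
                for prods, mult in sorted(groups.items()):
                    self.reactions.append(Reaction(
                        (label,), prods, k * mult / sym, rule.name, mult))
            elif len(rule.reactants) == 2:
                p0, p1 = rule.reactants
                for partner in partners:
                    key = (ri, tuple(sorted((label, partner))))
                    if key in self._processed:
                        continue
                    self._processed.add(key)
                    pair_recs = [self.species[x] for x in (label, partner)]
                    groups: dict[tuple, int] = {}
                    assignments = [(0, 1), (1, 0)] if label != partner else [(0, 1)]
                    for a0, a1 in assignments:
                        r0, r1 = pair_recs[a0], pair_recs[a1]
                        g0, g1 = r0.graph, r1.graph
                        e0s = self._embeddings(p0, r0)
                        if not e0s:
                            continue
                        e1s = self._embeddings(p1, r1)
                        for e0 in e0s:
                            for e1 in e1s:
                                prods = self._apply(rule, [g0, g1], [e0, e1])
                                groups[prods] = groups.get(prods, 0) + 1
                    for prods, mult in sorted(groups.items()):
                        self.reactions.append(Reaction(
                            tuple(sorted((label, partner))), prods,
                            k * mult / sym, rule.name, mult))
        rec.expanded = True

    def expand_all(self) -> None:
        """Eagerly expand the frontier to exhaustion (full enumeration)."""
        i = 0
        while i < len(self.order):
            self.expand_species(self.order[i])
            i += 1

    def to_json(self) -> dict:
        return {
            "species": [{"label": lb,
                         "population": self.populations[self.species[lb].index]}
                        for lb in self.order],
            "reactions": [{"reactants": list(r.reactants),
                           "products": list(r.products),
                           "c": r.c, "rule": r.rule,
                           "multiplicity": r.multiplicity}
                          for r in self.reactions],
            "truncated": self.truncated,
        }


def generate_network(model: Model, params: Optional[dict] = None,
                     max_species: int = 50_000) -> ReactionNetwork:
    """Full (eager) network generation from the seed species."""
    net = ReactionNetwork(model, params, max_species)
    net.expand_all()
    return net


# ---------------------------------------------------------------------------
# Simulation

def _model_hash(model: Model) -> str:
    return hashlib.sha256(bngl.write_model(model).encode()).hexdigest()[:16]


class _ObsEval:
    """Per-species observable weights, extended as species appear."""

    def __init__(self, model: Model):
        self.model = model
        self.weights: list[list[int]] = [[] for _ in model.observables]
        self.matches: list[list[bool]] = [[] for _ in model.observables]
        self._auts = {id(p): max(1, count_automorphisms(p))
                      for o in model.observables for p in o.patterns}

    def extend(self, net: ReactionNetwork) -> None:
        n = len(net.order)
        for oi, obs in enumerate(self.model.observables):
            while len(self.weights[oi]) < n:
                lb = net.order[len(self.weights[oi])]
                g = net.species[lb].graph
                w = 0
                for pat in obs.patterns:
                    ne = len(find_embeddings(pat, g))
                    w += ne // self._auts[id(pat)]
                self.weights[oi].append(w)
                self.matches[oi].append(w > 0)

    def values(self, net: ReactionNetwork, pops: np.ndarray) -> list[int]:
        self.extend(net)
        out = []
        for oi, obs in enumerate(self.model.observables):
            w = np.asarray(self.weights[oi][:len(pops)])
            if obs.kind == "Molecules":
                out.append(int((w * pops).sum()))
            else:
                m = np.asarray(self.matches[oi][:len(pops)])
                out.append(int(((pops >= 1) & m).sum()))
        return out


def run(model: Model, params: Optional[dict] = None,
        protocol: Optional[Protocol] = None, t_end: float = 100.0,
        sample_dt: float = 1.0, seed: int = 0,
        scale: Optional[float] = None,
        max_species: int = 50_000) -> tuple[Trajectory, pd.DataFrame]:
    """Gillespie direct-method simulation over the lazily generated network.

    Returns the observable trajectory and a species census: per sample time,
    the number of currently populated species (population >= 1), the total
    number of species generated so far, and the total reactions generated.
    Hitting the species cap is a reportable outcome: the run stops early and
    the partial results carry ``metadata["truncated"] = True``.
    """
    protocol = protocol or Protocol()
    net = ReactionNetwork(model, params, max_species)
    rng = np.random.default_rng(seed)
    obs_eval = _ObsEval(model)

    # Seed scaling mirrors the network-free simulator's convention.
    if scale is not None or any(c.scale_factor != 1.0
                                for c in model.compartments.values()):
        net.populations = [0] * len(net.populations)
        for g, copies in model.seed_species:
            eff = scale
            if eff is None:
                mol = g.molecules[0]
                comp = mol.compartment
                if comp is None:
                    mt = model.molecule_types.get(mol.typename)
                    comp = mt.home_compartment if mt else None
                eff = (model.compartments[comp].scale_factor
                       if comp in model.compartments else 1.0)
            rec = net.intern(g)
            net.populations[rec.index] += int(round(copies * eff))

    truncated = False
    try:
        for lb in list(net.order):
            if net.populations[net.species[lb].index] >= 1:
                net.expand_species(lb)
    except NetworkCapReached:
        truncated = True

    pops = np.array(net.populations, dtype=np.int64)

    def sync_pops():
        nonlocal pops
        if len(pops) < len(net.populations):
            pops = np.concatenate([pops, np.zeros(
                len(net.populations) - len(pops), dtype=np.int64)])

    sync_pops()

    # Cached reaction index arrays for vectorized propensities; rebuilt
    # whenever expansion appends reactions.
    _rx_cache: dict = {"n": -1}

    def _rx_arrays():
        if _rx_cache["n"] != len(net.reactions):
            n = len(net.reactions)
            c = np.empty(n)
            i1 = np.zeros(n, dtype=np.int64)
            i2 = np.zeros(n, dtype=np.int64)
            kind = np.zeros(n, dtype=np.int8)  # 0 zero-order, 1 uni, 2 bi, 3 bi-same
            for i, rx in enumerate(net.reactions):
                c[i] = rx.c
                if not rx.reactants:
                    kind[i] = 0
                elif len(rx.reactants) == 1:
                    kind[i] = 1
                    i1[i] = net.species[rx.reactants[0]].index
                else:
                    a = net.species[rx.reactants[0]].index
                    b = net.species[rx.reactants[1]].index
                    i1[i], i2[i] = a, b
                    kind[i] = 3 if a == b else 2
            _rx_cache.update(n=n, c=c, i1=i1, i2=i2, kind=kind)
        return _rx_cache

    def propensities() -> np.ndarray:
        a = _rx_arrays()
        x1 = pops[a["i1"]]
        x2 = pops[a["i2"]]
        prop = a["c"] * np.where(
            a["kind"] == 0, 1.0,
            np.where(a["kind"] == 1, x1,
                     np.where(a["kind"] == 2, x1 * x2, x1 * (x1 - 1))))
        return prop

    time = 0.0
    events = 0

    def advance_to(t_target: float) -> None:
        nonlocal time, events, truncated
        while time < t_target and not truncated:
            prop = propensities()
            total = float(prop.sum())
            if total <= 0:
                time = t_target
                return
            dt = rng.exponential(1.0 / total)
            if time + dt > t_target:
                time = t_target
                return
            u = rng.random() * total
            ridx = int(np.searchsorted(np.cumsum(prop), u, side="right"))
            ridx = min(ridx, len(net.reactions) - 1)
            rx = net.reactions[ridx]
            time += dt
            events += 1
            for lb in rx.reactants:
                pops[net.species[lb].index] -= 1
            newly = []
            for lb in rx.products:
                idx = net.species[lb].index
                sync_pops()
                pops[idx] += 1
                if pops[idx] == 1 and not net.species[lb].expanded:
                    newly.append(lb)
            for lb in newly:
                try:
                    net.expand_species(lb)
                except NetworkCapReached:
                    truncated = True
                    return
                sync_pops()

    if protocol.equilibrate > 0:
        advance_to(protocol.equilibrate)
        time = 0.0

    grid = sample_grid(t_end, sample_dt)
    values = []
    census_rows = []
    times_done = []
    evq = protocol.events()
    ei = 0
    for t in grid:
        while ei < len(evq) and evq[ei][0] <= t:
            advance_to(evq[ei][0])
            ev = evq[ei][1]
            if isinstance(ev, Addition):
                g = ev.species if isinstance(ev.species, SiteGraph) \
                    else bngl.parse_pattern(ev.species)
                try:
                    rec = net.intern(g)
                    sync_pops()
                    pops[rec.index] += ev.copies
                    if not rec.expanded and pops[rec.index] >= 1:
                        net.expand_species(rec.label)
                        sync_pops()
                except NetworkCapReached:
                    truncated = True
            elif isinstance(ev, ParamSwitch):
                raise NotImplementedError(
                    "parameter switching requires rebuilding generated "
                    "reaction coefficients; not supported in the on-the-fly "
                    "simulator")
            ei += 1
        advance_to(t)
        times_done.append(time if truncated else t)
        values.append(obs_eval.values(net, pops))
        census_rows.append({
            "time": times_done[-1],
            "populated_species": int((pops >= 1).sum()),
            "total_species_generated": len(net.order),
            "total_reactions_generated": len(net.reactions),
        })
        if truncated:
            break

    traj = Trajectory(np.array(times_done), np.array(values, dtype=np.int64),
                      [o.name for o in model.observables],
                      metadata={"method": "on-the-fly", "seed": seed,
                                "model_hash": _model_hash(model),
                                "events": events,
                                "truncated": bool(truncated),
                                "species_generated": len(net.order),
                                "reactions_generated": len(net.reactions)})
    census = pd.DataFrame(census_rows)
    traj.network = net  # expose for census/debug inspection
    return traj, census
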
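"""Particle-based (network-free) stochastic simulator.

Individual molecules are tracked as particles carrying component states and
bonds; rule firings are sampled from per-rule embedding counts, so the cost
per reaction event depends on the number of particles, rules, and pattern
sizes — never on the number of chemical species or reactions the rules
imply.  The algorithm is the rejection-based network-free scheme: embeddings
for a selected rule are drawn uniformly and selections that overlap (same
particle or same complex for a bimolecular rule) are *null events* — time
advances, nothing changes — which preserves exactness of the underlying
chemical master equation.

Conventions (shared with the on-the-fly simulator so the two are mutually
consistent oracles):

* a rule's propensity is ``k / sym`` times the product of its reactant
  pattern embedding counts, with ``n (n-1)`` for a bimolecular rule whose
  two patterns are identical; ``sym`` is the automorphism count of the full
  reactant side, so an A+A rule is not double-counted;
* a 2-reactant rule requires its two embeddings to lie in distinct
  complexes (no ring closure);
* Molecules observables count embeddings divided by the pattern's
  automorphisms; Species observables count distinct complexes containing a
  match.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import bngl
from .core import (AddBond, ChangeCompartment, ChangeState, CreateMolecule,
                   DeleteBond, DeleteMolecule, Model, Rule, SiteGraph,
                   connected_component_indices, validate_model)
from .matching import (MatchCounter, count_automorphisms, find_embeddings,
                       pattern_info)
from .core import union_graphs
from .trajectory import Addition, ParamSwitch, Protocol, Trajectory, sample_grid


class SimulationError(RuntimeError):
    pass


class Particle:
    """One molecule instance: per-component state and bond partner."""

    __slots__ = ("pid", "typename", "comp_names", "states", "bonds",
                 "compartment")

    def __init__(self, pid, typename, comp_names, states, bonds, compartment):
        self.pid = pid
        self.typename = typename
        self.comp_names = comp_names      # tuple, from the molecule type def
        self.states = states              # list[Optional[str]]
        self.bonds = bonds                # list[Optional[(pid, cidx)]]
        self.compartment = compartment


class _EmbSet:
    """Set of embeddings with O(1) insert/remove/uniform-sample."""

    __slots__ = ("items", "pos")

    def __init__(self):
        self.items: list = []
        self.pos: dict = {}

    def __len__(self):
        return len(self.items)

    def add(self, emb):
        if emb not in self.pos:
            self.pos[emb] = len(self.items)
            self.items.append(emb)

    def remove(self, emb):
        i = self.pos.pop(emb)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i


@dataclass
class _PatternSlot:
    pattern: SiteGraph
    automorphisms: int
    embs: _EmbSet = field(default_factory=_EmbSet)


@dataclass
class _RuleRuntime:
    rule: Rule
    k: float
    sym: int
    slots: list[_PatternSlot]
    same_pattern: bool
    offsets: list[int]          # flattened molecule index offset per slot


def match_particles(pattern: SiteGraph, particles: dict[int, Particle],
                    candidates: list[int],
                    counter: Optional[MatchCounter] = None) -> list[tuple]:
    """All embeddings of a (connected) pattern into the particle mixture.

    Returns tuples over pattern molecules of ``(pid, comp_assignment)``.
    Mirrors :func:`rulesim.matching.find_embeddings` but works directly on
    particle bond pointers so no global adjacency is ever materialized.
    """
    np_ = len(pattern.molecules)
    if np_ == 0:
        return []
    p_neighbors, order, bonds, _ = pattern_info(pattern)
    results = []
    mol_assign: dict[int, int] = {}
    comp_assign: dict[int, tuple] = {}
    used: set[int] = set()

    def mol_options(pmol, part):
        if pmol.typename != part.typename:
            return []
        if pmol.compartment is not None and pmol.compartment != part.compartment:
            return []
        cands = []
        for pc in pmol.comps:
            cs = []
            for ti, tname in enumerate(part.comp_names):
                if counter is not None:
                    counter.checks += 1
                if tname != pc.name:
                    continue
                if pc.state is not None and pc.state != part.states[ti]:
                    continue
                b = part.bonds[ti]
                if pc.bond is None and b is not None:
                    continue
                if pc.bond == "+" and b is None:
                    continue
                if isinstance(pc.bond, int) and b is None:
                    continue
                cs.append(ti)
            if not cs:
                return []
            cands.append(cs)
        out = []

        def rec(i, usedc, acc):
            if i == len(cands):
                out.append(tuple(acc))
                return
            for ti in cands[i]:
                if ti not in usedc:
                    usedc.add(ti)
                    acc.append(ti)
                    rec(i + 1, usedc, acc)
                    acc.pop()
                    usedc.remove(ti)

        rec(0, set(), [])
        return out

    def bonds_ok():
        for (mi, ci), (mj, cj) in bonds:
            if mi in mol_assign and mj in mol_assign:
                pi = particles[mol_assign[mi]]
                tci = comp_assign[mi][ci]
                if pi.bonds[tci] != (mol_assign[mj], comp_assign[mj][cj]):
                    return False
        return True

    def rec(k):
        if k == np_:
            if bonds_ok():
                results.append(tuple((mol_assign[i], comp_assign[i])
                                     for i in range(np_)))
            return
        mi = order[k]
        pmol = pattern.molecules[mi]
        cand = candidates
        for nb in p_neighbors[mi]:
            if nb in mol_assign:
                part = particles[mol_assign[nb]]
                linked = {b[0] for b in part.bonds if b is not None}
                cand = [p for p in cand if p in linked]
                break
        for pid in sorted(cand):
            if pid in used:
                continue
            part = particles.get(pid)
            if part is None:
                continue
            for ca in mol_options(pmol, part):
                mol_assign[mi] = pid
                comp_assign[mi] = ca
                used.add(pid)
                rec(k + 1)
                used.discard(pid)
                del mol_assign[mi]
                del comp_assign[mi]

    rec(0)
    results.sort()
    return results


def complex_of(particles: dict[int, Particle], start: list[int]) -> set[int]:
    """All particle ids bond-connected to the given seed particles."""
    seen = set(start)
    stack = list(start)
    while stack:
        pid = stack.pop()
        for b in particles[pid].bonds:
            if b is not None and b[0] not in seen:
                seen.add(b[0])
                stack.append(b[0])
    return seen


class SimState:
    """Full particle-level state of a network-free simulation."""

    def __init__(self, model: Model, seed: int,
                 params: Optional[dict] = None,
                 scale: Optional[float] = None,
                 max_particles: int = 1_000_000):
        diags = [d for d in validate_model(model) if d.severity == "error"]
        if diags:
            raise SimulationError(
                "model has validation errors: "
                + "; ".join(f"{d.location}: {d.message}" for d in diags[:5]))
        self.model = model
        self.params = dict(params or {})
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.time = 0.0
        self.event_count = 0
        self.null_count = 0
        self.work = MatchCounter()
        self.work_history: list[tuple[int, int]] = []
        self.max_particles = max_particles

        self.particles: dict[int, Particle] = {}
        self._next_pid = 0

        self.rule_rt: list[_RuleRuntime] = []
        for rule in model.rules:
            for g in rule.reactants:
                if len(connected_component_indices(g)) > 1:
                    raise SimulationError(
                        f"rule {rule.name}: each reactant pattern must be "
                        "connected")
            slots = [_PatternSlot(g, count_automorphisms(g))
                     for g in rule.reactants]
            union, offsets = union_graphs(rule.reactants)
            sym = count_automorphisms(union) if union.molecules else 1
            same = (len(slots) == 2 and
                    bngl.format_pattern(rule.reactants[0]) ==
                    bngl.format_pattern(rule.reactants[1]))
            self.rule_rt.append(_RuleRuntime(
                rule, model.rate_value(rule, self.params), sym, slots, same,
                offsets))

        self.obs_slots: list[list[_PatternSlot]] = []
        for obs in model.observables:
            slots = []
            for g in obs.patterns:
                if len(connected_component_indices(g)) > 1:
                    raise SimulationError(
                        f"observable {obs.name}: patterns must be connected")
                slots.append(_PatternSlot(g, count_automorphisms(g)))
            self.obs_slots.append(slots)

        self.by_particle: dict[int, set] = {}

        scale_used = {}
        for g, copies in model.seed_species:
            eff = self._effective_scale(g, scale)
            n = int(round(copies * eff))  # banker's rounding: unbiased
            scale_used[bngl.format_pattern(g)] = eff
            for _ in range(n):
                self.instantiate(g, reindex=False)
        self.scale_used = scale_used
        if len(self.particles) > self.max_particles:
            raise SimulationError(
                f"{len(self.particles)} particles exceed the configured cap "
                f"({self.max_particles}); scale compartments down "
                "(e.g. scale_factor 0.2) or reduce copy numbers")
        self._full_reindex()

    # -- construction helpers ------------------------------------------------

    def _effective_scale(self, g: SiteGraph, override: Optional[float]) -> float:
        if override is not None:
            return override
        mol = g.molecules[0]
        comp = mol.compartment
        if comp is None:
            mt = self.model.molecule_types.get(mol.typename)
            comp = mt.home_compartment if mt else None
        if comp is not None and comp in self.model.compartments:
            return self.model.compartments[comp].scale_factor
        return 1.0

    def instantiate(self, species: SiteGraph, reindex: bool = True) -> list[int]:
        """Add one copy of a concrete species; returns the new particle ids."""
        pids = []
        for mol in species.molecules:
            mt = self.model.molecule_types[mol.typename]
            comp_names = tuple(cd.name for cd in mt.components)
            # align graph components to type-def order by name occurrence
            states: list = [None] * len(comp_names)
            bonds: list = [None] * len(comp_names)
            taken: list[bool] = [False] * len(comp_names)
            idx_map = []
            for c in mol.comps:
                slot = next(i for i, nm in enumerate(comp_names)
                            if nm == c.name and not taken[i])
                taken[slot] = True
                states[slot] = c.state
                idx_map.append(slot)
            pid = self._next_pid
            self._next_pid += 1
            comp = mol.compartment
            if comp is None:
                comp = mt.home_compartment
            p = Particle(pid, mol.typename, comp_names, states, bonds, comp)
            self.particles[pid] = p
            self.by_particle[pid] = set()
            pids.append(pid)
        # wire bonds using the species' bond labels
        endpoint_map = {}
        for mi, mol in enumerate(species.molecules):
            mt = self.model.molecule_types[mol.typename]
            comp_names = tuple(cd.name for cd in mt.components)
            taken = [False] * len(comp_names)
            for ci, c in enumerate(mol.comps):
                slot = next(i for i, nm in enumerate(comp_names)
                            if nm == c.name and not taken[i])
                taken[slot] = True
                endpoint_map[(mi, ci)] = (pids[mi], slot)
        for ends in species.bond_map().values():
            if len(ends) == 2:
                (a, b) = ends
                pa, ca = endpoint_map[a]
                pb, cb = endpoint_map[b]
                self.particles[pa].bonds[ca] = (pb, cb)
                self.particles[pb].bonds[cb] = (pa, ca)
        if reindex:
            self._rematch(set(pids))
        return pids

    def _all_slots(self):
        for ri, rt in enumerate(self.rule_rt):
            for si, slot in enumerate(rt.slots):
                if rt.same_pattern and si == 1:
                    continue
                yield ("r", ri, si), slot
        for oi, slots in enumerate(self.obs_slots):
            for si, slot in enumerate(slots):
                yield ("o", oi, si), slot

    def _full_reindex(self) -> None:
        for key, slot in self._all_slots():
            slot.embs = _EmbSet()
        for pid in self.by_particle:
            self.by_particle[pid] = set()
        self._rematch(set(self.particles.keys()))

    def _rematch(self, pids: set[int]) -> None:
        cand = sorted(pids)
        for key, slot in self._all_slots():
            for emb in match_particles(slot.pattern, self.particles, cand,
                                       self.work):
                slot.embs.add(emb)
                for pid, _ in emb:
                    self.by_particle[pid].add((key, emb))

    def _drop_embeddings(self, pids: set[int]) -> None:
        slot_lookup = dict(self._all_slots())
        dropped = set()
        for pid in pids:
            entries = self.by_particle.get(pid)
            if not entries:
                continue
            for key, emb in list(entries):
                if (key, emb) in dropped:
                    continue
                dropped.add((key, emb))
                slot_lookup[key].embs.remove(emb)
                for qid, _ in emb:
                    self.by_particle[qid].discard((key, emb))

    # -- rates and stepping --------------------------------------------------

    def rule_rates(self) -> np.ndarray:
        rates = np.empty(len(self.rule_rt))
        for i, rt in enumerate(self.rule_rt):
            if not rt.slots:
                rates[i] = rt.k
            elif len(rt.slots) == 1:
                rates[i] = rt.k * len(rt.slots[0].embs) / rt.sym
            elif rt.same_pattern:
                n = len(rt.slots[0].embs)
                rates[i] = rt.k * n * (n - 1) / rt.sym
            else:
                rates[i] = (rt.k * len(rt.slots[0].embs)
                            * len(rt.slots[1].embs) / rt.sym)
        return rates

    def total_rate(self) -> float:
        return float(self.rule_rates().sum())

    def _pick_embeddings(self, rt: _RuleRuntime):
        if not rt.slots:
            return []
        if len(rt.slots) == 1:
            items = rt.slots[0].embs.items
            return [items[int(self.rng.integers(len(items)))]]
        if rt.same_pattern:
            items = rt.slots[0].embs.items
            i = int(self.rng.integers(len(items)))
            j = int(self.rng.integers(len(items) - 1))
            if j >= i:
                j += 1
            return [items[i], items[j]]
        e1 = rt.slots[0].embs.items[int(self.rng.integers(len(rt.slots[0].embs)))]
        e2 = rt.slots[1].embs.items[int(self.rng.integers(len(rt.slots[1].embs)))]
        return [e1, e2]

    def step(self) -> Optional[dict]:
        """One stochastic event (possibly null).  Returns an event record,
        or None if the total rate is zero."""
        rates = self.rule_rates()
        total = float(rates.sum())
        if total <= 0:
            return None
        dt = self.rng.exponential(1.0 / total)
        u = self.rng.random() * total
        ri = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        ri = min(ri, len(self.rule_rt) - 1)
        rt = self.rule_rt[ri]
        embs = self._pick_embeddings(rt)
        self.time += dt
        self.event_count += 1

        record = {"time": self.time, "rule": rt.rule.name, "null": False}
        if len(embs) == 2:
            pids1 = [pid for pid, _ in embs[0]]
            pids2 = [pid for pid, _ in embs[1]]
            cx1 = complex_of(self.particles, pids1)
            if any(p in cx1 for p in pids2):
                self.null_count += 1
                record["null"] = True
                self.work_history.append((self.event_count, self.work.checks))
                return record

        self._apply(rt, embs)
        self.work_history.append((self.event_count, self.work.checks))
        return record

    def _apply(self, rt: _RuleRuntime, embs) -> None:
        # flat molecule index -> (pid, comp index map)
        flat: dict[int, tuple[int, tuple]] = {}
        for si, emb in enumerate(embs):
            off = rt.offsets[si]
            for mi, (pid, cmap) in enumerate(emb):
                flat[off + mi] = (pid, cmap)
        n_r = sum(len(g.molecules) for g in rt.rule.reactants)

        involved = [pid for pid, _ in flat.values()]
        affected = complex_of(self.particles, involved) if involved else set()
        created: list[int] = []
        deleted: set[int] = set()

        for tf in rt.rule.transformations:
            if isinstance(tf, ChangeState):
                pid, cmap = flat[tf.site[0]]
                self.particles[pid].states[cmap[tf.site[1]]] = tf.state
            elif isinstance(tf, DeleteBond):
                pa, ca = flat[tf.a[0]][0], flat[tf.a[0]][1][tf.a[1]]
                pb, cb = flat[tf.b[0]][0], flat[tf.b[0]][1][tf.b[1]]
                self.particles[pa].bonds[ca] = None
                self.particles[pb].bonds[cb] = None
            elif isinstance(tf, AddBond):
                pa, ca = flat[tf.a[0]][0], flat[tf.a[0]][1][tf.a[1]]
                pb, cb = flat[tf.b[0]][0], flat[tf.b[0]][1][tf.b[1]]
                if self.particles[pa].bonds[ca] is not None or \
                        self.particles[pb].bonds[cb] is not None:
                    raise SimulationError(
                        f"rule {rt.rule.name}: AddBond on occupied site")
                self.particles[pa].bonds[ca] = (pb, cb)
                self.particles[pb].bonds[cb] = (pa, ca)
            elif isinstance(tf, CreateMolecule):
                mt = self.model.molecule_types[tf.typename]
                comp_names = tuple(cd.name for cd in mt.components)
                states: list = [None] * len(comp_names)
                taken = [False] * len(comp_names)
                cmap = []
                for name, st in tf.comps:
                    slot = next(i for i, nm in enumerate(comp_names)
                                if nm == name and not taken[i])
                    taken[slot] = True
                    states[slot] = st
                    cmap.append(slot)
                pid = self._next_pid
                self._next_pid += 1
                self.particles[pid] = Particle(
                    pid, tf.typename, comp_names, states,
                    [None] * len(comp_names),
                    tf.compartment or mt.home_compartment)
                self.by_particle[pid] = set()
                flat[n_r + len(created)] = (pid, tuple(cmap))
                created.append(pid)
            elif isinstance(tf, DeleteMolecule):
                pid = flat[tf.mol][0]
                part = self.particles[pid]
                for ci, b in enumerate(part.bonds):  # break dangling bonds
                    if b is not None:
                        self.particles[b[0]].bonds[b[1]] = None
                        part.bonds[ci] = None
                deleted.add(pid)
            elif isinstance(tf, ChangeCompartment):
                pid = flat[tf.mol][0]
                self.particles[pid].compartment = tf.compartment

        self._drop_embeddings(affected | deleted | set(created))
        for pid in deleted:
            del self.particles[pid]
            del self.by_particle[pid]
        alive = (affected - deleted) | set(created)
        self._rematch(alive)

    # -- observables ---------------------------------------------------------

    def observable_values(self) -> list[int]:
        vals = []
        comp_rep: dict[int, int] = {}

        def rep(pid: int) -> int:
            if pid in comp_rep:
                return comp_rep[pid]
            cx = complex_of(self.particles, [pid])
            r = min(cx)
            for q in cx:
                comp_rep[q] = r
            return r

        for obs, slots in zip(self.model.observables, self.obs_slots):
            if obs.kind == "Molecules":
                total = 0
                for slot in slots:
                    n = len(slot.embs)
                    total += n // slot.automorphisms
                vals.append(total)
            else:  # Species
                reps = set()
                for slot in slots:
                    for emb in slot.embs.items:
                        reps.add(rep(emb[0][0]))
                vals.append(len(reps))
        return vals

    # -- debugging -----------------------------------------------------------

    def check_index(self) -> None:
        """Assert the incremental embedding index equals a fresh recompute."""
        cand = sorted(self.particles)
        for key, slot in self._all_slots():
            fresh = set(match_particles(slot.pattern, self.particles, cand))
            have = set(slot.embs.items)
            if fresh != have:
                raise AssertionError(
                    f"embedding index inconsistent for {key}: "
                    f"{len(have)} indexed vs {len(fresh)} recomputed")

    def molecule_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.particles.values():
            out[p.typename] = out.get(p.typename, 0) + 1
        return out


def initialize(model: Model, seed: int, params: Optional[dict] = None,
               scale: Optional[float] = None,
               max_particles: int = 1_000_000) -> SimState:
    """Instantiate particles from the model's seed species."""
    return SimState(model, seed, params, scale, max_particles)


def total_rate(state: SimState) -> float:
    return state.total_rate()


def step(state: SimState) -> Optional[dict]:
    return state.step()


def _model_hash(model: Model) -> str:
    return hashlib.sha256(bngl.write_model(model).encode()).hexdigest()[:16]


def run(model: Model, params: Optional[dict] = None,
        protocol: Optional[Protocol] = None, t_end: float = 100.0,
        sample_dt: float = 1.0, seed: int = 0,
        scale: Optional[float] = None,
        max_particles: int = 1_000_000,
        debug_check_interval: Optional[int] = None) -> Trajectory:
    """Simulate and sample observables on a regular grid.

    The protocol may request pre-equilibration (simulated before t=0 without
    sampling) and timed species additions / parameter switches.  Identical
    (model, params, protocol, seed) inputs give identical trajectories.
    """
    protocol = protocol or Protocol()
    state = SimState(model, seed, params, scale, max_particles)

    def advance_to(t_target: float) -> None:
        while state.time < t_target:
            rates = state.rule_rates()
            total = float(rates.sum())
            if total <= 0:
                state.time = t_target
                return
            # peek the waiting time; discard the draw if it crosses the
            # boundary (memorylessness keeps this exact)
            dt = state.rng.exponential(1.0 / total)
            if state.time + dt > t_target:
                state.time = t_target
                return
            # commit: redo selection inline to reuse the drawn dt
            u = state.rng.random() * total
            ri = int(np.searchsorted(np.cumsum(rates), u, side="right"))
            ri = min(ri, len(state.rule_rt) - 1)
            rt = state.rule_rt[ri]
            embs = state._pick_embeddings(rt)
            state.time += dt
            state.event_count += 1
            null = False
            if len(embs) == 2:
                cx1 = complex_of(state.particles, [p for p, _ in embs[0]])
                if any(p in cx1 for p, _ in embs[1]):
                    state.null_count += 1
                    null = True
            if not null:
                state._apply(rt, embs)
            state.work_history.append((state.event_count, state.work.checks))
            if debug_check_interval and \
                    state.event_count % debug_check_interval == 0:
                state.check_index()

    if protocol.equilibrate > 0:
        advance_to(protocol.equilibrate)
        state.time = 0.0

    grid = sample_grid(t_end, sample_dt)
    values = np.zeros((len(grid), len(model.observables)), dtype=np.int64)
    events = protocol.events()
    ei = 0
    for gi, t in enumerate(grid):
        while ei < len(events) and events[ei][0] <= t:
            advance_to(events[ei][0])
            ev = events[ei][1]
            if isinstance(ev, Addition):
                g = ev.species if isinstance(ev.species, SiteGraph) \
                    else bngl.parse_pattern(ev.species)
                for _ in range(ev.copies):
                    state.instantiate(g)
            elif isinstance(ev, ParamSwitch):
                state.params[ev.name] = ev.value
                for rt in state.rule_rt:
                    rt.k = model.rate_value(rt.rule, state.params)
            ei += 1
        advance_to(t)
        values[gi] = state.observable_values()

    traj = Trajectory(grid, values, [o.name for o in model.observables],
                      metadata={"method": "network-free", "seed": seed,
                                "model_hash": _model_hash(model),
                                "events": state.event_count,
                                "null_events": state.null_count,
                                "scale": scale})
    traj.state = state  # expose final state for diagnostics
    return traj
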
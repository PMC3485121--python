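"""Site-graph pattern matching.

Embedding enumeration (the "match" underlying rule application), automorphism
counting for mass-action symmetry factors, canonical species labelling for
species identity, and connectivity splitting.

Species in rule-based signaling models are short chains/trees of at most a
few tens of molecules, so the algorithms here favour exactness and
determinism over asymptotic cleverness: backtracking search with
most-constrained-first ordering for embeddings, and iterative neighbourhood
refinement with exhaustive tie-breaking for canonical labels.
"""
from __future__ import annotations

import itertools
from typing import Optional

from .core import (BOUND_ANY, UNSPEC_BOND, SiteGraph, connected_component_indices,
                   subgraph)

# An embedding maps pattern molecules to target molecules and, per molecule,
# pattern component indices to target component indices:
#   tuple over pattern molecules of (target_mol_index, tuple_of_target_comp_idx)
Embedding = tuple[tuple[int, tuple[int, ...]], ...]


class MatchCounter:
    """Mutable counter of candidate checks, used to measure matching work."""

    __slots__ = ("checks",)

    def __init__(self) -> None:
        self.checks = 0


def _comp_matches(pc, tc, exact: bool) -> bool:
    """Can pattern component pc map onto target component tc?

    ``exact`` compares wildcards literally (used for automorphisms of
    patterns); otherwise wildcard semantics apply: unspecified state matches
    any state, "+" matches any bonded component, "?" matches anything.
    """
    if pc.name != tc.name:
        return False
    if exact:
        if pc.state != tc.state:
            return False
        kind_p = pc.bond if pc.bond in (None, BOUND_ANY, UNSPEC_BOND) else int
        kind_t = tc.bond if tc.bond in (None, BOUND_ANY, UNSPEC_BOND) else int
        return kind_p == kind_t
    if pc.state is not None and pc.state != tc.state:
        return False
    if pc.bond is None:
        return tc.bond is None
    if pc.bond == BOUND_ANY:
        return tc.bond is not None and tc.bond != UNSPEC_BOND
    if pc.bond == UNSPEC_BOND:
        return True
    # explicit bond label: target must be bonded (partner checked globally)
    return isinstance(tc.bond, int)


def _molecule_assignments(pmol, tmol, exact: bool,
                          counter: Optional[MatchCounter]) -> list[tuple[int, ...]]:
    """All injective component assignments of pattern molecule onto target."""
    if pmol.typename != tmol.typename:
        return []
    if pmol.compartment is not None and not exact and \
            pmol.compartment != tmol.compartment:
        return []
    if exact and pmol.compartment != tmol.compartment:
        return []
    cands: list[list[int]] = []
    for pc in pmol.comps:
        cs = []
        for ti, tc in enumerate(tmol.comps):
            if counter is not None:
                counter.checks += 1
            if _comp_matches(pc, tc, exact):
                cs.append(ti)
        if not cs:
            return []
        cands.append(cs)
    out: list[tuple[int, ...]] = []

    def rec(i: int, used: set[int], acc: list[int]) -> None:
        if i == len(cands):
            out.append(tuple(acc))
            return
        for ti in cands[i]:
            if ti not in used:
                used.add(ti)
                acc.append(ti)
                rec(i + 1, used, acc)
                acc.pop()
                used.remove(ti)

    rec(0, set(), [])
    return out


def _bonds_consistent(p_bonds: list, t_adj: dict,
                      mol_assign: dict[int, int],
                      comp_assign: dict[int, tuple[int, ...]]) -> bool:
    """Check explicit pattern bonds are realized between mapped components."""
    for (mi, ci), (mj, cj) in p_bonds:
        if mi in mol_assign and mj in mol_assign:
            a = (mol_assign[mi], comp_assign[mi][ci])
            b = (mol_assign[mj], comp_assign[mj][cj])
            if t_adj.get(a) != b:
                return False
    return True


# Pattern preprocessing (match order, bond structure) cached by object
# identity: rule/observable patterns are fixed objects matched thousands of
# times.  Callers must not mutate a pattern between find_embeddings calls.
_PATTERN_CACHE: dict[int, tuple] = {}


def pattern_info(pattern: SiteGraph) -> tuple:
    """(neighbors, match order, bond endpoint pairs, type counts)."""
    key = id(pattern)
    hit = _PATTERN_CACHE.get(key)
    if hit is not None and hit[0] is pattern:
        return hit[1]
    np_ = len(pattern.molecules)
    p_adj = pattern.adjacency()
    p_neighbors: dict[int, set[int]] = {i: set() for i in range(np_)}
    for (mi, _), (mj, _) in p_adj.items():
        p_neighbors[mi].add(mj)

    # most-constrained-first (explicit bonds, then size), then BFS over the
    # pattern's bond structure so partial embeddings prune via bonds
    def constraint(mi: int) -> tuple:
        mol = pattern.molecules[mi]
        nb = sum(1 for c in mol.comps if isinstance(c.bond, int))
        return (-nb, -len(mol.comps), mi)

    order: list[int] = []
    remaining = sorted(range(np_), key=constraint)
    placed: set[int] = set()
    while len(order) < np_:
        nxt = next((mi for mi in remaining
                    if mi not in placed and (not order or p_neighbors[mi] & placed)),
                   None)
        if nxt is None:  # disconnected pattern: start a new component
            nxt = next(mi for mi in remaining if mi not in placed)
        order.append(nxt)
        placed.add(nxt)

    bonds = [tuple(ends) for ends in pattern.bond_map().values()
             if len(ends) == 2]
    type_counts: dict[str, int] = {}
    for mol in pattern.molecules:
        type_counts[mol.typename] = type_counts.get(mol.typename, 0) + 1
    info = (p_neighbors, order, bonds, type_counts)
    if len(_PATTERN_CACHE) > 8192:
        _PATTERN_CACHE.clear()
    _PATTERN_CACHE[key] = (pattern, info)
    return info


def find_embeddings(pattern: SiteGraph, target: SiteGraph,
                    candidate_mols: Optional[list[int]] = None,
                    exact: bool = False,
                    counter: Optional[MatchCounter] = None) -> list[Embedding]:
    """All injective, structure-preserving maps of ``pattern`` into ``target``.

    Symmetric duplicates are included (each automorphic image is a separate
    embedding); order is deterministic.  ``candidate_mols`` restricts the
    target molecules considered (used for local re-matching in simulators).
    ``exact`` switches wildcard subsumption off (self-embeddings of patterns).
    """
    np_ = len(pattern.molecules)
    if np_ == 0:
        return []
    p_neighbors, order, _, type_counts = pattern_info(pattern)

    # cheap prescreen: the target must carry enough molecules of each type
    t_counts: dict[str, int] = {}
    for mol in target.molecules:
        t_counts[mol.typename] = t_counts.get(mol.typename, 0) + 1
    for tname, need in type_counts.items():
        if t_counts.get(tname, 0) < need:
            return []

    targets = candidate_mols if candidate_mols is not None \
        else list(range(len(target.molecules)))

    results: list[Embedding] = []
    mol_assign: dict[int, int] = {}
    used_targets: set[int] = set()
    comp_assign: dict[int, tuple[int, ...]] = {}
    p_bonds = pattern_info(pattern)[2]
    t_adj = target.adjacency()

    def rec(k: int) -> None:
        if k == np_:
            if _bonds_consistent(p_bonds, t_adj, mol_assign, comp_assign):
                emb = tuple((mol_assign[i], comp_assign[i]) for i in range(np_))
                results.append(emb)
            return
        mi = order[k]
        pmol = pattern.molecules[mi]
        # candidate target molecules: follow an already-mapped bond if any
        cand = targets
        for nb in p_neighbors[mi]:
            if nb in mol_assign:
                # restrict to target molecules bonded to the mapped image
                tnb = mol_assign[nb]
                linked = {t_adj[(tnb, tci)][0]
                          for tci in range(len(target.molecules[tnb].comps))
                          if (tnb, tci) in t_adj}
                cand = [t for t in cand if t in linked]
                break
        for ti in sorted(cand):
            if ti in used_targets:
                continue
            for ca in _molecule_assignments(pmol, target.molecules[ti],
                                            exact, counter):
                mol_assign[mi] = ti
                used_targets.add(ti)
                comp_assign[mi] = ca
                rec(k + 1)
                del mol_assign[mi]
                used_targets.discard(ti)
                del comp_assign[mi]

    rec(0)
    # Deterministic order: sort by the mapped target molecule/component tuple.
    results.sort()
    return results


def count_embeddings(pattern: SiteGraph, target: SiteGraph, **kw) -> int:
    return len(find_embeddings(pattern, target, **kw))


def count_automorphisms(pattern: SiteGraph) -> int:
    """Number of self-embeddings (wildcards compared literally)."""
    if not pattern.molecules:
        return 1
    return len(find_embeddings(pattern, pattern, exact=True))


def is_isomorphic(a: SiteGraph, b: SiteGraph) -> bool:
    """Exact structural isomorphism between two site graphs."""
    if len(a.molecules) != len(b.molecules):
        return False
    embs = find_embeddings(a, b, exact=True)
    return len(embs) > 0


def connected_components(g: SiteGraph) -> list[SiteGraph]:
    """Split a graph into its bond-connected complexes (order preserved)."""
    return [subgraph(g, idx) for idx in connected_component_indices(g)]


# ---------------------------------------------------------------------------
# Canonical labelling

def _initial_colors(g: SiteGraph) -> list[tuple]:
    cols = []
    for mol in g.molecules:
        comps = tuple(sorted(
            (c.name, c.state if c.state is not None else "",
             "b" if isinstance(c.bond, int) else "u")
            for c in mol.comps))
        cols.append((mol.typename, mol.compartment or "", comps))
    return cols


def _refine(g: SiteGraph, colors: list[int]) -> list[int]:
    """Iterative neighbourhood refinement until the partition stabilizes."""
    adj = g.adjacency()
    n = len(g.molecules)
    while True:
        sigs = []
        for mi in range(n):
            nbr = []
            for ci, c in enumerate(g.molecules[mi].comps):
                if (mi, ci) in adj:
                    tj, tc = adj[(mi, ci)]
                    nbr.append((c.name, colors[tj],
                                g.molecules[tj].comps[tc].name))
            sigs.append((colors[mi], tuple(sorted(nbr))))
        ranks = {s: r for r, s in enumerate(sorted(set(sigs)))}
        new = [ranks[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _serialize(g: SiteGraph, order: list[int]) -> str:
    """Serialize with molecules in the given order; bonds numbered by first
    appearance; components ordered canonically within each molecule."""
    pos = {mi: k for k, mi in enumerate(order)}
    adj = g.adjacency()

    def comp_key(mi: int, ci: int):
        c = g.molecules[mi].comps[ci]
        if (mi, ci) in adj:
            tj, tc = adj[(mi, ci)]
            partner = (pos[tj], g.molecules[tj].comps[tc].name)
        else:
            partner = (-1, "")
        return (c.name, c.state or "", partner, ci)

    comp_order = {mi: sorted(range(len(g.molecules[mi].comps)),
                             key=lambda ci: comp_key(mi, ci))
                  for mi in order}
    bond_ids: dict[frozenset, int] = {}
    parts = []
    for mi in order:
        mol = g.molecules[mi]
        cparts = []
        for ci in comp_order[mi]:
            c = mol.comps[ci]
            s = c.name
            if c.state is not None:
                s += f"~{c.state}"
            if (mi, ci) in adj:
                key = frozenset(((mi, ci), adj[(mi, ci)]))
                if key not in bond_ids:
                    bond_ids[key] = len(bond_ids) + 1
                s += f"!{bond_ids[key]}"
            cparts.append(s)
        tag = f"@{mol.compartment}" if mol.compartment else ""
        parts.append(f"{mol.typename}({','.join(cparts)}){tag}")
    return ".".join(parts)


def canonical_label(species: SiteGraph) -> str:
    """Canonical text label: equal iff isomorphic, stable across runs.

    Iterative refinement partitions molecules; remaining ties are broken by
    individualization (branch on every member of the smallest ambiguous
    class) and the lexicographically smallest serialization wins.
    """
    if species.has_wildcards():
        raise ValueError("canonical_label requires a concrete species "
                         "(no bond wildcards)")
    n = len(species.molecules)
    if n == 0:
        return ""
    init = _initial_colors(species)
    ranks = {s: r for r, s in enumerate(sorted(set(init)))}
    colors = _refine(species, [ranks[s] for s in init])

    best: list[Optional[str]] = [None]

    def search(colors: list[int]) -> None:
        classes: dict[int, list[int]] = {}
        for mi, c in enumerate(colors):
            classes.setdefault(c, []).append(mi)
        ambiguous = sorted((len(v), c) for c, v in classes.items() if len(v) > 1)
        if not ambiguous:
            order = sorted(range(n), key=lambda mi: colors[mi])
            s = _serialize(species, order)
            if best[0] is None or s < best[0]:
                best[0] = s
            return
        _, cls = ambiguous[0]
        for mi in classes[cls]:
            branched = list(colors)
            branched[mi] = -1  # individualize: strictly smallest color
            sub = _refine(species, _rerank(branched))
            search(sub)

    def _rerank(colors: list[int]) -> list[int]:
        ranks = {c: r for r, c in enumerate(sorted(set(colors)))}
        return [ranks[c] for c in colors]

    search(colors)
    assert best[0] is not None
    return best[0]
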
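"""Shared fixtures: random site-graph generators and brute-force oracles.

The oracles here are deliberately independent of the package's matching
code: embeddings are found by exhaustive search over all injective molecule
maps and component assignments with a final whole-graph constraint check.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from rulesim.core import Component, Molecule, SiteGraph


# ---------------------------------------------------------------------------
# Random concrete species / patterns

TYPE_POOL = [
    ("X", [("a", ()), ("b", ("U", "P"))]),
    ("Y", [("a", ()), ("c", ("U", "P", "Q"))]),
    ("Z", [("a", ()), ("a", ()), ("s", ("U", "P"))]),   # repeated comp name
    ("W", [("a", ())]),
]


def random_species(rng: np.random.Generator, n_mols: int) -> SiteGraph:
    """A random concrete species: molecules with definite states, random
    bonds between free components (connected not guaranteed)."""
    mols = []
    for _ in range(n_mols):
        tname, comps = TYPE_POOL[int(rng.integers(len(TYPE_POOL)))]
        cs = []
        for cname, states in comps:
            state = states[int(rng.integers(len(states)))] if states else None
            cs.append(Component(cname, state))
        mols.append(Molecule(tname, cs))
    g = SiteGraph(mols)
    free = [(mi, ci) for mi, m in enumerate(mols)
            for ci in range(len(m.comps))]
    rng.shuffle(free)
    n_bonds = int(rng.integers(0, max(1, len(free) // 2)))
    label = 1
    while n_bonds > 0 and len(free) >= 2:
        a = free.pop()
        b = free.pop()
        if a[0] == b[0]:
            continue
        g.molecules[a[0]].comps[a[1]].bond = label
        g.molecules[b[0]].comps[b[1]].bond = label
        label += 1
        n_bonds -= 1
    return g


def random_pattern(rng: np.random.Generator, species: SiteGraph) -> SiteGraph:
    """Relax a species into a pattern: keep a sub-complex, drop components,
    blur states, wildcard some bonds."""
    # choose a connected sub-complex seed
    from rulesim.core import connected_component_indices
    comps = connected_component_indices(species)
    members = list(comps[int(rng.integers(len(comps)))])
    keep = sorted(rng.choice(members, size=int(rng.integers(1, len(members) + 1)),
                             replace=False))
    idx_map = {mi: k for k, mi in enumerate(keep)}
    mols = []
    for mi in keep:
        src = species.molecules[mi]
        cs = []
        for ci, c in enumerate(src.comps):
            if rng.random() < 0.25 and not isinstance(c.bond, int):
                continue  # omit component entirely (unconstrained)
            state = c.state if rng.random() < 0.7 else None
            bond = c.bond
            if isinstance(bond, int):
                # bond partner might be outside the kept set
                partner_outside = True
                for mj in keep:
                    if mj != mi:
                        for c2 in species.molecules[mj].comps:
                            if c2.bond == bond:
                                partner_outside = False
                if partner_outside:
                    bond = "+" if rng.random() < 0.7 else "?"
                elif rng.random() < 0.15:
                    bond = "+"
            elif bond is None and rng.random() < 0.15:
                bond = "?"
            cs.append(Component(c.name, state, bond))
        if not cs:
            cs = [Component(src.comps[0].name)]
            cs[0].state = None
            cs[0].bond = "?"
        mols.append(Molecule(src.typename, cs))
    g = SiteGraph(mols)
    # clear bond labels that lost one endpoint
    counts = {}
    for m in g.molecules:
        for c in m.comps:
            if isinstance(c.bond, int):
                counts[c.bond] = counts.get(c.bond, 0) + 1
    for m in g.molecules:
        for c in m.comps:
            if isinstance(c.bond, int) and counts[c.bond] != 2:
                c.bond = "+"
    return g


# ---------------------------------------------------------------------------
# Brute-force oracles

def _comp_ok(pc: Component, tc: Component) -> bool:
    if pc.name != tc.name:
        return False
    if pc.state is not None and pc.state != tc.state:
        return False
    if pc.bond is None:
        return tc.bond is None
    if pc.bond == "+":
        return isinstance(tc.bond, int)
    if pc.bond == "?":
        return True
    return isinstance(tc.bond, int)


def brute_force_embeddings(pattern: SiteGraph, target: SiteGraph) -> set:
    """All embeddings by exhaustive enumeration of injective maps."""
    np_, nt = len(pattern.molecules), len(target.molecules)
    results = set()
    if np_ == 0 or np_ > nt:
        return results
    t_adj = target.adjacency()
    for mol_map in itertools.permutations(range(nt), np_):
        percomp = []
        ok = True
        for mi, ti in enumerate(mol_map):
            pmol, tmol = pattern.molecules[mi], target.molecules[ti]
            if pmol.typename != tmol.typename:
                ok = False
                break
            options = []
            for pc in pmol.comps:
                cands = [ci for ci, tc in enumerate(tmol.comps)
                         if _comp_ok(pc, tc)]
                options.append(cands)
            percomp.append(options)
        if not ok:
            continue
        for assign in itertools.product(*[
                itertools.product(*opts) for opts in percomp]):
            # injectivity within each molecule
            if any(len(set(a)) != len(a) for a in assign):
                continue
            # explicit pattern bonds must map onto target bonds
            good = True
            for ends in pattern.bond_map().values():
                if len(ends) != 2:
                    good = False
                    break
                (mi, ci), (mj, cj) = ends
                a = (mol_map[mi], assign[mi][ci])
                b = (mol_map[mj], assign[mj][cj])
                if t_adj.get(a) != b:
                    good = False
                    break
            if good:
                results.add(tuple((mol_map[i], tuple(assign[i]))
                                  for i in range(np_)))
    return results


def brute_force_isomorphic(a: SiteGraph, b: SiteGraph) -> bool:
    """Exact isomorphism by exhaustive search (states and bonds equal)."""
    if len(a.molecules) != len(b.molecules):
        return False
    na = len(a.molecules)
    b_adj = b.adjacency()
    for mol_map in itertools.permutations(range(na)):
        ok = True
        comp_maps = []
        for mi, ti in enumerate(mol_map):
            am, bm = a.molecules[mi], b.molecules[ti]
            if am.typename != bm.typename or len(am.comps) != len(bm.comps):
                ok = False
                break
            opts = []
            for c in am.comps:
                opts.append([ci for ci, d in enumerate(bm.comps)
                             if d.name == c.name and d.state == c.state
                             and (isinstance(c.bond, int) ==
                                  isinstance(d.bond, int))
                             and (c.bond == d.bond or isinstance(c.bond, int))])
            comp_maps.append(opts)
        if not ok:
            continue
        for assign in itertools.product(*[
                itertools.product(*opts) for opts in comp_maps]):
            if any(len(set(x)) != len(x) for x in assign):
                continue
            good = True
            a_adj = a.adjacency()
            mapped = {(mi, ci): (mol_map[mi], assign[mi][ci])
                      for mi in range(na)
                      for ci in range(len(a.molecules[mi].comps))}
            for end_a, end_b in a_adj.items():
                if b_adj.get(mapped[end_a]) != mapped[end_b]:
                    good = False
                    break
            if good and len(a_adj) == len(b_adj):
                return True
    return False


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
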
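"""Post-simulation analysis and model-level contact-map extraction.

Time courses of site-specific phosphorylation are max-normalized (each row
divided by its own maximum over the simulation) and ordered by hierarchical
clustering with average linkage under the Pearson correlation distance
d = 1 - r, the standard preprocessing for phosphoproteomic heat maps.
The agglomeration is implemented directly (row counts here are tens, so the
O(n^3) naive scheme is instant) with a documented deterministic tie rule:
among equally distant cluster pairs the one containing the lowest original
row index merges first, and at each merge the cluster containing the lower
original index becomes the left child, fixing the leaf order.

The contact map summarizes a rule-based model as proteins with components
and modification flags, undirected binding edges (one per distinct
component pair appearing in any bond-forming rule) and directed
enzyme-substrate edges (catalyst molecule -> modified component).  Many
rules map to one edge — contextual refinements of a common interaction —
and the per-edge rule multiplicity records how many.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import AddBond, ChangeState, DeleteBond, Model, Rule
from .trajectory import Trajectory


@dataclass
class TimecourseMatrix:
    """Rows = observables (phosphosites), columns = sample times."""

    data: pd.DataFrame                  # index: row labels, columns: times
    zero_rows: list[str] = field(default_factory=list)
    normalized: bool = False

    @classmethod
    def from_trajectory(cls, traj: Trajectory,
                        rows: Optional[list[str]] = None) -> "TimecourseMatrix":
        df = traj.to_dataframe().set_index("time").T
        if rows is not None:
            df = df.loc[rows]
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep)


def normalize_timecourses(m: TimecourseMatrix) -> TimecourseMatrix:
    """Divide each row by its own maximum; all-zero rows stay zero and are
    flagged.  Idempotent."""
    values = m.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("time courses must be nonnegative")
    maxima = values.max(axis=1)
    zero = maxima == 0
    scaled = np.where(zero[:, None], values, values / np.where(
        zero, 1.0, maxima)[:, None])
    out = pd.DataFrame(scaled, index=m.data.index, columns=m.data.columns)
    return TimecourseMatrix(out, [str(lbl) for lbl, z in
                                  zip(m.data.index, zero) if z],
                            normalized=True)


def pearson_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson r between rows (rows must be non-constant)."""
    r = np.corrcoef(values)
    return 1.0 - r


def cluster_timecourses(m: TimecourseMatrix) \
        -> tuple[list[int], np.ndarray, list[str]]:
    """Average-linkage agglomeration under d = 1 - Pearson.

    Returns (row ordering as original indices, linkage matrix in the scipy
    (n-1, 4) convention, warnings).  Constant rows (Pearson undefined) are
    segregated first and appended after the clustered rows in original
    order.
    """
    values = m.data.to_numpy(dtype=float)
    n = values.shape[0]
    warnings: list[str] = []
    constant = [i for i in range(n) if np.ptp(values[i]) == 0]
    usable = [i for i in range(n) if i not in set(constant)]
    if constant:
        warnings.append(
            "constant rows segregated (Pearson undefined): "
            + ", ".join(str(m.data.index[i]) for i in constant))
    if len(usable) < 2:
        warnings.append("fewer than 2 clusterable rows; identity ordering")
        return list(range(n)), np.empty((0, 4)), warnings

    d = pearson_distance_matrix(values[usable])
    k = len(usable)
    # active clusters: id -> (member original-row positions within `usable`,
    # min original index for tie-breaking)
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    sizes = {i: 1 for i in range(k)}
    dist = {(i, j): d[i, j] for i in range(k) for j in range(i + 1, k)}
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {i: 0.0 for i in range(k)}
    linkage = np.zeros((k - 1, 4))
    next_id = k
    active = set(range(k))
    for step in range(k - 1):
        # deterministic tie rule: smallest distance; ties broken by the
        # lowest original row index contained in the pair
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                cand = (dist[(i, j)],
                        min(min(members[i]), min(members[j])),
                        max(min(members[i]), min(members[j])), i, j)
                if best is None or cand < best:
                    best = cand
        _, _, _, a, b = best
        h = dist[(a, b)]
        new = next_id
        next_id += 1
        # left child = cluster containing the lower original index
        left, right = (a, b) if min(members[a]) < min(members[b]) else (b, a)
        children[new] = (left, right)
        heights[new] = h
        linkage[step] = [left, right, h, sizes[a] + sizes[b]]
        members[new] = members[left] + members[right]
        sizes[new] = sizes[a] + sizes[b]
        active.discard(a)
        active.discard(b)
        for other in sorted(active):
            na, nb = sizes[a], sizes[b]
            da = dist[(min(a, other), max(a, other))]
            db = dist[(min(b, other), max(b, other))]
            dist[(other, new) if other < new else (new, other)] = \
                (na * da + nb * db) / (na + nb)
        active.add(new)

    # leaf order: left-to-right depth-first
    def leaves(cid: int) -> list[int]:
        if cid < k:
            return [cid]
        l, r = children[cid]
        return leaves(l) + leaves(r)

    root = next_id - 1
    order = [usable[i] for i in leaves(root)] + constant
    return order, linkage, warnings


# ---------------------------------------------------------------------------
# Contact maps

@dataclass
class ContactMap:
    """Machine-readable extended-contact-map content (no drawing).

    ``nodes`` maps protein name -> {"components": [...], "flags":
    [(component, state labels)], "compartment": name}.  ``binding_edges``
    are undirected ((protein, component), (protein, component)) pairs;
    ``enzyme_edges`` are directed (enzyme protein, (substrate protein,
    component)).  Edge values are rule multiplicities.  ``unmapped`` lists
    rules contributing no edge (transport, degradation, uncatalyzed state
    changes), so every rule is accounted for.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    binding_edges: dict[tuple, int] = field(default_factory=dict)
    enzyme_edges: dict[tuple, int] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)


def _enzyme_annotation(rule: Rule) -> Optional[str]:
    if "@enzyme=" in rule.name:
        return rule.name.split("@enzyme=", 1)[1].split("_", 1)[0].split(":")[0]
    return None


def extract_contact_map(model: Model) -> ContactMap:
    cmap = ContactMap()
    for mt in model.molecule_types.values():
        cmap.nodes[mt.name] = {
            "components": [cd.name for cd in mt.components],
            "flags": [(cd.name, list(cd.states)) for cd in mt.components
                      if cd.states],
            "compartment": mt.home_compartment,
        }

    for rule in model.rules:
        flat_mols = [mol for g in rule.reactants for mol in g.molecules]
        mapped = False
        for tf in rule.transformations:
            # both bond formation and its reverse belong to the binding arrow
            if isinstance(tf, (AddBond, DeleteBond)):
                ends = []
                for mi, ci in (tf.a, tf.b):
                    mol = flat_mols[mi]
                    ends.append((mol.typename, mol.comps[ci].name))
                edge = tuple(sorted(ends))
                cmap.binding_edges[edge] = cmap.binding_edges.get(edge, 0) + 1
                mapped = True
            elif isinstance(tf, ChangeState):
                subst = flat_mols[tf.site[0]]
                target = (subst.typename, subst.comps[tf.site[1]].name)
                enzyme = None
                others = {m.typename for i, m in enumerate(flat_mols)
                          if i != tf.site[0]}
                if len(flat_mols) == 2 and len(others) == 1:
                    enzyme = next(iter(others))
                ann = _enzyme_annotation(rule)
                if ann is not None:
                    enzyme = ann
                if enzyme is not None:
                    key = (enzyme, target)
                    cmap.enzyme_edges[key] = cmap.enzyme_edges.get(key, 0) + 1
                    mapped = True
        if not mapped:
            cmap.unmapped.append(rule.name)
    return cmap


# ---------------------------------------------------------------------------
# Export

def export_contact_map(cmap: ContactMap, fmt: str, path) -> None:
    """Write a contact map as GraphML, JSON or DOT (deterministic output)."""
    fmt = fmt.lower()
    if fmt == "json":
        payload = {
            "nodes": {k: cmap.nodes[k] for k in sorted(cmap.nodes)},
            "binding_edges": [
                {"a": list(a), "b": list(b), "rules": mult}
                for (a, b), mult in sorted(cmap.binding_edges.items())],
            "enzyme_edges": [
                {"enzyme": e, "substrate": list(s), "rules": mult}
                for (e, s), mult in sorted(cmap.enzyme_edges.items())],
            "unmapped_rules": sorted(cmap.unmapped),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    elif fmt == "graphml":
        import networkx as nx
        g = nx.MultiDiGraph()
        for name in sorted(cmap.nodes):
            info = cmap.nodes[name]
            g.add_node(name,
                       components=",".join(info["components"]),
                       compartment=info["compartment"] or "")
        for (a, b), mult in sorted(cmap.binding_edges.items()):
            g.add_edge(a[0], b[0], kind="binding",
                       site_a=a[1], site_b=b[1], rules=mult)
        for (e, s), mult in sorted(cmap.enzyme_edges.items()):
            g.add_edge(e, s[0], kind="enzyme_substrate",
                       substrate_site=s[1], rules=mult)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        lines = ["digraph contact_map {"]
        for name in sorted(cmap.nodes):
            comp = cmap.nodes[name]["compartment"] or ""
            lines.append(f'  "{name}" [label="{name}\\n{comp}"];')
        for (a, b), mult in sorted(cmap.binding_edges.items()):
            lines.append(f'  "{a[0]}" -> "{b[0]}" [dir=both, '
                         f'label="{a[1]}-{b[1]} (x{mult})"];')
        for (e, s), mult in sorted(cmap.enzyme_edges.items()):
            lines.append(f'  "{e}" -> "{s[0]}" [arrowhead=odot, '
                         f'label="{s[1]} (x{mult})"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown contact-map format {fmt!r}")


def export_matrix(m: TimecourseMatrix, fmt: str, path) -> None:
    fmt = fmt.lower()
    if fmt == "csv":
        m.to_csv(path, sep=",")
    elif fmt == "tsv":
        m.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
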
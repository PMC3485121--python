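"""In-memory representation of rule-based models.

A model is a set of molecule type graphs (molecules with binding/modification
components), compartments, parameters, seed species, observables, and rules.
Species and rule patterns are both *site graphs*: graphs whose nodes are
molecule instances carrying typed components; bonds join component pairs.
Patterns may leave component states unspecified and may carry bond wildcards
(``!+`` bound-to-anything, ``!?`` bond state unconstrained); concrete species
carry none of these.

Rules are stored operationally: reactant patterns plus a list of
transformations (bond add/delete, state change, molecule create/delete,
compartment change) derived from the reactant/product forms by a positional
diff.  Applying a rule's transformations to its reactant side reproduces its
product side — this round trip is the defining contract of
:func:`derive_transformations`.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

BOUND_ANY = "+"   # pattern bond wildcard: bound to an unspecified partner
UNSPEC_BOND = "?"  # pattern bond wildcard: bound or unbound, unconstrained

COMPARTMENT_NAMES = ("Ex", "M", "C", "En")


@dataclass(frozen=True)
class SourceSpan:
    """Position of an entity in its source text (1-based)."""

    line: int
    column: int = 1
    snippet: str = ""


@dataclass(frozen=True)
class ComponentDef:
    name: str
    states: tuple[str, ...] = ()


@dataclass(frozen=True)
class MoleculeTypeDef:
    name: str
    components: tuple[ComponentDef, ...] = ()
    home_compartment: Optional[str] = None
    span: Optional[SourceSpan] = field(default=None, compare=False)


@dataclass(frozen=True)
class Compartment:
    name: str
    dimension: int = 3
    size: float = 1.0
    scale_factor: float = 1.0
    span: Optional[SourceSpan] = field(default=None, compare=False)

    @property
    def effective_size(self) -> float:
        return self.size * self.scale_factor


@dataclass
class Component:
    """A component instance inside a site graph molecule.

    ``state`` is ``None`` when unspecified (pattern wildcard, or the
    component is a pure binding site).  ``bond`` is ``None`` (unbound), an
    integer bond label shared with exactly one other component, or one of the
    wildcard markers ``"+"`` / ``"?"``.
    """

    name: str
    state: Optional[str] = None
    bond: Union[int, str, None] = None

    def copy(self) -> "Component":
        return Component(self.name, self.state, self.bond)


@dataclass
class Molecule:
    typename: str
    comps: list[Component] = field(default_factory=list)
    compartment: Optional[str] = None

    def copy(self) -> "Molecule":
        return Molecule(self.typename, [c.copy() for c in self.comps], self.compartment)

    def comp_indices(self, name: str) -> list[int]:
        return [i for i, c in enumerate(self.comps) if c.name == name]


class SiteGraph:
    """A site graph: molecule instances plus bonds between components.

    Doubles as concrete species (no wildcards, typically connected) and as
    rule/observable pattern (wildcards allowed, omitted components mean
    "unconstrained").
    """

    __slots__ = ("molecules", "span")

    def __init__(self, molecules: Optional[list[Molecule]] = None,
                 span: Optional[SourceSpan] = None):
        self.molecules: list[Molecule] = molecules or []
        self.span = span

    def copy(self) -> "SiteGraph":
        return SiteGraph([m.copy() for m in self.molecules], self.span)

    def __len__(self) -> int:
        return len(self.molecules)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteGraph):
            return NotImplemented
        return self.molecules == other.molecules

    def bond_map(self) -> dict[int, list[tuple[int, int]]]:
        """Bond label -> list of (molecule index, component index) endpoints."""
        out: dict[int, list[tuple[int, int]]] = {}
        for mi, mol in enumerate(self.molecules):
            for ci, comp in enumerate(mol.comps):
                if isinstance(comp.bond, int):
                    out.setdefault(comp.bond, []).append((mi, ci))
        return out

    def adjacency(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Component endpoint -> bonded partner endpoint (labelled bonds only)."""
        adj: dict[tuple[int, int], tuple[int, int]] = {}
        for ends in self.bond_map().values():
            if len(ends) == 2:
                a, b = ends
                adj[a] = b
                adj[b] = a
        return adj

    def check_bonds(self) -> list[str]:
        """Structural bond diagnostics (labels not paired exactly twice)."""
        problems = []
        for label, ends in self.bond_map().items():
            if len(ends) != 2:
                problems.append(
                    f"bond !{label} has {len(ends)} endpoint(s), expected 2")
        return problems

    def has_wildcards(self) -> bool:
        return any(c.bond in (BOUND_ANY, UNSPEC_BOND)
                   for m in self.molecules for c in m.comps)

    def add_bond(self, a: tuple[int, int], b: tuple[int, int]) -> None:
        labels = set(self.bond_map())
        label = 1
        while label in labels:
            label += 1
        self.molecules[a[0]].comps[a[1]].bond = label
        self.molecules[b[0]].comps[b[1]].bond = label

    def delete_bond(self, a: tuple[int, int], b: tuple[int, int]) -> None:
        ca = self.molecules[a[0]].comps[a[1]]
        cb = self.molecules[b[0]].comps[b[1]]
        if not (isinstance(ca.bond, int) and ca.bond == cb.bond):
            raise ValueError(f"no shared bond between {a} and {b}")
        ca.bond = None
        cb.bond = None

    def renumber_bonds(self) -> "SiteGraph":
        """Relabel bonds 1..n in order of first appearance (in place)."""
        mapping: dict[int, int] = {}
        for mol in self.molecules:
            for comp in mol.comps:
                if isinstance(comp.bond, int):
                    if comp.bond not in mapping:
                        mapping[comp.bond] = len(mapping) + 1
        for mol in self.molecules:
            for comp in mol.comps:
                if isinstance(comp.bond, int):
                    comp.bond = mapping[comp.bond]
        return self


def connected_component_indices(g: SiteGraph) -> list[list[int]]:
    """Partition molecule indices by bond connectivity (order preserved)."""
    adj = g.adjacency()
    neighbors: dict[int, set[int]] = {i: set() for i in range(len(g.molecules))}
    for (mi, _), (mj, _) in adj.items():
        neighbors[mi].add(mj)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in range(len(g.molecules)):
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        members = []
        while stack:
            cur = stack.pop()
            members.append(cur)
            for nb in neighbors[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(sorted(members))
    return comps


def subgraph(g: SiteGraph, mol_indices: Iterable[int]) -> SiteGraph:
    """Extract the site graph induced by the given molecule indices."""
    idx = list(mol_indices)
    sub = SiteGraph([g.molecules[i].copy() for i in idx])
    sub.renumber_bonds()
    return sub


def union_graphs(graphs: Iterable[SiteGraph]) -> tuple[SiteGraph, list[int]]:
    """Disjoint union with relabelled bonds.

    Returns the union and the molecule-index offset of each input graph.
    """
    out = SiteGraph()
    offsets = []
    next_label = 1
    for g in graphs:
        offsets.append(len(out.molecules))
        relabel: dict[int, int] = {}
        for mol in g.molecules:
            m2 = mol.copy()
            for comp in m2.comps:
                if isinstance(comp.bond, int):
                    if comp.bond not in relabel:
                        relabel[comp.bond] = next_label
                        next_label += 1
                    comp.bond = relabel[comp.bond]
            out.molecules.append(m2)
    return out, offsets


# ---------------------------------------------------------------------------
# Transformations

@dataclass(frozen=True)
class AddBond:
    a: tuple[int, int]
    b: tuple[int, int]


@dataclass(frozen=True)
class DeleteBond:
    a: tuple[int, int]
    b: tuple[int, int]


@dataclass(frozen=True)
class ChangeState:
    site: tuple[int, int]
    state: str


@dataclass(frozen=True)
class CreateMolecule:
    """Create a fresh molecule; its index is nR + (creation order)."""

    typename: str
    comps: tuple[tuple[str, Optional[str]], ...]  # (name, state), unbonded
    compartment: Optional[str] = None


@dataclass(frozen=True)
class DeleteMolecule:
    mol: int


@dataclass(frozen=True)
class ChangeCompartment:
    mol: int
    compartment: str


Transformation = Union[AddBond, DeleteBond, ChangeState, CreateMolecule,
                       DeleteMolecule, ChangeCompartment]


class AmbiguousRuleError(ValueError):
    """Raised when identical reactant molecules make the reactant/product
    correspondence (and hence the transformation diff) ambiguous."""


class RuleApplicationError(ValueError):
    pass


def apply_transformations(union: SiteGraph, tfs: Iterable[Transformation]) -> SiteGraph:
    """Apply a transformation list to a (copy of a) flattened reactant graph.

    Molecule indices in the transformations refer to positions in ``union``;
    created molecules take indices beyond the initial length in creation
    order.  Deleted molecules are compacted out at the end.
    """
    g = union.copy()
    deleted: set[int] = set()
    for tf in tfs:
        if isinstance(tf, ChangeState):
            g.molecules[tf.site[0]].comps[tf.site[1]].state = tf.state
        elif isinstance(tf, DeleteBond):
            g.delete_bond(tf.a, tf.b)
        elif isinstance(tf, AddBond):
            for end in (tf.a, tf.b):
                if g.molecules[end[0]].comps[end[1]].bond is not None:
                    raise RuleApplicationError(
                        f"AddBond target {end} already bonded")
            g.add_bond(tf.a, tf.b)
        elif isinstance(tf, CreateMolecule):
            g.molecules.append(Molecule(
                tf.typename, [Component(n, s) for n, s in tf.comps],
                tf.compartment))
        elif isinstance(tf, DeleteMolecule):
            for comp in g.molecules[tf.mol].comps:
                if isinstance(comp.bond, int):
                    raise RuleApplicationError(
                        f"DeleteMolecule {tf.mol} still has bond !{comp.bond}"
                        " (DeleteBond must precede)")
            deleted.add(tf.mol)
        elif isinstance(tf, ChangeCompartment):
            g.molecules[tf.mol].compartment = tf.compartment
        else:  # pragma: no cover
            raise TypeError(f"unknown transformation {tf!r}")
    g.molecules = [m for i, m in enumerate(g.molecules) if i not in deleted]
    return g.renumber_bonds()


def _bond_set(g: SiteGraph) -> set[frozenset[tuple[int, int]]]:
    return {frozenset(ends) for ends in g.bond_map().values() if len(ends) == 2}


def _diff_under_mapping(r_union: SiteGraph, p_union: SiteGraph,
                        mol_map: dict[int, int]) -> Optional[list[Transformation]]:
    """Transformation diff for a reactant->product molecule correspondence.

    ``mol_map`` maps reactant molecule index -> product molecule index for
    conserved molecules.  Returns None if the mapping is inconsistent (type
    mismatch, or product mentions a component absent from its reactant
    counterpart).
    """
    inv = {v: k for k, v in mol_map.items()}
    # Component correspondence: k-th occurrence of a name on the reactant
    # side maps to the k-th occurrence on the product side.
    comp_map: dict[tuple[int, int], tuple[int, int]] = {}   # reactant -> product
    for rmi, pmi in mol_map.items():
        rmol, pmol = r_union.molecules[rmi], p_union.molecules[pmi]
        if rmol.typename != pmol.typename:
            return None
        for name in {c.name for c in pmol.comps}:
            ris = rmol.comp_indices(name)
            pis = pmol.comp_indices(name)
            if len(pis) > len(ris):
                return None
            for k, pci in enumerate(pis):
                comp_map[(rmi, ris[k])] = (pmi, pci)
    inv_comp = {v: k for k, v in comp_map.items()}

    tfs: list[Transformation] = []
    # State and compartment changes on conserved molecules.
    for (rmi, rci), (pmi, pci) in sorted(comp_map.items()):
        rst = r_union.molecules[rmi].comps[rci].state
        pst = p_union.molecules[pmi].comps[pci].state
        if pst is not None and pst != rst:
            tfs.append(ChangeState((rmi, rci), pst))
    for rmi, pmi in sorted(mol_map.items()):
        rc = r_union.molecules[rmi].compartment
        pc = p_union.molecules[pmi].compartment
        if pc is not None and pc != rc:
            tfs.append(ChangeCompartment(rmi, pc))

    created_types = []
    created_index: dict[int, int] = {}  # product mol idx -> created slot idx
    n_r = len(r_union.molecules)
    for pmi, pmol in enumerate(p_union.molecules):
        if pmi not in inv:
            created_index[pmi] = n_r + len(created_types)
            created_types.append(CreateMolecule(
                pmol.typename,
                tuple((c.name, c.state) for c in pmol.comps),
                pmol.compartment))

    def p_endpoint_to_r(end: tuple[int, int]) -> Optional[tuple[int, int]]:
        if end in inv_comp:
            return inv_comp[end]
        if end[0] in created_index:
            return (created_index[end[0]], end[1])
        return None

    r_bonds = _bond_set(r_union)
    p_bonds_translated: set[frozenset[tuple[int, int]]] = set()
    for ends in _bond_set(p_union):
        t = [p_endpoint_to_r(e) for e in ends]
        if any(e is None for e in t):
            return None
        p_bonds_translated.add(frozenset(t))

    # A reactant bond "survives" only if both endpoints are conserved and the
    # translated product side contains it.
    for bond in sorted(r_bonds, key=sorted):
        ends = sorted(bond)
        # Bonds whose endpoints are unmentioned on the product side but whose
        # molecules are conserved and mention the component? If the product
        # omits the component entirely the bond is untouched.
        both_mapped = all(e in comp_map for e in ends)
        if both_mapped and bond not in p_bonds_translated:
            tfs.append(DeleteBond(ends[0], ends[1]))
        elif not both_mapped:
            # endpoint on a deleted molecule: bond must go before deletion
            if any(e[0] not in {k for k in mol_map} for e in ends):
                tfs.append(DeleteBond(ends[0], ends[1]))
    new_bonds = sorted(p_bonds_translated - r_bonds, key=sorted)
    tfs.extend(created_types)
    for bond in new_bonds:
        a, b = sorted(bond)
        tfs.append(AddBond(a, b))
    for rmi in range(n_r):
        if rmi not in mol_map:
            tfs.append(DeleteMolecule(rmi))
    return tfs


def derive_transformations(reactants: list[SiteGraph], products: list[SiteGraph],
                           rule_name: str = "") -> list[Transformation]:
    """Diff reactant patterns against product patterns.

    Correspondence is positional: the k-th occurrence of a molecule type in
    the flattened reactant list maps to the k-th occurrence in the flattened
    product list; components match by name and occurrence order.  If swapping
    two identical reactant molecules would change the diff, the rule is
    ambiguous and an :class:`AmbiguousRuleError` is raised.
    """
    r_union, _ = union_graphs(reactants)
    p_union, _ = union_graphs(products)

    by_type_r: dict[str, list[int]] = {}
    by_type_p: dict[str, list[int]] = {}
    for i, m in enumerate(r_union.molecules):
        by_type_r.setdefault(m.typename, []).append(i)
    for i, m in enumerate(p_union.molecules):
        by_type_p.setdefault(m.typename, []).append(i)

    base_map: dict[int, int] = {}
    for tname, ris in by_type_r.items():
        pis = by_type_p.get(tname, [])
        for k in range(min(len(ris), len(pis))):
            base_map[ris[k]] = pis[k]

    base = _diff_under_mapping(r_union, p_union, base_map)
    if base is None:
        raise RuleApplicationError(
            f"rule {rule_name or '<anonymous>'}: product side does not "
            "correspond to reactant side under positional matching")

    def normalize(tfs: list[Transformation]):
        out = []
        for tf in tfs:
            if isinstance(tf, (AddBond, DeleteBond)):
                a, b = sorted((tf.a, tf.b))
                out.append((type(tf).__name__, a, b))
            else:
                out.append(tf)
        return sorted(out, key=repr)

    base_norm = normalize(base)
    # Ambiguity probe: transpose any two same-type product assignments.
    for tname, ris in by_type_r.items():
        pis = by_type_p.get(tname, [])
        n = min(len(ris), len(pis))
        if n < 2:
            continue
        for i, j in itertools.combinations(range(n), 2):
            alt_map = dict(base_map)
            alt_map[ris[i]], alt_map[ris[j]] = alt_map[ris[j]], alt_map[ris[i]]
            alt = _diff_under_mapping(r_union, p_union, alt_map)
            if alt is not None and normalize(alt) != base_norm:
                raise AmbiguousRuleError(
                    f"rule {rule_name or '<anonymous>'}: molecules of type "
                    f"{tname} are interchangeable but yield different diffs")
    return base


# ---------------------------------------------------------------------------
# Rules, observables, parameters, model

@dataclass
class Rule:
    name: str
    reactants: list[SiteGraph]
    transformations: list[Transformation]
    rate_param: Union[str, float]
    reversible_partner: Optional[str] = None
    products: Optional[list[SiteGraph]] = None  # as written; derivable
    span: Optional[SourceSpan] = None

    def derived_products(self) -> list[SiteGraph]:
        """Product patterns recomputed by applying the transformations."""
        union, _ = union_graphs(self.reactants)
        result = apply_transformations(union, self.transformations)
        return [subgraph(result, idx) for idx in connected_component_indices(result)]


@dataclass
class Observable:
    name: str
    kind: str  # "Molecules" | "Species"
    patterns: list[SiteGraph]
    span: Optional[SourceSpan] = None


@dataclass
class Parameter:
    name: str
    value: float
    units: Optional[str] = None
    param_class: Optional[str] = None
    span: Optional[SourceSpan] = None


@dataclass
class Model:
    molecule_types: dict[str, MoleculeTypeDef] = field(default_factory=dict)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    parameters: dict[str, Parameter] = field(default_factory=dict)
    seed_species: list[tuple[SiteGraph, int]] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)

    def rate_value(self, rule: Rule,
                   overrides: Optional[dict[str, float]] = None) -> float:
        rp = rule.rate_param
        if isinstance(rp, (int, float)):
            return float(rp)
        if overrides and rp in overrides:
            return float(overrides[rp])
        if rp in self.parameters:
            return float(self.parameters[rp].value)
        raise KeyError(f"rate parameter {rp!r} not defined")

    def rule_by_name(self, name: str) -> Rule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class Diagnostic:
    severity: str   # "error" | "warning"
    location: str
    message: str


def _check_pattern(model: Model, g: SiteGraph, loc: str,
                   concrete: bool) -> list[Diagnostic]:
    diags = []

    def err(msg):
        diags.append(Diagnostic("error", loc, msg))

    for mol in g.molecules:
        mt = model.molecule_types.get(mol.typename)
        if mt is None:
            err(f"undeclared molecule type {mol.typename}")
            continue
        avail: dict[str, list[ComponentDef]] = {}
        for cd in mt.components:
            avail.setdefault(cd.name, []).append(cd)
        used: dict[str, int] = {}
        for comp in mol.comps:
            defs = avail.get(comp.name)
            if not defs:
                err(f"undeclared component {mol.typename}.{comp.name}")
                continue
            used[comp.name] = used.get(comp.name, 0) + 1
            if used[comp.name] > len(defs):
                err(f"component {mol.typename}.{comp.name} mentioned more "
                    f"times than declared ({len(defs)})")
                continue
            cd = defs[0]
            if comp.state is not None and comp.state not in cd.states:
                err(f"state {mol.typename}.{comp.name}~{comp.state} not "
                    f"declared (allowed: {','.join(cd.states) or 'none'})")
            if concrete:
                if comp.bond in (BOUND_ANY, UNSPEC_BOND):
                    err(f"wildcard bond on concrete species at "
                        f"{mol.typename}.{comp.name}")
                if cd.states and comp.state is None:
                    err(f"unspecified state for {mol.typename}.{comp.name} "
                        "in concrete species")
        if concrete:
            for name, defs in avail.items():
                if used.get(name, 0) != len(defs):
                    err(f"concrete species must mention all components; "
                        f"{mol.typename}.{name} incomplete")
        if mol.compartment is not None and mol.compartment not in model.compartments:
            err(f"undeclared compartment {mol.compartment}")
    for p in g.check_bonds():
        err(p)
    if concrete and g.molecules and len(connected_component_indices(g)) != 1:
        err("concrete seed species must be a single connected complex")
    return diags


def validate_model(model: Model) -> list[Diagnostic]:
    """Model-wide consistency diagnostics; an empty list means valid."""
    diags: list[Diagnostic] = []

    def err(loc, msg):
        diags.append(Diagnostic("error", loc, msg))

    for name, comp in model.compartments.items():
        loc = f"compartment {name}"
        if comp.dimension not in (2, 3):
            err(loc, f"dimension must be 2 or 3, got {comp.dimension}")
        if not comp.size > 0:
            err(loc, f"size must be positive, got {comp.size}")
        if not comp.scale_factor > 0:
            err(loc, f"scale_factor must be positive, got {comp.scale_factor}")

    for tname, mt in model.molecule_types.items():
        loc = f"molecule type {tname}"
        seen: dict[str, tuple[str, ...]] = {}
        for cd in mt.components:
            if len(set(cd.states)) != len(cd.states):
                err(loc, f"duplicate state labels on component {cd.name}")
            if cd.name in seen and seen[cd.name] != cd.states:
                err(loc, f"repeated component {cd.name} declared with "
                    "conflicting state labels")
            seen[cd.name] = cd.states
        if mt.home_compartment is not None and \
                mt.home_compartment not in model.compartments:
            err(loc, f"undeclared home compartment {mt.home_compartment}")

    for pname, p in model.parameters.items():
        if p.value < 0:
            err(f"parameter {pname}", f"negative value {p.value}")

    for i, (g, copies) in enumerate(model.seed_species):
        loc = f"seed species #{i + 1}"
        diags.extend(_check_pattern(model, g, loc, concrete=True))
        if not (isinstance(copies, int) and copies >= 0):
            err(loc, f"copy number must be a nonnegative integer, got {copies}")

    names = set()
    for rule in model.rules:
        loc = f"rule {rule.name}"
        if rule.name in names:
            err(loc, "duplicate rule name")
        names.add(rule.name)
        if len(rule.reactants) > 2:
            err(loc, f"{len(rule.reactants)} reactant patterns; mass action "
                "allows at most 2")
        if not rule.transformations:
            err(loc, "rule has no transformations")
        for g in rule.reactants:
            diags.extend(_check_pattern(model, g, loc, concrete=False))
        if isinstance(rule.rate_param, str) and \
                rule.rate_param not in model.parameters:
            err(loc, f"undeclared rate parameter {rule.rate_param}")
        if rule.reversible_partner is not None and \
                all(r.name != rule.reversible_partner for r in model.rules):
            err(loc, f"unknown reversible partner {rule.reversible_partner}")

    for obs in model.observables:
        loc = f"observable {obs.name}"
        if obs.kind not in ("Molecules", "Species"):
            err(loc, f"unknown observable kind {obs.kind}")
        for g in obs.patterns:
            diags.extend(_check_pattern(model, g, loc, concrete=False))
    return diags
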
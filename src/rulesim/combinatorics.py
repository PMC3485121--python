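"""Exact enumeration of local site states and monomer/dimer state-space counts.

A receptor component (a ligand-binding ectodomain or a phosphorylatable
docking site) has a finite set of *local states*: its unbound modification
states plus one state per distinct adapter complex that can attach to it.
Adapter complexes are described recursively: a binder (e.g. SHC1) has its own
modification states and child sites (e.g. a GRB2-recruitment site that is
only occupiable when SHC1 is phosphorylated), each child site independently
empty or bound to one of its allowed sub-complexes.

The number of possible states of a whole monomer is the product of its
per-site counts; a heterodimer multiplies the two monomer counts and a
homodimer counts unordered pairs with repetition, n(n+1)/2.  All arithmetic
is exact integer arithmetic.

The module ships the EGFR/ERBB3 specifications for the classic ERBB
adapter-recruitment slice (EGF/HRG ligands; SHC1, GRB2, PI3K docking with
SOS1/GAB1 recruitment through GRB2), which yield the well-known monomer
counts 331,776 (EGFR) and 11,664 (ERBB3).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

# A local state is a hashable nested tuple:
#   ("unbound", modification)                     e.g. ("unbound", "phos")
#   ("bound", complex)                            complex = recursive tuple
# complex = (molecule, modification, ((site_name, sub_complex | None), ...))


@dataclass(frozen=True)
class BinderSpec:
    """A molecule that can occupy a site, with its own recursive sub-sites.

    ``child_sites`` entries are (site name, allowed binders, gating): the
    child site is occupiable only when the binder's modification state equals
    ``gating`` (or always, if gating is None).
    """

    molecule: str
    modification_states: tuple[str, ...] = ("",)
    child_sites: tuple[tuple[str, tuple["BinderSpec", ...], Optional[str]], ...] = ()


@dataclass(frozen=True)
class LocalSiteSpec:
    """One physical site on a molecule: unbound states plus attachable trees."""

    name: str
    phospho_dependent: bool = False
    binders: tuple[BinderSpec, ...] = ()

    @property
    def unbound_states(self) -> tuple[str, ...]:
        return ("unphos", "phos") if self.phospho_dependent else ("unphos",)


@dataclass(frozen=True)
class MoleculeStateSpec:
    molecule: str
    sites: tuple[LocalSiteSpec, ...] = ()


class CyclicSpecError(ValueError):
    pass


def _enumerate_complexes(binder: BinderSpec, stack: tuple[str, ...] = ()) -> list[tuple]:
    if binder.molecule in stack:
        raise CyclicSpecError(
            f"binder recursion cycle through {binder.molecule}")
    stack = stack + (binder.molecule,)
    out: list[tuple] = []
    for mod in binder.modification_states:
        # Each child site is independently empty or bound to one of its
        # allowed sub-complexes, subject to gating on the binder state.
        per_site_options: list[list] = []
        for site_name, sub_binders, gating in binder.child_sites:
            options: list = [None]
            if gating is None or gating == mod:
                for sb in sub_binders:
                    options.extend(_enumerate_complexes(sb, stack))
            per_site_options.append(options)

        def rec(i: int, acc: list) -> None:
            if i == len(per_site_options):
                out.append((binder.molecule, mod,
                            tuple((binder.child_sites[j][0], acc[j])
                                  for j in range(len(acc)))))
                return
            for opt in per_site_options[i]:
                acc.append(opt)
                rec(i + 1, acc)
                acc.pop()

        rec(0, [])
    # de-duplicate while preserving deterministic order
    seen: set = set()
    uniq = []
    for c in out:
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    return uniq


def enumerate_site_states(site: LocalSiteSpec) -> list[tuple]:
    """All distinct local states of one site, duplicate-free, deterministic."""
    states: list[tuple] = [("unbound", s) for s in site.unbound_states]
    seen: set = set(states)
    for binder in site.binders:
        for cplx in _enumerate_complexes(binder):
            st = ("bound", cplx)
            if st not in seen:
                seen.add(st)
                states.append(st)
    return states


def count_site_states(site: LocalSiteSpec) -> int:
    return len(enumerate_site_states(site))


def count_dual_site(specs: Iterable[LocalSiteSpec]) -> int:
    """State count of one physical site shared by several docking roles.

    All specs must agree on the unbound states; bound-complex states are
    pooled with duplicates removed (set union).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one site spec")
    unbound = specs[0].unbound_states
    for s in specs[1:]:
        if s.unbound_states != unbound:
            raise ValueError(
                f"inconsistent unbound states between {specs[0].name} "
                f"and {s.name}")
    pooled: set = set()
    for s in specs:
        for st in enumerate_site_states(s):
            if st[0] == "bound":
                pooled.add(st)
    return len(unbound) + len(pooled)


def dual_site(name: str, specs: Iterable[LocalSiteSpec]) -> LocalSiteSpec:
    """Merge several docking roles of one physical site into a single spec."""
    specs = list(specs)
    merged = LocalSiteSpec(
        name,
        phospho_dependent=specs[0].phospho_dependent,
        binders=tuple(b for s in specs for b in s.binders))
    if count_site_states(merged) != count_dual_site(specs):
        raise ValueError("binder union does not reproduce the pooled count")
    return merged


def count_monomer_states(spec: MoleculeStateSpec) -> int:
    """Exact number of states of a monomer: product of per-site counts."""
    n = 1
    for site in spec.sites:
        n *= count_site_states(site)
    return n


def count_dimer_states(a: MoleculeStateSpec, b: MoleculeStateSpec) -> int:
    """Exact state count of a dimer.

    Heterodimer: product of the monomer counts.  Homodimer (same spec):
    unordered pairs with repetition, n(n+1)//2 — the two protomers are
    physically interchangeable.
    """
    na = count_monomer_states(a)
    if a == b:
        return na * (na + 1) // 2
    return na * count_monomer_states(b)


# ---------------------------------------------------------------------------
# The ERBB adapter-recruitment slice

def _grb2_binder() -> BinderSpec:
    # GRB2 recruits SOS1 (SH3-N) and GAB1 (SH3-C) on independent sites.
    sos1 = BinderSpec("SOS1")
    gab1 = BinderSpec("GAB1")
    return BinderSpec("GRB2", ("",), (
        ("sh3n", (sos1,), None),
        ("sh3c", (gab1,), None),
    ))


def shc1_docking_site(name: str) -> LocalSiteSpec:
    """A receptor SHC1 docking site: 8 local states.

    unphosphorylated / phosphorylated / bound to SHC1 (unphos or phos) /
    bound to phospho-SHC1 carrying GRB2, GRB2:SOS1, GRB2:GAB1, or the full
    GRB2:SOS1:GAB1 ternary complex.
    """
    shc1 = BinderSpec("SHC1", ("unphos", "phos"), (
        ("y317", (_grb2_binder(),), "phos"),
    ))
    return LocalSiteSpec(name, phospho_dependent=True, binders=(shc1,))


def grb2_docking_site(name: str) -> LocalSiteSpec:
    """A receptor GRB2 docking site: 6 local states."""
    return LocalSiteSpec(name, phospho_dependent=True,
                         binders=(_grb2_binder(),))


def pi3k_docking_site(name: str) -> LocalSiteSpec:
    """A receptor PI3K docking site: 3 local states."""
    return LocalSiteSpec(name, phospho_dependent=True,
                         binders=(BinderSpec("PI3K"),))


def ligand_site(name: str, ligand: str) -> LocalSiteSpec:
    """An ectodomain ligand site: free or ligand-bound (2 states)."""
    return LocalSiteSpec(name, phospho_dependent=False,
                         binders=(BinderSpec(ligand),))


def egfr_state_spec() -> MoleculeStateSpec:
    """EGFR: EGF site, two SHC1 sites, three GRB2 sites, one dual
    GRB2/SHC1 site (Y1114).  Residue naming is illustrative."""
    return MoleculeStateSpec("EGFR", (
        ligand_site("ecto", "EGF"),
        shc1_docking_site("y1148"),
        grb2_docking_site("y1068"),
        shc1_docking_site("y1173"),
        dual_site("y1114", [grb2_docking_site("y1114"),
                            shc1_docking_site("y1114")]),
        grb2_docking_site("y1086"),
        grb2_docking_site("y992"),
    ))


def erbb3_state_spec() -> MoleculeStateSpec:
    """ERBB3: HRG site, six PI3K sites, one SHC1 site."""
    pi3k_sites = tuple(pi3k_docking_site(n) for n in
                       ("y1035", "y1178", "y1203", "y1241", "y1257", "y1270"))
    return MoleculeStateSpec("ERBB3", (
        ligand_site("ecto", "HRG"),
    ) + pi3k_sites + (
        shc1_docking_site("y1328"),
    ))


# ---------------------------------------------------------------------------
# JSON spec files (for the CLI)

def _binder_from_json(d: dict) -> BinderSpec:
    return BinderSpec(
        d["molecule"],
        tuple(d.get("modification_states", [""])),
        tuple((cs["site"],
               tuple(_binder_from_json(b) for b in cs.get("binders", [])),
               cs.get("gating"))
              for cs in d.get("child_sites", [])))


def molecule_spec_from_json(text: str) -> MoleculeStateSpec:
    d = json.loads(text)
    return MoleculeStateSpec(d["molecule"], tuple(
        LocalSiteSpec(s["name"], bool(s.get("phospho_dependent", False)),
                      tuple(_binder_from_json(b) for b in s.get("binders", [])))
        for s in d["sites"]))


def _binder_to_json(b: BinderSpec) -> dict:
    return {
        "molecule": b.molecule,
        "modification_states": list(b.modification_states),
        "child_sites": [
            {"site": name, "binders": [_binder_to_json(sb) for sb in subs],
             "gating": gating}
            for name, subs, gating in b.child_sites],
    }


def molecule_spec_to_json(spec: MoleculeStateSpec) -> str:
    return json.dumps({
        "molecule": spec.molecule,
        "sites": [
            {"name": s.name, "phospho_dependent": s.phospho_dependent,
             "binders": [_binder_to_json(b) for b in s.binders]}
            for s in spec.sites],
    }, indent=2, sort_keys=True)
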
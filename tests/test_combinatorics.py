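"""Exact local-state enumeration and monomer/dimer state counts.

The published reference values for the ERBB adapter-recruitment slice:
site counts 8 (SHC1 dock), 6 (GRB2 dock), 3 (PI3K dock), 12 (dual
GRB2/SHC1 dock); monomers 331,776 (EGFR) and 11,664 (ERBB3); EGFR:ERBB3
heterodimer 331,776 x 11,664; EGFR homodimer n(n+1)/2.
"""
import itertools

import numpy as np
import pytest

from rulesim import combinatorics as cb


def test_shc1_docking_site_has_eight_states_with_expected_structure():
    states = cb.enumerate_site_states(cb.shc1_docking_site("y"))
    assert len(states) == 8
    unbound = [s for s in states if s[0] == "unbound"]
    bound = [s for s in states if s[0] == "bound"]
    # unphosphorylated, phosphorylated, SHC1 (unphos/phos), and the
    # phospho-SHC1:GRB2 sub-tree (GRB2 alone, +SOS1, +GAB1, +both)
    assert len(unbound) == 2 and len(bound) == 6
    shc1_mods = {c[1] for _, c in bound}
    assert shc1_mods == {"unphos", "phos"}


@pytest.mark.parametrize("factory, expected", [
    (lambda: cb.grb2_docking_site("y"), 6),
    (lambda: cb.pi3k_docking_site("y"), 3),
    (lambda: cb.ligand_site("e", "EGF"), 2),
])
def test_site_state_counts(factory, expected):
    assert cb.count_site_states(factory()) == expected


def test_site_with_no_binders_and_no_phospho_has_one_state():
    site = cb.LocalSiteSpec("inert")
    assert cb.enumerate_site_states(site) == [("unbound", "unphos")]


def test_dual_grb2_shc1_site_has_twelve_states():
    assert cb.count_dual_site([cb.grb2_docking_site("y1114"),
                               cb.shc1_docking_site("y1114")]) == 12


def test_dual_site_with_identical_specs_deduplicates():
    s = cb.shc1_docking_site("y")
    assert cb.count_dual_site([s, s]) == cb.count_site_states(s)


def test_dual_site_inconsistent_unbound_states_rejected():
    with pytest.raises(ValueError):
        cb.count_dual_site([cb.shc1_docking_site("y"),
                            cb.ligand_site("y", "EGF")])


def test_three_way_dual_site_equals_set_union_oracle():
    specs = [cb.grb2_docking_site("y"), cb.shc1_docking_site("y"),
             cb.pi3k_docking_site("y")]
    pooled = set()
    for s in specs:
        pooled.update(st for st in cb.enumerate_site_states(s)
                      if st[0] == "bound")
    assert cb.count_dual_site(specs) == 2 + len(pooled)


def test_egfr_monomer_count():
    assert cb.count_monomer_states(cb.egfr_state_spec()) == 331_776


def test_erbb3_monomer_count():
    assert cb.count_monomer_states(cb.erbb3_state_spec()) == 11_664


def test_empty_molecule_has_one_state():
    assert cb.count_monomer_states(cb.MoleculeStateSpec("null")) == 1


def test_monomer_count_equals_cartesian_product_on_small_spec():
    spec = cb.MoleculeStateSpec("toy", (
        cb.ligand_site("e", "L"),
        cb.pi3k_docking_site("y1"),
        cb.grb2_docking_site("y2"),
    ))
    lists = [cb.enumerate_site_states(s) for s in spec.sites]
    assert cb.count_monomer_states(spec) == len(list(
        itertools.product(*lists)))


def test_heterodimer_is_product_of_monomer_counts():
    egfr, erbb3 = cb.egfr_state_spec(), cb.erbb3_state_spec()
    n = cb.count_dimer_states(egfr, erbb3)
    assert n == 331_776 * 11_664 == 3_869_835_264
    assert n >= 3.8e9      # the published lower bound


def test_homodimer_uses_unordered_pairs_with_repetition():
    egfr = cb.egfr_state_spec()
    n = cb.count_monomer_states(egfr)
    hom = cb.count_dimer_states(egfr, egfr)
    assert hom == n * (n + 1) // 2 == 55_037_822_976
    assert hom >= 5.5e10   # the published lower bound


def test_homodimer_of_single_state_molecule_is_one():
    spec = cb.MoleculeStateSpec("null")
    assert cb.count_dimer_states(spec, spec) == 1


def test_cyclic_binder_spec_rejected():
    # A binder that (indirectly) recruits itself never terminates
    inner = cb.BinderSpec("A")
    a = cb.BinderSpec("A", ("",), (("s", (inner,), None),))
    site = cb.LocalSiteSpec("y", binders=(a,))
    with pytest.raises(cb.CyclicSpecError):
        cb.enumerate_site_states(site)


def _brute_force_site_count(site: cb.LocalSiteSpec) -> int:
    """Independent enumeration: recursively expand every binder complex."""

    def complexes(binder):
        out = []
        for mod in binder.modification_states:
            child_opts = []
            for sname, subs, gating in binder.child_sites:
                opts = [("empty",)]
                if gating is None or gating == mod:
                    for sb in subs:
                        opts += [("bound", c) for c in complexes(sb)]
                child_opts.append(opts)
            for combo in itertools.product(*child_opts):
                out.append((binder.molecule, mod, combo))
        uniq = []
        for c in out:
            if c not in uniq:
                uniq.append(c)
        return uniq

    states = set()
    for m in site.unbound_states:
        states.add(("u", m))
    for b in site.binders:
        for c in complexes(b):
            states.add(("b", c))
    return len(states)


def test_random_specs_match_brute_force(rng):
    """Random binder trees (depth <=3, branching <=3) against an
    independent recursive enumeration."""

    counter = itertools.count()

    def random_binder(depth):
        mods = tuple(f"m{i}" for i in range(int(rng.integers(1, 3))))
        children = []
        if depth < 3:
            for j in range(int(rng.integers(0, 3))):
                subs = tuple(random_binder(depth + 1)
                             for _ in range(int(rng.integers(1, 3))))
                gating = mods[0] if rng.random() < 0.4 else None
                children.append((f"s{j}", subs, gating))
        return cb.BinderSpec(f"B{next(counter)}", mods, tuple(children))

    for _ in range(50):
        site = cb.LocalSiteSpec(
            "y", phospho_dependent=bool(rng.random() < 0.5),
            binders=tuple(random_binder(1)
                          for _ in range(int(rng.integers(0, 3)))))
        got = len(cb.enumerate_site_states(site))
        assert got == _brute_force_site_count(site)
        # duplicate-free by construction
        states = cb.enumerate_site_states(site)
        assert len(states) == len(set(states))


def test_counts_are_exact_integers():
    # large homodimer counts must not pass through floating point
    egfr = cb.egfr_state_spec()
    n = cb.count_dimer_states(egfr, egfr)
    assert isinstance(n, int)
    assert n % 2 == 0 or n % 2 == 1  # plain int arithmetic, no overflow


def test_json_spec_roundtrip():
    spec = cb.egfr_state_spec()
    text = cb.molecule_spec_to_json(spec)
    again = cb.molecule_spec_from_json(text)
    assert cb.count_monomer_states(again) == 331_776
    assert [s.name for s in again.sites] == [s.name for s in spec.sites]
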
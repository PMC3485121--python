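"""Pattern matching against independent brute-force oracles."""
import numpy as np
import pytest

from rulesim import bngl
from rulesim.core import connected_component_indices
from rulesim.matching import (canonical_label, connected_components,
                              count_automorphisms, find_embeddings,
                              is_isomorphic)

from conftest import (brute_force_embeddings, brute_force_isomorphic,
                      random_pattern, random_species)


@pytest.mark.parametrize("pattern, target, expected", [
    ("A(b)", "A(b)", 1),
    ("A(b!1).B(a!1)", "A(b!1).B(a!1)", 1),
    ("A(b!1).A(b!1)", "A(b!1).A(b!1)", 2),       # homodimer swap symmetry
    ("R(y~P)", "R(y~P)", 1),
    ("R(y~P)", "R(y~U)", 0),
    ("R(y~P!+)", "R(y~P!1).S(a!1)", 1),          # bound-any matches a bond
    ("R(y!?)", "R(y)", 1),                        # unconstrained bond
    ("R(y)", "R(y!1).S(a!1)", 0),                 # bare component = unbound
])
def test_embedding_counts_on_dialect_examples(pattern, target, expected):
    p = bngl.parse_pattern(pattern)
    t = bngl.parse_pattern(target)
    assert len(find_embeddings(p, t)) == expected


def test_free_monomer_pool_counts_every_copy():
    p = bngl.parse_pattern("A(b)")
    pool = bngl.parse_pattern(".".join(["A(b)"] * 10))
    pool = bngl.SiteGraph([m for m in pool.molecules])
    assert len(find_embeddings(p, pool)) == 10


def test_embeddings_match_brute_force_on_random_instances(rng):
    """>=500 random pattern/target pairs, <=6 molecules, vs exhaustive
    enumeration of all injective maps."""
    checked = 0
    while checked < 520:
        target = random_species(rng, int(rng.integers(1, 7)))
        pattern = random_pattern(rng, target)
        if len(connected_component_indices(pattern)) != 1:
            continue
        got = set(find_embeddings(pattern, target))
        want = brute_force_embeddings(pattern, target)
        assert got == want, (bngl.format_pattern(pattern),
                             bngl.format_pattern(target))
        checked += 1


@pytest.mark.parametrize("pattern, expected", [
    ("A(b!1).B(a!1)", 1),
    ("A(b!1).A(b!1)", 2),
    ("A(x!1,x!2,x!3).B(a!1).B(a!2).B(a!3)", 6),  # 3 identical B arms
    ("A(b)", 1),
])
def test_automorphism_counts(pattern, expected):
    assert count_automorphisms(bngl.parse_pattern(pattern)) == expected


def test_automorphisms_equal_brute_force_self_embeddings(rng):
    for _ in range(120):
        g = random_species(rng, int(rng.integers(1, 6)))
        want = len(brute_force_embeddings(g, g))
        # concrete species: wildcard-free, so exact self-embeddings coincide
        assert count_automorphisms(g) == want


class TestCanonicalLabel:
    def test_build_order_invariance(self):
        a = bngl.parse_pattern("A(b!1).B(a!1)")
        b = bngl.parse_pattern("B(a!5).A(b!5)")
        assert canonical_label(a) == canonical_label(b)

    def test_distinguishes_phosphoforms(self):
        a = bngl.parse_pattern("R(y1~P,y2~U)")
        b = bngl.parse_pattern("R(y1~U,y2~P)")
        assert canonical_label(a) != canonical_label(b)

    def test_wildcard_input_rejected(self):
        with pytest.raises(ValueError):
            canonical_label(bngl.parse_pattern("R(y~P!+)"))

    def test_label_equality_iff_isomorphic_on_corpus(self, rng):
        """Random-species corpus: identical labels exactly for isomorphic
        graphs (checked against the exhaustive isomorphism oracle)."""
        corpus = [random_species(rng, int(rng.integers(1, 6)))
                  for _ in range(400)]
        labels = [canonical_label(g) for g in corpus]
        idx = rng.integers(0, len(corpus), size=(300, 2))
        for i, j in idx:
            same = labels[i] == labels[j]
            assert same == brute_force_isomorphic(corpus[i], corpus[j]), \
                (labels[i], labels[j])

    def test_shuffled_copies_collide(self, rng):
        """Shuffling molecule order (an isomorphic relabeling) never
        changes the label."""
        for _ in range(150):
            g = random_species(rng, int(rng.integers(2, 7)))
            perm = rng.permutation(len(g.molecules))
            shuffled = bngl.SiteGraph([g.molecules[i].copy() for i in perm])
            assert canonical_label(g) == canonical_label(shuffled)

    def test_is_isomorphic_agrees_with_oracle(self, rng):
        for _ in range(80):
            a = random_species(rng, int(rng.integers(1, 5)))
            b = random_species(rng, int(rng.integers(1, 5)))
            assert is_isomorphic(a, b) == brute_force_isomorphic(a, b)


def test_connected_components_examples():
    g = bngl.parse_pattern("A(b!1).B(a!1).C(x)")
    comps = connected_components(g)
    assert [len(c.molecules) for c in comps] == [2, 1]


def test_connected_components_agree_with_networkx(rng):
    import networkx as nx
    for _ in range(100):
        g = random_species(rng, int(rng.integers(1, 7)))
        nxg = nx.Graph()
        nxg.add_nodes_from(range(len(g.molecules)))
        for (mi, _), (mj, _) in g.adjacency().items():
            nxg.add_edge(mi, mj)
        want = sorted(sorted(c) for c in nx.connected_components(nxg))
        got = sorted(connected_component_indices(g))
        assert got == want
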
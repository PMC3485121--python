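"""Normalization, clustering (vs scipy oracle), contact maps, exports."""
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from rulesim import analysis as an, bngl, fixtures


def _tm(arr, labels=None):
    df = pd.DataFrame(np.asarray(arr, dtype=float))
    if labels is not None:
        df.index = labels
    return an.TimecourseMatrix(df)


class TestNormalize:
    def test_row_divided_by_its_maximum(self):
        out = an.normalize_timecourses(_tm([[0, 2, 4]]))
        assert out.data.iloc[0].tolist() == [0, 0.5, 1.0]

    def test_zero_row_unchanged_and_flagged(self):
        out = an.normalize_timecourses(_tm([[0, 0, 0], [1, 2, 1]],
                                           ["dead", "live"]))
        assert out.data.loc["dead"].tolist() == [0, 0, 0]
        assert out.zero_rows == ["dead"]

    def test_idempotent(self):
        m = _tm(np.random.default_rng(0).random((5, 9)))
        once = an.normalize_timecourses(m)
        twice = an.normalize_timecourses(once)
        assert np.allclose(once.data, twice.data)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            an.normalize_timecourses(_tm([[-1, 2]]))


class TestClustering:
    def test_identical_rows_merge_first(self):
        rows = [[0, 1, 2, 3], [0, 1, 2, 3], [3, 2, 1, 0]]
        order, Z, _ = an.cluster_timecourses(_tm(rows))
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_constant_rows_segregated_with_warning(self):
        rows = [[1, 1, 1, 1], [0, 1, 2, 3], [3, 2, 1, 0], [0, 1, 3, 2]]
        order, Z, warnings = an.cluster_timecourses(_tm(rows))
        assert order[-1] == 0
        assert any("constant" in w for w in warnings)

    def test_fewer_than_two_clusterable_rows(self):
        order, Z, warnings = an.cluster_timecourses(_tm([[1, 1], [2, 2]]))
        assert order == [0, 1]
        assert any("identity ordering" in w for w in warnings)

    def test_merge_heights_match_scipy_on_random_matrices(self, rng):
        """Average-linkage / Pearson against scipy.cluster.hierarchy on 200
        random matrices (n <= 20)."""
        for _ in range(200):
            n = int(rng.integers(3, 21))
            t = int(rng.integers(4, 12))
            X = rng.random((n, t))
            order, Z, _ = an.cluster_timecourses(_tm(X))
            d = an.pearson_distance_matrix(X)
            Zs = scipy_linkage(squareform(d, checks=False), method="average")
            assert np.allclose(np.sort(Z[:, 2]), np.sort(Zs[:, 2]),
                               atol=1e-10)
            assert sorted(order) == list(range(n))

    def test_row_permutation_gives_same_tree_up_to_relabeling(self, rng):
        X = rng.random((10, 8))
        _, Z1, _ = an.cluster_timecourses(_tm(X))
        perm = rng.permutation(10)
        _, Z2, _ = an.cluster_timecourses(_tm(X[perm]))

        def partitions(Z, k, relabel=None):
            members = {i: frozenset([relabel[i] if relabel is not None
                                     else i]) for i in range(k)}
            out = set()
            for step, (l, r, h, s) in enumerate(Z):
                members[k + step] = members[int(l)] | members[int(r)]
                out.add(members[k + step])
            return out

        assert partitions(Z1, 10) == partitions(Z2, 10, relabel=perm)


class TestContactMap:
    def test_binding_toy_has_single_edge(self):
        cm = an.extract_contact_map(fixtures.build_toy("binding"))
        assert set(cm.binding_edges) == {(("A", "b"), ("B", "a"))}
        assert cm.unmapped == []

    def test_erbb_edges_match_manifest(self):
        model, manifest = fixtures.build_erbb_mini_with_manifest(
            fixtures.ErbbConfig(tier=1))
        cm = an.extract_contact_map(model)
        assert set(cm.binding_edges) == \
            {tuple(sorted(e)) for e in manifest.binding_edges}

    def test_enzyme_substrate_edges_directed_at_flags(self):
        model = fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=2))
        cm = an.extract_contact_map(model)
        assert ("MEK", ("ERK", "t185")) in cm.enzyme_edges
        assert ("ERK", ("SOS1", "s1134")) in cm.enzyme_edges  # feedback
        # uncatalyzed dephosphorylation rules are listed, not mapped
        assert "dp_erk" in cm.unmapped

    def test_every_rule_mapped_or_listed(self):
        model = fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=2))
        cm = an.extract_contact_map(model)
        mapped = sum(cm.binding_edges.values()) + sum(
            cm.enzyme_edges.values())
        assert mapped + len(cm.unmapped) == len(model.rules)

    def test_contextual_refinements_collapse_to_one_edge(self):
        model = bngl.parse_model("""
begin parameters
  k1 1.0
  k2 1.0
  k3 1.0
end parameters
begin molecule types
  A(x,s~U~P)
  B(y)
end molecule types
begin seed species
  A(x,s~U) 5
  B(y) 5
end seed species
begin observables
end observables
begin reaction rules
  ctx1: A(x,s~U) + B(y) -> A(x!1,s~U).B(y!1) k1
  ctx2: A(x,s~P) + B(y) -> A(x!1,s~P).B(y!1) k2
  ctx3: A(x) + B(y) -> A(x!1).B(y!1) k3
end reaction rules
""")
        cm = an.extract_contact_map(model)
        assert cm.binding_edges == {(("A", "x"), ("B", "y")): 3}


class TestExport:
    def test_graphml_parses_with_networkx(self, tmp_path):
        import networkx as nx
        cm = an.extract_contact_map(fixtures.build_erbb_mini())
        p = tmp_path / "cm.graphml"
        an.export_contact_map(cm, "graphml", p)
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == 14

    def test_matrix_csv_roundtrip(self, tmp_path):
        m = _tm(np.random.default_rng(1).random((4, 6)),
                ["a", "b", "c", "d"])
        p = tmp_path / "m.csv"
        an.export_matrix(m, "csv", p)
        back = pd.read_csv(p, index_col=0)
        assert np.allclose(back.to_numpy(), m.data.to_numpy())

    def test_exports_are_byte_identical(self, tmp_path):
        cm = an.extract_contact_map(fixtures.build_toy("binding"))
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        an.export_contact_map(cm, "json", p1)
        an.export_contact_map(cm, "json", p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_format_rejected(self, tmp_path):
        cm = an.extract_contact_map(fixtures.build_toy("binding"))
        with pytest.raises(ValueError):
            an.export_contact_map(cm, "svg", tmp_path / "x")
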
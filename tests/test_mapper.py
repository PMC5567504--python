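"""Patient-patient network construction: normalization, lens, nerve graph,
flares and peripheral selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import pdist, squareform

from topostrat import (
    ClinicalMatrix,
    CoverConfig,
    build_mapper,
    denormalize,
    euclidean_distances,
    extract_flares,
    fit_reference_normalization,
    linf_centrality,
    map_attribute,
    normalize,
    select_peripheral,
    stratify_cohort,
)
from conftest import exact_summary_sample, make_mapper_graph


def matrix_from_values(values, labels=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ClinicalMatrix(
        values,
        [f"s{i}" for i in range(n)],
        [f"x{j}" for j in range(p)],
        labels or ["g"] * n,
    )


class TestNormalization:
    def test_population_moments_closed_form(self):
        M = matrix_from_values([[1.0], [2.0], [3.0]])
        params = fit_reference_normalization(M, ["s0", "s1", "s2"])
        assert params.ref_means[0] == pytest.approx(2.0)
        assert params.ref_sds[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_single_reference_subject_errors(self):
        M = matrix_from_values([[1.0], [2.0]])
        with pytest.raises(ValueError, match="zero spread"):
            fit_reference_normalization(M, ["s0"])

    def test_zero_spread_column_names_feature(self):
        M = matrix_from_values([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="x1"):
            fit_reference_normalization(M, ["s0", "s1", "s2"])

    def test_reference_summary_round_trip(self):
        """A cohort built to have mean 123.0 / SD 15.0 reproduces exactly
        those reference constants (population SD on the same rows)."""
        rng = np.random.default_rng(0)
        col = exact_summary_sample(123.0, 15.0, 20, rng)
        # exact_summary_sample fixes the sample SD; rescale to population SD
        col = 123.0 + (col - 123.0) * (15.0 / col.std(ddof=0))
        M = matrix_from_values(col[:, None])
        params = fit_reference_normalization(M, M.subject_ids)
        assert params.ref_means[0] == pytest.approx(123.0)
        assert params.ref_sds[0] == pytest.approx(15.0)

    def test_reference_zscore_of_known_value(self):
        """FSIQ 108 against reference mean 123, SD 15 normalizes to -1."""
        rng = np.random.default_rng(1)
        col = exact_summary_sample(123.0, 15.0, 30, rng)
        col = 123.0 + (col - 123.0) * (15.0 / col.std(ddof=0))
        values = np.concatenate([col, [108.0]])[:, None]
        M = matrix_from_values(values)
        params = fit_reference_normalization(M, M.subject_ids[:30])
        Mhat = normalize(M, params)
        assert Mhat.values[-1, 0] == pytest.approx(-1.0)
        # reference rows are zero-mean unit-SD after normalization
        ref = Mhat.values[:30, 0]
        assert ref.mean() == pytest.approx(0.0, abs=1e-12)
        assert ref.std(ddof=0) == pytest.approx(1.0)

    def test_not_idempotent_unless_standard(self):
        M = matrix_from_values([[1.0], [2.0], [4.0]])
        params = fit_reference_normalization(M, M.subject_ids)
        once = normalize(M, params)
        twice = normalize(once, params)
        assert not np.allclose(once.values, twice.values)

    def test_feature_mismatch_errors(self):
        M = matrix_from_values([[1.0], [2.0], [4.0]])
        params = fit_reference_normalization(M, M.subject_ids)
        params.feature_names = ["other"]
        with pytest.raises(ValueError):
            normalize(M, params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        hnp.arrays(
            float, (6, 3),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_round_trip_property(self, values):
        if np.any(values.std(axis=0) < 1e-3):
            return
        M = matrix_from_values(values)
        params = fit_reference_normalization(M, M.subject_ids)
        back = denormalize(normalize(M, params), params)
        np.testing.assert_allclose(back.values, M.values, atol=1e-9)


class TestDistancesAndLens:
    def test_identical_rows_distance_zero(self):
        M = matrix_from_values([[1, 2, 3], [1, 2, 3]])
        assert euclidean_distances(M)[0, 1] == 0.0

    def test_three_four_five(self):
        M = matrix_from_values(
            [[1, 2, 0, 0, 0, 0], [4, 6, 0, 0, 0, 0]]
        )
        assert euclidean_distances(M)[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(12)
        values = rng.standard_normal((5, 6))
        D = euclidean_distances(matrix_from_values(values))
        for a in range(5):
            for b in range(5):
                expected = np.sqrt(((values[a] - values[b]) ** 2).sum())
                assert D[a, b] == pytest.approx(expected)

    def test_linf_collinear_points(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [3.0]])))
        np.testing.assert_allclose(linf_centrality(D), [3.0, 2.0, 3.0])

    def test_linf_coincident_points(self):
        np.testing.assert_array_equal(
            linf_centrality(np.zeros((2, 2))), [0.0, 0.0]
        )

    def test_linf_equals_row_maximum(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 3))
        D = squareform(pdist(X))
        f = linf_centrality(D)
        for i in range(12):
            assert f[i] == max(D[i, j] for j in range(12))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        hnp.arrays(
            float, st.tuples(st.integers(3, 8), st.integers(1, 4)),
            elements=st.floats(-20, 20, allow_nan=False),
        )
    )
    def test_metric_axioms(self, X):
        D = euclidean_distances(matrix_from_values(X))
        n = X.shape[0]
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D, D.T)
        assert (D >= 0).all()
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestBuildMapper:
    def test_identical_subjects_single_node(self):
        D = np.zeros((4, 4))
        f = np.zeros(4)
        g = build_mapper(D, f, CoverConfig(1, 0.5, 3))
        assert g.graph.number_of_nodes() == 1
        assert g.graph.number_of_edges() == 0
        assert len(g.members(next(iter(g.graph.nodes)))) == 4

    def test_two_separated_groups_two_nodes_no_edge(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        D = squareform(pdist(X))
        f = np.array([0.0, 0.1, 0.9, 1.0])
        g = build_mapper(D, f, CoverConfig(2, 0.1, 3))
        assert g.graph.number_of_nodes() == 2
        assert g.graph.number_of_edges() == 0
        member_sets = {g.members(n) for n in g.graph.nodes}
        assert member_sets == {frozenset({"0", "1"}), frozenset({"2", "3"})}

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_mapper(np.zeros((0, 0)), np.zeros(0))

    def test_nerve_property_brute_force(self, topology_cohort):
        """Edge present iff the two nodes share at least one subject."""
        res = stratify_cohort(topology_cohort)
        g = res.graph
        nodes = list(g.graph.nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                shared = g.members(a) & g.members(b)
                assert g.graph.has_edge(a, b) == bool(shared)
                if shared:
                    assert g.graph[a][b]["weight"] == len(shared)

    def test_every_subject_covered(self, topology_cohort):
        for ov in (0.2, 0.45, 0.7):
            res = stratify_cohort(topology_cohort, cover=CoverConfig(4, ov, 3))
            assert res.graph.covered_subjects() == set(topology_cohort.subject_ids)

    def test_edge_count_monotone_in_overlap(self, topology_cohort):
        res = stratify_cohort(topology_cohort)
        counts = []
        for ov in (0.1, 0.25, 0.45, 0.6, 0.75):
            g = build_mapper(res.distances, res.lens, CoverConfig(4, ov, 3),
                             topology_cohort.subject_ids)
            counts.append(g.graph.number_of_edges())
        assert counts == sorted(counts)

    def test_deterministic(self, small_cohort):
        a = stratify_cohort(small_cohort)
        b = stratify_cohort(small_cohort)
        assert set(a.graph.graph.nodes) == set(b.graph.graph.nodes)
        assert set(a.graph.graph.edges) == set(b.graph.graph.edges)


class TestAttributesAndFlares:
    def test_constant_attribute(self, small_cohort):
        res = stratify_cohort(small_cohort)
        means = map_attribute(res.graph, {s: 7.0 for s in small_cohort.subject_ids})
        assert all(v == pytest.approx(7.0) for v in means.values())

    def test_two_member_mean(self):
        g = make_mapper_graph({}, {(0, 0): ["a", "b"]})
        means = map_attribute(g, {"a": 10.0, "b": 20.0})
        assert means[(0, 0)] == pytest.approx(15.0)

    def test_missing_value_errors(self):
        g = make_mapper_graph({}, {(0, 0): ["a", "b"]})
        with pytest.raises(ValueError, match="missing"):
            map_attribute(g, {"a": 1.0})

    def test_node_means_match_direct_average(self, small_cohort):
        res = stratify_cohort(small_cohort)
        rng = np.random.default_rng(0)
        vals = dict(zip(small_cohort.subject_ids, rng.standard_normal(45)))
        means = map_attribute(res.graph, vals)
        for n, m in means.items():
            assert m == pytest.approx(
                np.mean([vals[s] for s in res.graph.members(n)])
            )

    def test_y_shaped_graph_three_flares(self):
        members = {
            "c": ["j"],
            "a1": ["j", "a"], "a2": ["a", "aa"],
            "b1": ["j", "b"], "b2": ["b", "bb"],
            "d1": ["j", "d"], "d2": ["d", "dd"],
        }
        edges = [("c", "a1"), ("a1", "a2"), ("c", "b1"), ("b1", "b2"),
                 ("c", "d1"), ("d1", "d2")]
        labels = {s: s[0].upper() for s in "j a aa b bb d dd".split()}
        g = make_mapper_graph(edges, members, labels)
        flares = extract_flares(g)
        assert len(flares) == 3
        assert sorted(fl.majority_label for fl in flares) == ["A", "B", "D"]

    def test_path_graph_single_flare(self):
        members = {0: ["a", "b"], 1: ["b", "c"], 2: ["c", "d"]}
        g = make_mapper_graph([(0, 1), (1, 2)], members)
        flares = extract_flares(g)
        assert len(flares) == 1
        assert flares[0].subjects == {"a", "b", "c", "d"}

    def test_cohort_recovers_three_branches(self, topology_cohort):
        res = stratify_cohort(topology_cohort)
        labels = sorted(fl.majority_label for fl in res.flares)
        assert labels == ["TDC", "mADHD", "sADHD"]


class TestPeripheralSelection:
    def test_small_flare_returns_all_with_warning(self):
        g = make_mapper_graph({}, {(0, 0): ["a", "b", "c"]})
        fl = extract_flares(g)[0]
        with pytest.warns(UserWarning):
            out = select_peripheral(fl, {"a": 1.0, "b": 2.0, "c": 3.0}, k=15)
        assert sorted(out) == ["a", "b", "c"]

    def test_ranking_matches_full_sort(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(30)]
        f = dict(zip(ids, rng.standard_normal(30)))
        g = make_mapper_graph({}, {(0, 0): ids})
        fl = extract_flares(g)[0]
        out = select_peripheral(fl, f, k=10)
        expected = sorted(ids, key=lambda s: (-f[s], s))[:10]
        assert out == expected

    def test_low_direction_selects_smallest(self):
        ids = [f"s{i}" for i in range(6)]
        f = {s: float(i) for i, s in enumerate(ids)}
        g = make_mapper_graph({}, {(0, 0): ids})
        fl = extract_flares(g)[0]
        assert select_peripheral(fl, f, k=2, direction="low") == ["s0", "s1"]

    def test_pipeline_peripheral_purity(self, topology_cohort):
        """Peripheral-15 subjects carry their branch's majority label."""
        res = stratify_cohort(topology_cohort, k_peripheral=15)
        lab = dict(zip(topology_cohort.subject_ids, topology_cohort.group_labels))
        for fl in res.flares:
            assert len(fl.peripheral) == 15
            purity = np.mean([lab[s] == fl.majority_label for s in fl.peripheral])
            assert purity >= 0.8
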
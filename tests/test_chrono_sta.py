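"""The main clustering loop, completed matrix, UPGMA stage, ultrametric
smoothing and the model/results surface."""

import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy
import scipy.optimize
import scipy.spatial.distance

from chronosta import (
    ChronoSTA,
    ClusterRecord,
    DisconnectedCollectionError,
    Supermatrix,
    average_linkage_tree,
    complete_matrix_from_records,
    graft_outgroup,
    normalized_rf,
    parse_timetree,
    run_chrono_sta,
    smooth_to_ultrametric,
)

from conftest import complete_cooccurrence_collection, random_model, trees_equal


# --------------------------------------------------------------------------
# completed matrix
# --------------------------------------------------------------------------

class TestCompleteMatrixFromRecords:
    def test_small_merge_sequence(self):
        records = [
            ClusterRecord("C1", frozenset("AB"), 1.0, 1),
            ClusterRecord("C2", frozenset("CD"), 2.0, 2),
            ClusterRecord("C3", frozenset("ABCD"), 3.0, 3),
        ]
        S = complete_matrix_from_records(records, "ABCD")
        assert S.get("A", "B") == 1.0
        assert S.get("C", "D") == 2.0
        for x, y in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
            assert S.get(x, y) == 3.0
        assert not np.isnan(S.D).any()

    def test_two_leaves(self):
        S = complete_matrix_from_records(
            [ClusterRecord("C1", frozenset("XY"), 5.0, 1)], "XY"
        )
        assert S.get("X", "Y") == 5.0

    def test_uncovered_pair_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            complete_matrix_from_records(
                [ClusterRecord("C1", frozenset("AB"), 1.0, 1)], "ABC"
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_three_point_condition_bruteforce(self, seed):
        """Monotone merge sequences yield ultrametric matrices: for every
        triple the largest entry is attained at least twice."""
        rng = np.random.default_rng(seed)
        leaves = [f"L{i}" for i in range(8)]
        groups = [frozenset([x]) for x in leaves]
        records, age = [], 0.0
        it = 1
        while len(groups) > 1:
            i, j = sorted(rng.choice(len(groups), size=2, replace=False))
            age += float(rng.uniform(0.5, 2.0))
            merged = groups[i] | groups[j]
            records.append(ClusterRecord(f"C{it}", merged, age, it))
            groups = [g for k, g in enumerate(groups) if k not in (i, j)]
            groups.append(merged)
            it += 1
        S = complete_matrix_from_records(records, leaves)
        for x, y, z in itertools.combinations(leaves, 3):
            d = sorted([S.get(x, y), S.get(x, z), S.get(y, z)])
            assert d[2] == pytest.approx(d[1])


# --------------------------------------------------------------------------
# average linkage
# --------------------------------------------------------------------------

def _complete_supermatrix(labels, D):
    return Supermatrix(labels=list(labels), D=np.asarray(D, float),
                       support=np.ones((len(labels),) * 2, dtype=int))


class TestAverageLinkage:
    def test_three_taxa(self):
        S = _complete_supermatrix(
            "ABC", [[0, 1, 3], [1, 0, 3], [3, 3, 0]]
        )
        t = average_linkage_tree(S)
        assert t.mrca_age({"A", "B"}) == pytest.approx(1.0)
        assert t.root_age == pytest.approx(3.0)

    def test_two_by_two(self):
        S = _complete_supermatrix("XY", [[0, 7], [7, 0]])
        t = average_linkage_tree(S)
        assert t.root_age == pytest.approx(7.0)

    def test_missing_cells_rejected(self):
        D = np.array([[0, 1, np.nan], [1, 0, 2], [np.nan, 2, 0]])
        with pytest.raises(ValueError, match="complete"):
            average_linkage_tree(_complete_supermatrix("ABC", D))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_scipy_average_linkage(self, seed):
        """Cluster memberships and merge heights agree with an independent
        average-linkage (UPGMA) implementation on random matrices."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        pts = rng.uniform(0, 10, size=(n, 3))
        D = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(pts)
        )
        labels = [f"L{i}" for i in range(n)]
        t = average_linkage_tree(_complete_supermatrix(labels, D))
        Z = scipy.cluster.hierarchy.linkage(
            scipy.spatial.distance.squareform(D), method="average"
        )
        # scipy merge k joins clusters into node n+k at height Z[k, 2]
        members = {i: frozenset([labels[i]]) for i in range(n)}
        expected = set()
        for k, (a, b, h, _) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            expected.add((merged, round(float(h), 9)))
        got = {
            (frozenset(t.leaves_under(v)), round(t.age[v], 9))
            for v in t.postorder()
            if not t.is_leaf(v)
        }
        assert got == expected

    def test_merge_sequence_matches_records(self):
        """UPGMA on a record-derived matrix re-creates the record clusters."""
        records = [
            ClusterRecord("C1", frozenset("AB"), 1.0, 1),
            ClusterRecord("C2", frozenset("ABE"), 2.5, 2),
            ClusterRecord("C3", frozenset("CD"), 3.0, 3),
            ClusterRecord("C4", frozenset("ABCDE"), 4.0, 4),
        ]
        S = complete_matrix_from_records(records, "ABCDE")
        t = average_linkage_tree(S)
        got = {
            (frozenset(t.leaves_under(v)), t.age[v])
            for v in t.postorder()
            if not t.is_leaf(v)
        }
        assert got == {(r.members, r.merge_age) for r in records}


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def _random_violating_instance(seed, n=10, sd=0.4):
    t = random_model(n, seed, root_age=50.0)
    rng = np.random.default_rng(seed + 1000)
    obs = {
        v: (t.age[v] * float(np.exp(rng.normal(0, sd))) if not t.is_leaf(v) else 0.0)
        for v in t.postorder()
    }
    return t, obs


def _qp_oracle(tree, obs):
    """Independent constrained-QP solve (SLSQP) of the smoothing problem."""
    internal = [v for v in tree.postorder() if not tree.is_leaf(v)]
    idx = {v: i for i, v in enumerate(internal)}
    y = np.array([obs[v] for v in internal])
    cons = []
    for v in internal:
        p = tree.parent[v]
        if p is not None:
            cons.append({"type": "ineq",
                         "fun": lambda a, i=idx[p], j=idx[v]: a[i] - a[j]})
        cons.append({"type": "ineq", "fun": lambda a, j=idx[v]: a[j]})
    res = scipy.optimize.minimize(
        lambda a: float((a - y) @ (a - y)),
        np.maximum.accumulate(np.maximum(y, 0.0)),
        jac=lambda a: 2 * (a - y),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return float(res.fun)


class TestSmoothing:
    def test_feasible_input_unchanged(self):
        t = random_model(10, 0)
        sm = smooth_to_ultrametric(t)
        assert trees_equal(t, sm)

    def test_cherry_pooled_mean(self):
        t = parse_timetree("((A:1,B:1):1,C:2);")
        sm = smooth_to_ultrametric(t, {t.mrca({"A", "B"}): 10.0, t.root: 8.0})
        assert sm.age[sm.mrca({"A", "B"})] == pytest.approx(9.0, abs=1e-6)
        assert sm.root_age == pytest.approx(9.0, abs=1e-6)

    def test_tips_anchored_and_monotone(self):
        t, obs = _random_violating_instance(5)
        sm = smooth_to_ultrametric(t, obs)
        for v in sm.postorder():
            if sm.is_leaf(v):
                assert sm.age[v] == 0.0
            p = sm.parent[v]
            if p is not None:
                assert sm.age[p] >= sm.age[v] - 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_matches_qp_oracle(self, seed):
        t, obs = _random_violating_instance(seed)
        sm = smooth_to_ultrametric(t, obs)
        obj = sum(
            (sm.age[v] - obs[v]) ** 2
            for v in t.postorder()
            if not t.is_leaf(v)
        )
        oracle = _qp_oracle(t, obs)
        assert obj <= oracle + 1e-6
        assert obj >= oracle - 1e-6  # oracle itself is optimal up to tolerance


# --------------------------------------------------------------------------
# the full loop
# --------------------------------------------------------------------------

class TestRunChronoSta:
    def test_single_tree_identity(self, seven_taxon_model):
        res = run_chrono_sta([seven_taxon_model])
        assert trees_equal(res.supertree, seven_taxon_model, age_tol=1e-9)

    def test_two_identical_trees(self, seven_taxon_model):
        res = run_chrono_sta([seven_taxon_model, seven_taxon_model.copy()])
        assert trees_equal(res.supertree, seven_taxon_model, age_tol=1e-9)

    def test_two_overlapping_restrictions(self, balanced_four_taxon_model):
        """Hand-executable case: AB=1 merges first; backpropagation into the
        {B,C,D} tree transfers its distances to the cluster; CD=2 merges
        next; the final merge lands at the model root age 3."""
        m = balanced_four_taxon_model
        res = run_chrono_sta(
            [m.restrict_to({"A", "B", "C"}), m.restrict_to({"B", "C", "D"})]
        )
        assert trees_equal(res.supertree, m, age_tol=1e-9)
        ages = [r.merge_age for r in res.records]
        assert ages == pytest.approx([1.0, 2.0, 3.0])

    def test_sparse_seven_taxon_recovery(
        self, seven_taxon_model, sparse_seven_taxon_collection
    ):
        """Recovery is exact even though 8 of 21 leaf pairs never co-occur."""
        res = run_chrono_sta(sparse_seven_taxon_collection)
        rf, nrf = normalized_rf(seven_taxon_model, res.supertree)
        assert nrf == 0.0
        assert trees_equal(res.supertree, seven_taxon_model, age_tol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_recovery_complete_cooccurrence(self, seed):
        """Noiseless leaf-restricted collections with complete pairwise
        co-occurrence are recovered exactly, topology and ages."""
        n = 8 + 3 * seed
        model = random_model(n, seed)
        trees = complete_cooccurrence_collection(model, seed)
        res = run_chrono_sta(trees)
        assert trees_equal(res.supertree, model, age_tol=1e-9)

    def test_record_count_and_leaf_union(self, sparse_seven_taxon_collection):
        res = run_chrono_sta(sparse_seven_taxon_collection)
        union = set().union(*(t.leaf_labels for t in sparse_seven_taxon_collection))
        assert res.supertree.leaf_labels == union
        assert len(res.records) == len(union) - 1
        assert not np.isnan(res.completed_matrix.D).any()

    def test_records_match_final_tree_when_monotone(
        self, sparse_seven_taxon_collection
    ):
        res = run_chrono_sta(sparse_seven_taxon_collection)
        ages = [r.merge_age for r in res.records]
        assert ages == sorted(ages)  # monotone here, so the stages coincide
        tree_clades = {
            (frozenset(res.supertree.leaves_under(v)), res.supertree.age[v])
            for v in res.supertree.postorder()
            if not res.supertree.is_leaf(v)
        }
        assert tree_clades == {(r.members, r.merge_age) for r in res.records}

    def test_disconnected_collection_reported(self):
        t1 = parse_timetree("(A:1,B:1);")
        t2 = parse_timetree("(C:2,D:2);")
        with pytest.raises(DisconnectedCollectionError) as exc:
            run_chrono_sta([t1, t2])
        comps = exc.value.components
        assert len(comps) == 2
        assert frozenset({"A", "B"}) in comps

    def test_diagnostics_populated(self, sparse_seven_taxon_collection):
        res = run_chrono_sta(sparse_seven_taxon_collection)
        assert len(res.diagnostics) == len(res.records)
        first = res.diagnostics[0]
        assert {"iteration", "pair", "merge_age", "support",
                "n_missing_cells"} <= set(first)


class TestOutgroupGraft:
    def test_graft_adds_root_cherry(self):
        t = parse_timetree("(A:1,B:1);")
        g = graft_outgroup(t, "OUT", 10.0)
        assert g.root_age == pytest.approx(10.0)
        assert g.leaf_labels == {"A", "B", "OUT"}
        assert g.mrca_age({"A", "B"}) == pytest.approx(1.0)

    def test_graft_age_must_exceed_root(self):
        t = parse_timetree("(A:5,B:5);")
        with pytest.raises(ValueError, match="exceed"):
            graft_outgroup(t, "OUT", 4.0)

    def test_outgroups_connect_disjoint_collections(self):
        t1 = parse_timetree("(A:1,B:1);")
        t2 = parse_timetree("(C:2,D:2);")
        model = ChronoSTA([t1, t2], outgroups=[("OUT", 10.0)])
        res = model.fit()
        assert res.supertree.leaf_labels == {"A", "B", "C", "D", "OUT"}


class TestModelResultsSurface:
    def test_fit_summary_and_frames(self, sparse_seven_taxon_collection):
        res = ChronoSTA(sparse_seven_taxon_collection).fit()
        s = res.summary()
        assert "Chrono-STA supertree" in s and "merge_age" in s
        rf = res.records_frame()
        assert list(rf["iteration"]) == list(range(1, 7))
        assert set(rf.columns) >= {"cluster_id", "merge_age", "members", "support"}
        df = res.diagnostics_frame()
        assert len(df) == 6

    def test_results_evaluate(self, seven_taxon_model, sparse_seven_taxon_collection):
        res = ChronoSTA(sparse_seven_taxon_collection).fit()
        report = res.evaluate(seven_taxon_model)
        assert report.nrf == 0.0
        assert report.slope == pytest.approx(1.0)
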
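import math

import numpy as np
import pytest

import hetrank as hr
from hetrank.data_io import DataError


def expr(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"g{i}" for i in range(rows.shape[0])]
    return hr.ExpressionMatrix(
        hr.NodeIndex.from_ids(ids, "lncRNA"),
        tuple(f"s{j}" for j in range(rows.shape[1])),
        rows,
    )


class TestPearsonNetwork:
    def test_identical_rows_get_weight_one(self):
        base = np.arange(10, dtype=float)
        net = hr.pearson_similarity_network(expr([base, base + 5.0]))
        assert net.weights[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert net.weights[0, 0] == 0  # diagonal zeroed

    def test_zero_correlation_is_zero_weight(self):
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        net = hr.pearson_similarity_network(expr([a, b]))
        assert net.weights[0, 1] == 0.0

    def test_strong_negative_correlation_zeroed(self):
        rng = np.random.default_rng(3)
        a = np.arange(20) + 0.1 * rng.standard_normal(20)
        net = hr.pearson_similarity_network(expr([a, -a]))
        # r ~ -1, p << 0.01, but the network keeps positive correlations only
        assert net.weights[0, 1] == 0.0

    def test_nonsignificant_positive_correlation_zeroed(self):
        # n=4 samples: even r=0.9 has p > 0.01
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = np.array([0.0, 1.3, 1.7, 3.2])
        net = hr.pearson_similarity_network(expr([a, b]))
        assert net.weights[0, 1] == 0.0

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(DataError, match="samples"):
            hr.pearson_similarity_network(expr([[1.0, 2.0], [2.0, 1.0]]))

    def test_zero_variance_row_contributes_nothing(self):
        net = hr.pearson_similarity_network(expr([[1.0] * 10, list(range(10)), list(range(10))]))
        assert np.all(net.weights[0] == 0) and np.all(net.weights[:, 0] == 0)
        assert net.weights[1, 2] == pytest.approx(1.0)

    def test_pvalue_matches_scipy_pearsonr(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        rows = rng.standard_normal((6, 15))
        net = hr.pearson_similarity_network(expr(rows), p_threshold=0.01)
        for i in range(6):
            for j in range(i + 1, 6):
                r, p = stats.pearsonr(rows[i], rows[j])
                expected = r if (r > 0 and p < 0.01) else 0.0
                assert net.weights[i, j] == pytest.approx(expected, abs=1e-10)


def bipartite(edges, left_ids, right_ids, kinds=("lncRNA", "miRNA")):
    return hr.BipartiteInteractions(
        hr.NodeIndex.from_ids(left_ids, kinds[0]),
        hr.NodeIndex.from_ids(right_ids, kinds[1]),
        frozenset(edges),
    )


class TestGipKernel:
    def test_disjoint_singleton_profiles_give_exp_minus_two(self):
        # two nodes, profiles (1,0) and (0,1): bandwidth 1, squared distance 2
        b = bipartite({("l1", "m1"), ("l2", "m2")}, ["l1", "l2"], ["m1", "m2"])
        net = hr.gip_kernel_matrix(b)
        assert net.weights[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_identical_profiles_give_one(self):
        b = bipartite({("l1", "m1"), ("l2", "m1"), ("l3", "m2")}, ["l1", "l2", "l3"], ["m1", "m2"])
        net = hr.gip_kernel_matrix(b)
        assert net.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_empty_profile_vs_singleton(self):
        b = bipartite({("l1", "m1")}, ["l1", "l2"], ["m1"])
        # norms: 1 and 0, kappa = 1/(1/2) = 2, distance^2 = 1
        net = hr.gip_kernel_matrix(b)
        assert net.weights[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_all_profiles_empty_rejected(self):
        b = bipartite(set(), ["l1", "l2"], ["m1"])
        with pytest.raises(DataError, match="bandwidth"):
            hr.gip_kernel_matrix(b)

    def test_right_side_and_scalar_oracle(self):
        rng = np.random.default_rng(5)
        inc = (rng.random((6, 8)) < 0.4).astype(float)
        edges = {(f"l{i}", f"m{j}") for i, j in zip(*np.nonzero(inc))}
        b = bipartite(edges, [f"l{i}" for i in range(6)], [f"m{j}" for j in range(8)])
        for side, mat in (("left", inc), ("right", inc.T)):
            net = hr.gip_kernel_matrix(b, side=side)
            kappa = 1.0 / np.mean([np.dot(r, r) for r in mat])
            n = mat.shape[0]
            for i in range(n):
                for j in range(n):
                    d2 = float(np.sum((mat[i] - mat[j]) ** 2))
                    want = 0.0 if i == j else math.exp(-kappa * d2)
                    assert net.weights[i, j] == pytest.approx(want, abs=1e-12)

    def test_partner_permutation_invariance(self):
        rng = np.random.default_rng(8)
        inc = (rng.random((5, 7)) < 0.5).astype(float)
        left = [f"l{i}" for i in range(5)]
        right = [f"m{j}" for j in range(7)]
        edges = {(left[i], right[j]) for i, j in zip(*np.nonzero(inc))}
        net = hr.gip_kernel_matrix(bipartite(edges, left, right))
        perm = rng.permutation(7)
        net_p = hr.gip_kernel_matrix(bipartite(edges, left, [right[p] for p in perm]))
        np.testing.assert_allclose(net.weights, net_p.weights, atol=1e-14)


def chain_dag(*levels):
    """levels[0] is the root; each subsequent term is_a the previous."""
    edges = {(levels[i], levels[i - 1]) for i in range(1, len(levels))}
    return hr.OntologyDAG(hr.NodeIndex.from_ids(levels, "disease"), frozenset(edges))


def wang_oracle(dag, a, b, w=0.8):
    """Memo-free recursive evaluation of Wang's measure."""

    def svalue(anchor, t):
        if t == anchor:
            return 1.0
        kids = [c for c in dag.ancestors_and_self(anchor) if t in dag.parents(c)]
        return w * max(svalue(anchor, c) for c in kids)

    ta = dag.ancestors_and_self(a)
    tb = dag.ancestors_and_self(b)
    sva = sum(svalue(a, t) for t in ta)
    svb = sum(svalue(b, t) for t in tb)
    num = sum(svalue(a, t) + svalue(b, t) for t in ta & tb)
    return num / (sva + svb)


class TestWangSimilarity:
    def test_child_of_root(self):
        dag = chain_dag("R", "A")
        terms = hr.NodeIndex.from_ids(["A", "R"], "disease")
        net = hr.ontology_similarity_matrix(dag, terms)
        # SV(A)=1.8, SV(R)=1, shared {R}: (0.8+1)/2.8
        assert net.weights[0, 1] == pytest.approx(1.8 / 2.8, abs=1e-12)

    def test_self_similarity_is_identity_of_measure(self):
        dag = chain_dag("R", "B", "A")
        assert wang_oracle(dag, "A", "A") == pytest.approx(1.0, abs=1e-15)
        # the returned network zeroes the diagonal by design
        net = hr.ontology_similarity_matrix(dag, hr.NodeIndex.from_ids(["A"], "disease"))
        assert net.weights[0, 0] == 0.0

    def test_disjoint_roots_score_zero(self):
        terms = ["R1", "R2", "A", "B"]
        edges = {("A", "R1"), ("B", "R2")}
        dag = hr.OntologyDAG(hr.NodeIndex.from_ids(terms, "disease"), frozenset(edges))
        net = hr.ontology_similarity_matrix(dag, hr.NodeIndex.from_ids(["A", "B"], "disease"))
        assert net.weights[0, 1] == 0.0

    def test_deeper_shared_parent_scores_higher(self):
        # siblings under a depth-2 parent vs terms sharing only the root
        terms = ["R", "P", "Q", "A", "B", "C"]
        edges = {("P", "R"), ("Q", "P"), ("A", "Q"), ("B", "Q"), ("C", "R")}
        dag = hr.OntologyDAG(hr.NodeIndex.from_ids(terms, "disease"), frozenset(edges))
        idx = hr.NodeIndex.from_ids(["A", "B", "C"], "disease")
        net = hr.ontology_similarity_matrix(dag, idx)
        assert net.weights[0, 1] > net.weights[0, 2] > 0

    def test_matches_recursive_oracle_on_random_dags(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = 12
            terms = [f"T{t}" for t in range(n)]
            edges = set()
            for i in range(1, n):
                # each term gets 1-2 parents among earlier terms: acyclic by construction
                for p in rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False):
                    edges.add((terms[i], terms[p]))
            dag = hr.OntologyDAG(hr.NodeIndex.from_ids(terms, "disease"), frozenset(edges))
            idx = hr.NodeIndex.from_ids(terms[: n // 2], "disease")
            net = hr.ontology_similarity_matrix(dag, idx)
            for i, a in enumerate(idx.ids):
                for j, b in enumerate(idx.ids):
                    if i != j:
                        assert net.weights[i, j] == pytest.approx(
                            wang_oracle(dag, a, b), abs=1e-12
                        )

    def test_unknown_term_named_in_error(self):
        dag = chain_dag("R", "A")
        with pytest.raises(DataError, match="NOPE"):
            hr.ontology_similarity_matrix(dag, hr.NodeIndex.from_ids(["NOPE"], "disease"))


class TestSimilarityNetworkInvariants:
    @pytest.mark.parametrize("builder", ["pearson", "gip", "wang"])
    def test_symmetric_nonnegative_zero_diagonal(self, builder, planted):
        if builder == "pearson":
            net = hr.pearson_similarity_network(planted.expression)
        elif builder == "gip":
            net = hr.gip_kernel_matrix(planted.lnc_mirna)
        else:
            terms = hr.NodeIndex.from_ids(planted.associations.disease_index.ids, "disease")
            net = hr.ontology_similarity_matrix(planted.ontology, terms)
        w = net.weights
        assert np.array_equal(w, w.T)
        assert np.all(w >= 0) and np.all(np.isfinite(w))
        assert np.all(np.diag(w) == 0)
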
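import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import vocseq
from vocseq.calltypes import _jsd_similarity


def blobs(rng, means, n_per, sd=1.0):
    pts = [rng.normal(m, sd, size=(n_per, 2)) for m in means]
    labels = np.repeat(np.arange(len(means)), n_per)
    x = np.vstack(pts)
    order = rng.permutation(len(x))
    return x[order], labels[order]


class TestClusterSelection:
    def test_two_separated_blobs_choose_k2(self, rng):
        x, _ = blobs(rng, [(0, 0), (8, 8)], 100)
        sel = vocseq.select_cluster_model(x, k_range=range(2, 6), seed=0)
        assert sel.chosen_k == 2
        assert ((sel.table.silhouette >= -1) & (sel.table.silhouette <= 1)).all()
        assert np.isfinite(sel.table.aic).all()

    def test_too_few_points_is_size_error(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="too small"):
            vocseq.select_cluster_model(x, k_range=range(2, 21))

    def test_assignment_at_component_mean(self, rng):
        x, _ = blobs(rng, [(0, 0), (8, 8)], 100)
        sel = vocseq.select_cluster_model(x, k_range=range(2, 4), seed=0)
        # the raw-space blob centres map onto distinct mixture components
        labels = vocseq.assign_types(sel, np.array([(0.0, 0.0), (8.0, 8.0)]))
        assert labels[0] != labels[1]
        assert set(labels) <= set(range(1, sel.chosen_k + 1))

    def test_label_count_conserved(self, rng):
        x, _ = blobs(rng, [(0, 0), (8, 8)], 60)
        sel = vocseq.select_cluster_model(x, k_range=range(2, 4), seed=0)
        assert len(vocseq.assign_types(sel, x)) == len(x)


class TestTransitionTable:
    def test_alternating_sequence(self):
        t = vocseq.build_transition_table(np.array([1, 2, 1, 2, 1]), k=2)
        assert t.counts.tolist() == [[0, 2], [2, 0]]
        assert t.probabilities.tolist() == [[0, 1], [1, 0]]

    def test_session_boundary_not_crossed(self):
        t = vocseq.build_transition_table([np.array([1, 2]), np.array([2, 1])], k=2)
        assert t.n_transitions == 2
        assert t.counts[1, 1] == 0  # no 2->2 across the boundary

    def test_counts_conserved_against_pair_enumeration(self, rng):
        labels = rng.integers(1, 6, size=100)
        t = vocseq.build_transition_table(labels, k=5)
        # independent oracle: count pairs one by one
        expected = {}
        for a, b in zip(labels[:-1], labels[1:]):
            expected[(a, b)] = expected.get((a, b), 0) + 1
        assert t.n_transitions == 99
        for (a, b), c in expected.items():
            assert t.counts[a - 1, b - 1] == c

    def test_unvisited_rows_stay_zero(self):
        t = vocseq.build_transition_table(np.array([1, 1, 1]), k=3)
        assert t.probabilities[1].sum() == 0
        assert t.probabilities[0, 0] == 1

    def test_short_sequence_yields_empty_table(self):
        t = vocseq.build_transition_table(np.array([2]), k=3)
        assert t.n_transitions == 0


def oracle_table_identity_similarity(counts_a, counts_b):
    """Independent oracle: 1 - MI(T;E)/H(T) computed from the joint
    distribution of the uniform binary table variable T and the cell
    variable E, term by term."""
    pa = np.asarray(counts_a, float).ravel()
    pb = np.asarray(counts_b, float).ravel()
    pa, pb = pa / pa.sum(), pb / pb.sum()
    joint = np.stack([0.5 * pa, 0.5 * pb])  # P(T=t, E=e)
    pe = joint.sum(axis=0)
    mi = 0.0
    for t in range(2):
        for e in range(joint.shape[1]):
            if joint[t, e] > 0:
                mi += joint[t, e] * math.log2(joint[t, e] / (0.5 * pe[e]))
    return 1.0 - mi / 1.0  # H(T) = 1 bit


class TestNmiSimilarity:
    def test_identical_tables_are_maximally_similar(self, rng):
        labels = rng.integers(1, 4, size=50)
        t = vocseq.build_transition_table(labels, k=3)
        assert vocseq.nmi_similarity(t, t) == 1.0

    def test_disjoint_supports_are_maximally_different(self):
        a = vocseq.build_transition_table(np.array([1, 2]), k=2)
        b = vocseq.build_transition_table(np.array([2, 1]), k=2)
        assert vocseq.nmi_similarity(a, b) == 0.0

    def test_matches_mutual_information_oracle(self):
        # one table concentrated on (1->1), the other uniform over 4 cells
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[1, 1], [1, 1]])
        expected = oracle_table_identity_similarity(a, b)
        got = _jsd_similarity(a.ravel().astype(float), b.ravel().astype(float))
        assert got == pytest.approx(expected, abs=1e-12)
        # frozen value of the hand-evaluated construction
        assert got == pytest.approx(0.45121, abs=1e-4)

    @given(
        st.lists(st.integers(0, 10), min_size=9, max_size=9),
        st.lists(st.integers(0, 10), min_size=9, max_size=9),
        st.permutations(list(range(3))),
    )
    def test_symmetric_and_relabeling_invariant(self, ca, cb, perm):
        a = np.array(ca).reshape(3, 3)
        b = np.array(cb).reshape(3, 3)
        ta = vocseq.TransitionTable(3, a)
        tb = vocseq.TransitionTable(3, b)
        s = vocseq.nmi_similarity(ta, tb)
        assert s == pytest.approx(vocseq.nmi_similarity(tb, ta))
        perm = list(perm)
        tap = vocseq.TransitionTable(3, a[perm][:, perm])
        tbp = vocseq.TransitionTable(3, b[perm][:, perm])
        assert vocseq.nmi_similarity(tap, tbp) == pytest.approx(s)
        assert 0 <= s <= 1

    def test_empty_tables_degenerate_identity(self):
        empty = vocseq.TransitionTable(2, np.zeros((2, 2), dtype=int))
        assert vocseq.nmi_similarity(empty, empty) == 1.0


class TestPermutationTest:
    def test_relabeled_copy_is_maximally_similar(self):
        seq = np.array([1, 2, 3, 1, 2, 3, 2, 1, 3, 3, 1, 2])
        types = np.concatenate([seq, seq])
        groups = np.repeat([0, 1], len(seq))
        res = vocseq.permutation_test(types, groups, n_perm=200, seed=0)
        assert res.observed_nmi == 1.0
        assert res.p_value == 1.0

    def test_disjoint_transition_supports_rejected(self):
        a = np.tile([1, 2], 30)
        b = np.tile([3, 4], 30)
        types = np.concatenate([a, b])
        groups = np.repeat([0, 1], 60)
        res = vocseq.permutation_test(types, groups, n_perm=200, seed=0)
        assert res.observed_nmi == 0.0
        assert res.p_value <= 0.01

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            vocseq.permutation_test(np.array([1, 2, 1]), np.array([0, 0, 0]), n_perm=100)

    def test_null_p_values_are_uniform(self):
        # Kolmogorov-Smirnov check over replicated null datasets
        pvals = []
        for rep in range(500):
            data = vocseq.two_subject_scenario("none", seed=10_000 + rep)
            res = vocseq.permutation_test(
                data.types, data.groups, data.sessions, n_perm=200, seed=rep
            )
            pvals.append(res.p_value)
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_small_n_perm_warns(self, caplog):
        types = np.tile([1, 2, 1, 2, 2, 1], 4)
        groups = np.repeat([0, 1], 12)
        with caplog.at_level("WARNING"):
            vocseq.permutation_test(types, groups, n_perm=50, seed=0)
        assert any("n_perm" in r.message for r in caplog.records)


def test_within_table_nmi_bounds(rng):
    labels = rng.integers(1, 5, size=200)
    t = vocseq.build_transition_table(labels, k=4)
    assert 0 <= vocseq.within_table_nmi(t) <= 1
    determ = vocseq.build_transition_table(np.tile([1, 2, 3, 4], 25), k=4)
    assert vocseq.within_table_nmi(determ) == pytest.approx(1.0)
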
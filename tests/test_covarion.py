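import math

import numpy as np
import pytest
from scipy.linalg import expm

from lexiclade.covarion import (
    CovarionParams,
    TransitionKernel,
    brute_force_log_likelihood,
    covarion_rate_matrix,
    tree_log_likelihood,
)
from lexiclade.trees import Tree
from lexiclade.wordlist import BinaryMatrix


@pytest.fixture
def matrix4(tree4):
    cells = np.array([[1, 0, 1], [1, 1, -1], [0, 1, 0], [0, 1, 1]], dtype=np.int8)
    return BinaryMatrix(list("ABCD"), [1, 2, 3], ["c1", "c1", "c2"], cells,
                        ["p1", "p1", "p2"])


class TestRateMatrix:
    def test_reduces_to_symmetric_binary(self):
        p = CovarionParams(1.0, 1e-12)
        Q = covarion_rate_matrix(p)
        # both classes identical symmetric process, expected rate 1
        assert np.isclose(Q[0, 1], Q[2, 3])
        assert np.isclose(Q[0, 1], 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stationarity(self, seed):
        rng = np.random.default_rng(seed)
        f1 = rng.uniform(0.2, 0.8)
        pf = rng.uniform(0.2, 0.8)
        p = CovarionParams(rng.uniform(0.05, 1.0), rng.uniform(0.01, 3.0),
                          (1 - f1, f1), (pf, 1 - pf))
        Q = covarion_rate_matrix(p)
        assert np.abs(p.stationary @ Q).max() < 1e-12
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_unit_expected_visible_rate(self):
        p = CovarionParams(0.3, 0.8, (0.4, 0.6), (0.7, 0.3))
        Q = covarion_rate_matrix(p)
        pi = p.stationary
        vis = pi[0] * Q[0, 1] + pi[1] * Q[1, 0] + pi[2] * Q[2, 3] + pi[3] * Q[3, 2]
        assert np.isclose(vis, 1.0)

    def test_transition_probs_match_series_oracle(self):
        p = CovarionParams(0.5, 0.7)
        Q = covarion_rate_matrix(p)
        t = 0.5
        series = np.zeros((4, 4))
        term = np.eye(4)
        for k in range(60):
            series += term
            term = term @ Q * (t / (k + 1))
        P = TransitionKernel(Q).probs(np.array([t]))[0]
        assert np.abs(P - series).max() < 1e-10

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CovarionParams(0.0, 1.0)
        with pytest.raises(ValueError):
            CovarionParams(0.5, -1.0)
        with pytest.raises(ValueError):
            CovarionParams(0.5, 1.0, (0.3, 0.6))


class TestTreeLikelihood:
    def test_single_tip_present_character(self):
        t = Tree(["A"], np.array([-1]), np.array([[-1, -1]]),
                 np.array([0.0]), np.array([1.0]), 0)
        m = BinaryMatrix(["A"], [1], ["c"], np.array([[1]], dtype=np.int8))
        ll = tree_log_likelihood(m, t, CovarionParams(0.5, 0.5), ascertainment=False)
        assert np.isclose(ll, math.log(0.5))  # f1 marginalised over classes

    @pytest.mark.parametrize("ascertainment", [False, True])
    @pytest.mark.parametrize("alpha,s", [(0.4, 0.7), (1.0, 0.01), (0.2, 2.0)])
    def test_pruning_equals_enumeration(self, tree4, matrix4, alpha, s, ascertainment):
        p = CovarionParams(alpha, s)
        a = tree_log_likelihood(matrix4, tree4, p, ascertainment=ascertainment)
        b = brute_force_log_likelihood(matrix4, tree4, p, ascertainment=ascertainment)
        assert abs(a - b) < 1e-10

    def test_switch_zero_is_mixture_of_binary_models(self, tree4, matrix4):
        """With s = 0 the covarion is a 2-component mixture of binary CTMCs."""
        pf, ps = 0.6, 0.4
        alpha = 0.35
        p = CovarionParams(alpha, 0.0, hidden_freqs=(pf, ps))
        got = tree_log_likelihood(matrix4, tree4, p, ascertainment=False)
        # the normalised generator gives visible off-diagonal rate
        # 0.5/norm (fast) and 0.5*alpha/norm (slow)
        norm = 2 * 0.25 * (pf + alpha * ps)
        durs = tree4.branch_durations()

        def binary_loglik_per_char(rate):
            Q2 = np.array([[-0.5, 0.5], [0.5, -0.5]]) * rate / 0.5
            Ps = [expm(Q2 * d) for d in durs]
            out = []
            order = [tree4.labels.index(x) for x in matrix4.taxa]
            for j in range(matrix4.n_chars):
                col = matrix4.cells[:, j]
                tips = {node: {1: [1], 0: [0], -1: [0, 1]}[int(col[r])]
                        for r, node in enumerate(order)}
                total = 0.0
                from itertools import product
                internals = [i for i in range(tree4.n_nodes) if not tree4.is_tip(i)]
                for st in product(range(2), repeat=len(internals)):
                    for tp in product(*(tips[t] for t in range(tree4.n_tips))):
                        states = dict(zip(internals, st))
                        states.update(dict(enumerate(tp)))
                        pr = 0.5
                        for i in range(tree4.n_nodes):
                            if i != tree4.root:
                                pr *= Ps[i][states[tree4.parent[i]], states[i]]
                        total += pr
                out.append(total)
            return np.array(out)

        lf = binary_loglik_per_char(0.5 / norm)
        ls = binary_loglik_per_char(0.5 * alpha / norm)
        expect = float(np.log(pf * lf + ps * ls).sum())
        assert abs(got - expect) < 1e-8

    def test_invariant_under_reordering(self, tree4, matrix4):
        base = tree_log_likelihood(matrix4, tree4, CovarionParams(0.4, 0.6))
        perm = [2, 0, 3, 1]
        m2 = BinaryMatrix([matrix4.taxa[i] for i in perm], list(matrix4.characters),
                          list(matrix4.char_concepts), matrix4.cells[perm],
                          list(matrix4.partitions))
        assert np.isclose(tree_log_likelihood(m2, tree4, CovarionParams(0.4, 0.6)), base)
        cperm = [2, 1, 0]
        m3 = BinaryMatrix(list(matrix4.taxa), [matrix4.characters[j] for j in cperm],
                          [matrix4.char_concepts[j] for j in cperm],
                          matrix4.cells[:, cperm],
                          [matrix4.partitions[j] for j in cperm])
        assert np.isclose(tree_log_likelihood(m3, tree4, CovarionParams(0.4, 0.6)), base)

    def test_ascertainment_raises_likelihood(self, tree4, matrix4):
        p = CovarionParams(0.4, 0.6)
        plain = tree_log_likelihood(matrix4, tree4, p, ascertainment=False)
        corrected = tree_log_likelihood(matrix4, tree4, p, ascertainment=True)
        assert corrected > plain

    def test_strict_rate_override_matches_equal_rates(self, tree4, matrix4):
        p = CovarionParams(0.4, 0.6)
        tree4.rates[:] = 0.73
        a = tree_log_likelihood(matrix4, tree4, p)
        b = tree_log_likelihood(matrix4, tree4, p, strict_rate=0.73)
        assert np.isclose(a, b)
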
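"""Information measures against independent brute-force oracles."""

import math
from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dataset
from targetbn.data import MISSING, from_codes
from targetbn.info_theory import (
    ParameterError,
    build_counts,
    conditional_local_mutual_information,
    conditional_mutual_information,
    local_mutual_information,
    mutual_information,
    pointwise_cmi,
    pointwise_mi,
    scmi_ranking,
    sclmi_ranking,
)


# ---------------------------------------------------------------------------
# independent oracles: direct summation over the empirical joint distribution
# ---------------------------------------------------------------------------

def mi_oracle(x, y, base=2.0):
    n = len(x)
    pxy = Counter(zip(x, y))
    px, py = Counter(x), Counter(y)
    return sum(
        (c / n) * math.log((c / n) / ((px[a] / n) * (py[b] / n)), base)
        for (a, b), c in pxy.items()
    )


def cmi_oracle(x1, x2, y, base=2.0):
    n = len(y)
    out = 0.0
    for c in set(y):
        idx = [t for t in range(n) if y[t] == c]
        pc = len(idx) / n
        sub1 = [x1[t] for t in idx]
        sub2 = [x2[t] for t in idx]
        out += pc * mi_oracle(sub1, sub2, base)
    return out


class TestBuildCounts:
    def test_direct_tally(self, toy_cache):
        assert toy_cache.n_total == 8
        assert list(toy_cache.class_counts) == [4, 4]
        assert toy_cache.value_counts[0].tolist() == [[3, 1], [1, 3]]

    def test_missing_cell_excluded_per_attribute(self):
        X = np.array([[MISSING, 1], [0, 0], [1, 1]])
        ds = from_codes(X, [0, 1, 1], [2, 2])
        cache = build_counts(ds)
        assert cache.value_counts[0].sum() == 2  # row 0 dropped for X1 only
        assert cache.value_counts[1].sum() == 3
        assert cache.pair(0, 1).sum() == 2

    def test_pair_symmetry(self, ):
        rng = np.random.default_rng(0)
        cache = build_counts(random_dataset(rng, n=3, v=3))
        assert np.array_equal(cache.pair(0, 2), cache.pair(2, 0).transpose(1, 0, 2))

    def test_marginalizing_pairs_reproduces_value_counts(self):
        rng = np.random.default_rng(1)
        cache = build_counts(random_dataset(rng, n=3, v=3))
        assert np.array_equal(cache.pair(0, 1).sum(axis=1), cache.value_counts[0])

    def test_empty_dataset_rejected(self):
        with pytest.raises(Exception):
            from_codes(np.zeros((0, 1), int), [], [2])


class TestMutualInformation:
    def test_deterministic_copy_is_one_bit(self):
        ds = from_codes(np.array([[0], [0], [1], [1]]), [0, 0, 1, 1], [2])
        assert mutual_information(build_counts(ds), 0) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        X = np.array([[0], [1], [0], [1]])
        ds = from_codes(X, [0, 0, 1, 1], [2])
        assert mutual_information(build_counts(ds), 0) == pytest.approx(0.0)

    def test_toy_joint_matches_direct_summation(self, toy_cache, toy_binary):
        # frozen from the 4-cell oracle: 0.75*log2(1.5) - 0.25
        expected = 0.75 * math.log2(1.5) - 0.25
        assert expected == pytest.approx(0.1887, abs=5e-5)
        got = mutual_information(toy_cache, 0)
        assert got == pytest.approx(expected, abs=1e-12)
        x = toy_binary.codes()[:, 0]
        assert got == pytest.approx(mi_oracle(x, toy_binary.labels), abs=1e-12)


class TestConditionalMutualInformation:
    def test_conditional_independence_is_zero(self):
        # X2 value distribution identical across X1 values within each class
        rows, ys = [], []
        for c in range(2):
            for a in range(2):
                for b in range(2):
                    rows.append([a, b]); ys.append(c)
        ds = from_codes(np.array(rows), ys, [2, 2])
        assert conditional_mutual_information(build_counts(ds), 0, 1) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_single_class_reduces_to_mi(self):
        X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        ds = from_codes(X, [0] * 4, [2, 2], class_domain=(0,))
        assert conditional_mutual_information(build_counts(ds), 0, 1) == (
            pytest.approx(1.0)
        )

    def test_i_equals_j_rejected(self, toy_cache):
        with pytest.raises(ParameterError):
            conditional_mutual_information(toy_cache, 0, 0)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ds = random_dataset(rng, n=4, v=3, rows=60)
            cache = build_counts(ds)
            codes = ds.codes()
            for i in range(4):
                for j in range(i + 1, 4):
                    got = conditional_mutual_information(cache, i, j)
                    want = cmi_oracle(list(codes[:, i]), list(codes[:, j]),
                                      list(ds.labels))
                    assert got == pytest.approx(want, abs=1e-12)
                    assert got == pytest.approx(
                        conditional_mutual_information(cache, j, i), abs=1e-12
                    )
                    assert got >= -1e-12


class TestLocalMeasures:
    def test_lmi_two_term_sum(self):
        # value 0 occurs only with class 0; P(c0)=0.5, P(v)=0.25
        X = np.array([[0], [0], [1], [2], [1], [1], [2], [2]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cache = build_counts(from_codes(X, y, [3]))
        assert local_mutual_information(cache, 0, 0) == pytest.approx(
            0.25 * math.log2(0.25 / (0.25 * 0.5)), abs=1e-12
        )
        assert local_mutual_information(cache, 0, 0) == pytest.approx(0.25)

    def test_lmi_zero_when_value_tracks_prior(self):
        X = np.array([[0], [0], [1], [0], [0], [1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        cache = build_counts(from_codes(X, y, [2]))
        assert local_mutual_information(cache, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_clmi_never_cooccurring_pair_is_zero(self):
        X = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        cache = build_counts(from_codes(X, [0, 0, 1, 1], [2, 2]))
        assert conditional_local_mutual_information(cache, 0, 0, 1, 0) == 0.0

    def test_clmi_requires_distinct_attributes(self, toy_cache):
        with pytest.raises(ParameterError):
            conditional_local_mutual_information(toy_cache, 0, 0, 0, 0)

    def test_clmi_symmetric_in_value_pairs(self):
        rng = np.random.default_rng(3)
        cache = build_counts(random_dataset(rng, n=2, v=3, rows=50))
        for a, b in product(range(3), range(3)):
            assert conditional_local_mutual_information(cache, 0, a, 1, b) == (
                pytest.approx(
                    conditional_local_mutual_information(cache, 1, b, 0, a),
                    abs=1e-12,
                )
            )


class TestDecompositionIdentities:
    """Sum of value-level measures equals the distribution-level measure."""

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_lmi_sums_to_mi_and_clmi_to_cmi(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n=3, v=3, rows=int(rng.integers(5, 60)),
                            missing=float(rng.choice([0.0, 0.15])))
        cache = build_counts(ds)
        for i in range(3):
            lmi_sum = sum(local_mutual_information(cache, i, v) for v in range(3))
            assert lmi_sum == pytest.approx(mutual_information(cache, i),
                                            abs=1e-10)
        for i in range(3):
            for j in range(i + 1, 3):
                clmi_sum = sum(
                    conditional_local_mutual_information(cache, i, a, j, b)
                    for a in range(3) for b in range(3)
                )
                assert clmi_sum == pytest.approx(
                    conditional_mutual_information(cache, i, j), abs=1e-10
                )


class TestLogBase:
    def test_base_change_rescales_by_ln2_and_preserves_order(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(rng, n=4, v=3, rows=80)
        c2 = build_counts(ds, log_base=2.0)
        ce = build_counts(ds, log_base=math.e)
        for i in range(4):
            assert mutual_information(c2, i) == pytest.approx(
                mutual_information(ce, i) / math.log(2), abs=1e-12
            )
        assert scmi_ranking(c2).order == scmi_ranking(ce).order


class TestRankings:
    def test_two_attributes_share_scmi_score(self):
        rng = np.random.default_rng(2)
        cache = build_counts(random_dataset(rng, n=2, v=3))
        r = scmi_ranking(cache)
        assert r.scores[0] == pytest.approx(r.scores[1])
        assert r.order == (0, 1)  # tie broken by index

    def test_hub_ranks_first(self):
        # X0 drives X1 and X2; brute-force SCMI confirms the hub wins
        rng = np.random.default_rng(4)
        x0 = rng.integers(0, 2, 600)
        x1 = np.where(rng.random(600) < 0.9, x0, 1 - x0)
        x2 = np.where(rng.random(600) < 0.9, x0, 1 - x0)
        y = rng.integers(0, 2, 600)
        ds = from_codes(np.c_[x0, x1, x2], y, [2, 2, 2])
        cache = build_counts(ds)
        r = scmi_ranking(cache)
        brute = [
            sum(cmi_oracle(list(ds.codes()[:, i]), list(ds.codes()[:, j]),
                           list(y))
                for j in range(3) if j != i)
            for i in range(3)
        ]
        assert r.order[0] == int(np.argmax(brute)) == 0
        np.testing.assert_allclose(r.scores, brute, atol=1e-10)

    def test_sclmi_excludes_missing_attributes(self):
        rng = np.random.default_rng(5)
        cache = build_counts(random_dataset(rng, n=3, v=3, rows=50))
        inst = np.array([1, MISSING, 2])
        r = sclmi_ranking(cache, inst)
        assert 1 not in r.order
        assert np.isnan(r.scores[1])
        # score of attr 0 only includes the (0, 2) term
        assert r.scores[0] == pytest.approx(
            conditional_local_mutual_information(cache, 0, 1, 2, 2)
        )

    def test_sclmi_all_missing_rejected(self):
        rng = np.random.default_rng(6)
        cache = build_counts(random_dataset(rng, n=2, v=2))
        with pytest.raises(ParameterError):
            sclmi_ranking(cache, np.array([MISSING, MISSING]))


class TestPointwise:
    def test_independent_value_class_zero(self):
        X = np.array([[0], [1], [0], [1]])
        cache = build_counts(from_codes(X, [0, 0, 1, 1], [2]))
        assert pointwise_mi(cache, 0, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_value_implies_class_one_bit(self):
        X = np.array([[0], [1]])
        cache = build_counts(from_codes(X, [0, 1], [2]))
        assert pointwise_mi(cache, 0, 0, 0) == pytest.approx(1.0)

    def test_three_way_log_ratio_oracle(self):
        rng = np.random.default_rng(8)
        ds = random_dataset(rng, n=2, v=2, rows=40)
        cache = build_counts(ds)
        codes = ds.codes()
        c_rows = ds.labels == 0
        nc = c_rows.sum()
        joint = np.mean((codes[c_rows, 0] == 1) & (codes[c_rows, 1] == 1))
        p1 = np.mean(codes[c_rows, 0] == 1)
        p2 = np.mean(codes[c_rows, 1] == 1)
        assert pointwise_cmi(cache, 0, 1, 1, 1, 0) == pytest.approx(
            math.log2(joint / (p1 * p2)), abs=1e-12
        )

    def test_zero_probability_warns_neg_inf(self):
        X = np.array([[0], [0]])
        cache = build_counts(from_codes(X, [0, 0], [2], class_domain=(0, 1)))
        with pytest.warns(UserWarning):
            assert pointwise_mi(cache, 0, 1, 0) == -np.inf
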
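import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crsig.io import FeatureTable, ValidationError
from crsig.weighting import (
    WeightVector,
    compute_all_weights,
    discretize_equal_frequency,
    normalize_weights,
    weight_chi_squared,
    weight_gain_ratio,
    weight_gini,
    weight_info_gain,
    weight_relief,
    weight_rule,
    weight_symmetric_uncertainty,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops over Counter tallies)
# ---------------------------------------------------------------------------


def entropy_oracle(values) -> float:
    n = len(values)
    return -sum(c / n * math.log2(c / n) for c in Counter(values).values())


def info_gain_oracle(f, y) -> float:
    n = len(y)
    cond = 0.0
    for v in set(f):
        ys = [yi for fi, yi in zip(f, y) if fi == v]
        cond += len(ys) / n * entropy_oracle(ys)
    return entropy_oracle(y) - cond


def chi_squared_oracle(f, y) -> float:
    n = len(y)
    stat = 0.0
    for v in set(f):
        for c in set(y):
            obs = sum(1 for fi, yi in zip(f, y) if fi == v and yi == c)
            exp = sum(1 for fi in f if fi == v) * sum(1 for yi in y if yi == c) / n
            if exp > 0:
                stat += (obs - exp) ** 2 / exp
    return stat


def gini_oracle(f, y) -> float:
    def impurity(vals):
        n = len(vals)
        return 1.0 - sum((c / n) ** 2 for c in Counter(vals).values())

    n = len(y)
    cond = 0.0
    for v in set(f):
        ys = [yi for fi, yi in zip(f, y) if fi == v]
        cond += len(ys) / n * impurity(ys)
    return impurity(y) - cond


def rule_oracle(f, y) -> float:
    """Exhaustive search over all threshold splits / level rules."""
    n = len(y)
    if isinstance(f[0], str):
        correct = 0
        for v in set(f):
            ys = [yi for fi, yi in zip(f, y) if fi == v]
            correct += max(Counter(ys).values())
        return correct / n
    best = max(Counter(y).values())
    for t in sorted(set(f)):
        left = [yi for fi, yi in zip(f, y) if fi <= t]
        right = [yi for fi, yi in zip(f, y) if fi > t]
        score = sum(max(Counter(side).values()) for side in (left, right) if side)
        best = max(best, score)
    return best / n


def relief_oracle(data: pd.DataFrame, y: np.ndarray, k: int = 1) -> dict:
    """Exhaustive nearest-neighbor Relief with range-normalized diffs."""
    n = len(y)
    feats = data.columns.tolist()
    diff = {}
    for f in feats:
        col = data[f].to_numpy()
        if col.dtype.kind in "if":
            rng_ = col.max() - col.min()
            if rng_ == 0:
                diff[f] = np.zeros((n, n))
            else:
                s = (col - col.min()) / rng_
                diff[f] = np.abs(s[:, None] - s[None, :])
        else:
            diff[f] = (col[:, None] != col[None, :]).astype(float)
    dist = sum(diff.values())
    w = dict.fromkeys(feats, 0.0)
    for i in range(n):
        hits = sorted(
            (j for j in range(n) if j != i and y[j] == y[i]),
            key=lambda j: (dist[i, j], j),
        )[:k]
        misses = sorted(
            (j for j in range(n) if y[j] != y[i]), key=lambda j: (dist[i, j], j)
        )[:k]
        for f in feats:
            w[f] += sum(diff[f][i, j] for j in misses) / (n * k)
            w[f] -= sum(diff[f][i, j] for j in hits) / (n * k)
    return w


# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_median_split(self):
        codes, d = discretize_equal_frequency([1, 2, 3, 4], 2)
        assert list(codes) == [0, 0, 1, 1]
        assert d.n_bins_effective == 2

    def test_constant_vector_single_bin(self):
        with pytest.warns(UserWarning, match="constant"):
            codes, d = discretize_equal_frequency([7, 7, 7], 3)
        assert set(codes) == {0}
        assert d.n_bins_effective == 1

    def test_tie_merging(self):
        codes, d = discretize_equal_frequency([1, 1, 1, 1, 9, 9], 3)
        assert d.n_bins_effective == 2
        assert len(set(codes)) == 2

    def test_every_value_assigned_one_bin(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=40)
        codes, d = discretize_equal_frequency(values, 5)
        assert codes.shape == values.shape
        assert codes.min() >= 0 and codes.max() < d.n_bins_effective

    def test_deterministic(self):
        values = np.random.default_rng(1).normal(size=30)
        c1, _ = discretize_equal_frequency(values, 4)
        c2, _ = discretize_equal_frequency(values, 4)
        np.testing.assert_array_equal(c1, c2)


class TestEntropyFamily:
    Y = np.array(["+", "+", "-", "-"])
    F = np.array(["a", "a", "a", "b"])

    def test_perfect_predictor_ig_one_bit(self):
        assert weight_info_gain(self.Y.copy(), self.Y) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        assert weight_info_gain(np.array(["x"] * 4), self.Y) == pytest.approx(0.0)

    def test_ig_hand_example(self):
        # H(y)=1; H(y|f) = 3/4 H(2/3) -> IG ~ 0.3113
        assert weight_info_gain(self.F, self.Y) == pytest.approx(0.3113, abs=1e-4)

    def test_gain_ratio_perfect(self):
        assert weight_gain_ratio(self.Y.copy(), self.Y) == pytest.approx(1.0)

    def test_gain_ratio_constant_convention(self):
        assert weight_gain_ratio(np.array(["x"] * 4), self.Y) == 0.0

    def test_gain_ratio_hand_example(self):
        assert weight_gain_ratio(self.F, self.Y) == pytest.approx(0.3837, abs=1e-4)

    def test_su_perfect(self):
        assert weight_symmetric_uncertainty(self.Y.copy(), self.Y) == pytest.approx(1.0)

    def test_su_independent(self):
        f = np.array(["a", "b", "a", "b"])
        assert weight_symmetric_uncertainty(f, self.Y) == pytest.approx(0.0, abs=1e-12)

    def test_su_hand_example(self):
        assert weight_symmetric_uncertainty(self.F, self.Y) == pytest.approx(
            0.3437, abs=1e-4
        )

    def test_chi2_diagonal_table(self):
        f = np.array(["a"] * 5 + ["b"] * 5)
        y = np.array(["+"] * 5 + ["-"] * 5)
        assert weight_chi_squared(f, y) == pytest.approx(10.0)

    def test_chi2_independence_zero(self):
        f = np.array(["a", "a", "b", "b"])
        y = np.array(["+", "-", "+", "-"])
        assert weight_chi_squared(f, y) == pytest.approx(0.0, abs=1e-12)

    def test_chi2_42_table(self):
        f = np.array(["a"] * 5 + ["b"] * 5)
        y = np.array(["+"] * 4 + ["-"] + ["+"] + ["-"] * 4)
        assert weight_chi_squared(f, y) == pytest.approx(3.6)

    def test_gini_perfect(self):
        assert weight_gini(self.Y.copy(), self.Y) == pytest.approx(0.5)

    def test_gini_constant(self):
        assert weight_gini(np.array(["x"] * 4), self.Y) == pytest.approx(0.0)

    def test_gini_hand_example(self):
        assert weight_gini(self.F, self.Y) == pytest.approx(1 / 6, abs=1e-4)


# hypothesis strategy: small categorical tables (<= 8 samples, <= 3 levels)
small_tables = st.integers(4, 8).flatmap(
    lambda n: st.tuples(
        st.lists(st.sampled_from("abc"), min_size=n, max_size=n),
        st.lists(st.sampled_from("+-"), min_size=n, max_size=n).filter(
            lambda y: len(set(y)) == 2
        ),
    )
)


class TestBruteForceAgreement:
    @given(small_tables)
    @settings(max_examples=200, deadline=None)
    def test_info_gain_matches_oracle(self, table):
        f, y = np.array(table[0]), np.array(table[1])
        assert weight_info_gain(f, y) == pytest.approx(
            max(0.0, info_gain_oracle(list(f), list(y))), abs=1e-10
        )

    @given(small_tables)
    @settings(max_examples=200, deadline=None)
    def test_chi_squared_matches_oracle(self, table):
        f, y = np.array(table[0]), np.array(table[1])
        assert weight_chi_squared(f, y) == pytest.approx(
            chi_squared_oracle(list(f), list(y)), abs=1e-10
        )

    @given(small_tables)
    @settings(max_examples=200, deadline=None)
    def test_gini_matches_oracle(self, table):
        f, y = np.array(table[0]), np.array(table[1])
        assert weight_gini(f, y) == pytest.approx(
            max(0.0, gini_oracle(list(f), list(y))), abs=1e-10
        )

    @given(small_tables)
    @settings(max_examples=200, deadline=None)
    def test_gain_ratio_and_su_from_oracle_parts(self, table):
        f, y = np.array(table[0]), np.array(table[1])
        ig = info_gain_oracle(list(f), list(y))
        hf = entropy_oracle(list(f))
        hy = entropy_oracle(list(y))
        gr = ig / hf if hf > 0 else 0.0
        su = 2 * ig / (hf + hy) if hf + hy > 0 else 0.0
        assert weight_gain_ratio(f, y) == pytest.approx(gr, abs=1e-10)
        assert weight_symmetric_uncertainty(f, y) == pytest.approx(su, abs=1e-10)

    @given(
        st.integers(4, 8).flatmap(
            lambda n: st.tuples(
                st.lists(
                    st.integers(0, 20).map(float), min_size=n, max_size=n
                ),
                st.lists(st.sampled_from("+-"), min_size=n, max_size=n).filter(
                    lambda y: len(set(y)) == 2
                ),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_rule_matches_exhaustive_threshold_search(self, table):
        f, y = np.array(table[0]), np.array(table[1])
        assert weight_rule(f, y) == pytest.approx(
            rule_oracle(list(f), list(y)), abs=1e-12
        )


class TestRule:
    def test_perfect_predictor(self):
        f = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array(["+", "+", "-", "-"])
        assert weight_rule(f, y) == 1.0

    def test_constant_feature_majority(self):
        f = np.array([3.0, 3.0, 3.0, 3.0])
        y = np.array(["+", "+", "-", "-"])
        assert weight_rule(f, y) == 0.5

    def test_hand_threshold_example(self):
        f = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array(["+", "+", "-", "+"])
        assert weight_rule(f, y) == 0.75


def _mixed_table(data: dict, y) -> FeatureTable:
    df = pd.DataFrame(data)
    df.index = [f"s{i}" for i in range(len(df))]
    if "tissue" not in df:
        df["tissue"] = "t"
    return FeatureTable(df, pd.Series(list(y), index=df.index, name="treatment"))


class TestRelief:
    def test_perfect_separator(self):
        t = _mixed_table({"f": [0.0, 0.0, 1.0, 1.0]}, ["+", "+", "-", "-"])
        w = weight_relief(t, k=1)
        assert w["f"] == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        t = _mixed_table(
            {"f": [0.0, 1.0, 2.0, 3.0], "c": [5.0] * 4}, ["+", "+", "-", "-"]
        )
        assert weight_relief(t, k=1)["c"] == pytest.approx(0.0)

    def test_single_sample_class_errors(self):
        t = _mixed_table({"f": [0.0, 1.0, 2.0]}, ["+", "-", "-"])
        with pytest.raises(ValidationError, match="Relief"):
            weight_relief(t, k=1)

    def test_matches_exhaustive_oracle_six_samples(self):
        rng = np.random.default_rng(5)
        data = {
            "f1": rng.normal(size=6),
            "f2": rng.normal(size=6),
            "tissue": ["a", "b", "a", "b", "a", "b"],
        }
        y = ["+", "+", "+", "-", "-", "-"]
        t = _mixed_table(data, y)
        got = weight_relief(t, k=1)
        want = relief_oracle(t.data, np.array(y), k=1)
        for f in got:
            assert got[f] == pytest.approx(want[f], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        data = {
            "f1": rng.normal(size=n),
            "f2": rng.integers(0, 3, n).astype(float),
            "tissue": rng.choice(["a", "b"], n),
        }
        y = rng.permutation(["+"] * 4 + ["-"] * 4)
        t = _mixed_table(data, y)
        got = weight_relief(t, k=2)
        want = relief_oracle(t.data, np.asarray(y), k=2)
        for f in got:
            assert got[f] == pytest.approx(want[f], abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=8)
        y = ["+"] * 4 + ["-"] * 4
        w1 = weight_relief(_mixed_table({"f": f}, y), k=2)["f"]
        w2 = weight_relief(_mixed_table({"f": 100 * f - 7}, y), k=2)["f"]
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(13)
        t = _mixed_table(
            {"a": rng.normal(size=10), "b": rng.normal(size=10)},
            rng.permutation(["+"] * 5 + ["-"] * 5),
        )
        for w in weight_relief(t, k=3).values():
            assert -1.0 - 1e-12 <= w <= 1.0 + 1e-12


class TestNormalizeWeights:
    def test_affine(self):
        wv = normalize_weights(WeightVector("gini", {"a": 2.0, "b": 4.0, "c": 6.0}))
        assert wv.normalized == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="all raw weights equal"):
            wv = normalize_weights(WeightVector("gini", {"a": 3.3, "b": 3.3}))
        assert set(wv.normalized.values()) == {0.0}

    def test_negative_raw_scale(self):
        wv = normalize_weights(
            WeightVector("relief", {"a": -0.2, "b": 0.1, "c": 0.4})
        )
        assert wv.normalized["a"] == pytest.approx(0.0)
        assert wv.normalized["b"] == pytest.approx(0.5)
        assert wv.normalized["c"] == pytest.approx(1.0)


class TestComputeAllWeights:
    def test_all_algorithms_and_range(self):
        rng = np.random.default_rng(2)
        t = _mixed_table(
            {
                "g1": rng.normal(size=12),
                "g2": rng.normal(size=12),
                "tissue": rng.choice(["a", "b"], 12),
            },
            rng.permutation(["+"] * 6 + ["-"] * 6),
        )
        wvs = compute_all_weights(t, n_bins=3, relief_k=2, seed=0)
        assert sorted(wvs) == sorted(
            ["info_gain", "gain_ratio", "rule", "chi_squared", "gini", "uncertainty", "relief"]
        )
        for wv in wvs.values():
            vals = np.array(list(wv.normalized.values()))
            assert (vals >= 0).all() and (vals <= 1).all()

    def test_irrelevant_feature_does_not_change_others(self):
        rng = np.random.default_rng(4)
        base = {
            "g1": rng.normal(size=10),
            "g2": rng.normal(size=10),
        }
        y = rng.permutation(["+"] * 5 + ["-"] * 5)
        t1 = _mixed_table(dict(base), y)
        with_extra = dict(base)
        with_extra["junk"] = rng.permutation(base["g1"])
        t2 = _mixed_table(with_extra, y)
        for fn in (weight_info_gain, weight_chi_squared, weight_gini):
            for g in ("g1", "g2"):
                assert fn(t1.data[g].to_numpy(), np.asarray(y)) == pytest.approx(
                    fn(t2.data[g].to_numpy(), np.asarray(y)), abs=1e-12
                )
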
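"""The seven attribute-weighting algorithms over mixed feature tables.

Numeric features are discretized by equal-frequency binning before the
contingency-table weighters (Info Gain, Gain Ratio, Symmetric Uncertainty,
chi-squared, Gini); Relief works on the raw values with range-normalized
Manhattan distance; Rule scores the best single-feature majority rule.
Raw weights are min-max normalized to [0, 1] per algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable, ValidationError

ALGORITHMS = (
    "info_gain",
    "gain_ratio",
    "rule",
    "chi_squared",
    "gini",
    "uncertainty",
    "relief",
)

DEFAULT_BINS = 5
DEFAULT_RELIEF_K = 10


@dataclass
class Discretization:
    """Inner bin edges from equal-frequency quantiles (ties merged)."""

    edges: np.ndarray
    n_bins_requested: int

    @property
    def n_bins_effective(self) -> int:
        return len(self.edges) + 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges, values, side="right")


@dataclass
class WeightVector:
    algorithm: str
    raw: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)


def discretize_equal_frequency(
    values, n_bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, Discretization]:
    """Equal-frequency binning; adjacent identical quantile edges are merged.

    Returns integer bin codes and the Discretization. A constant vector maps
    to a single bin with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("discretization requires n >= 2")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if np.all(values == values[0]):
        warnings.warn("constant feature: single bin", stacklevel=2)
        d = Discretization(np.array([]), n_bins)
        return np.zeros(values.size, dtype=int), d
    qs = np.quantile(values, np.arange(1, n_bins) / n_bins)
    edges = np.unique(qs)
    # edges at (or beyond) the extremes would leave empty bins
    edges = edges[(edges > values.min()) & (edges < values.max())]
    d = Discretization(edges, n_bins)
    return d.assign(values), d


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _codes(f, y, n_bins: int) -> np.ndarray:
    """Categorical codes for a feature: discretize numerics, pass categoricals."""
    f = np.asarray(f)
    if f.dtype.kind in "if":
        codes, _ = discretize_equal_frequency(f.astype(float), n_bins)
        return codes
    _, codes = np.unique(f, return_inverse=True)
    return codes


def _check_label(y) -> np.ndarray:
    y = np.asarray(y)
    _, ycodes = np.unique(y, return_inverse=True)
    if len(np.unique(ycodes)) != 2:
        raise ValidationError("label must be binary")
    return ycodes


def _contingency(fcodes: np.ndarray, ycodes: np.ndarray) -> np.ndarray:
    nf = fcodes.max() + 1
    ny = ycodes.max() + 1
    table = np.zeros((nf, ny))
    np.add.at(table, (fcodes, ycodes), 1)
    return table


def weight_info_gain(f, y, n_bins: int = DEFAULT_BINS) -> float:
    """IG = H(y) - sum_v p(v) H(y | f=v), base-2 entropy."""
    ycodes = _check_label(y)
    fcodes = _codes(f, y, n_bins)
    h_y = _entropy(ycodes)
    cond = 0.0
    n = len(ycodes)
    for v in np.unique(fcodes):
        mask = fcodes == v
        cond += mask.sum() / n * _entropy(ycodes[mask])
    return max(0.0, h_y - cond)


def weight_gain_ratio(f, y, n_bins: int = DEFAULT_BINS) -> float:
    """IG / H(f); 0 by convention when H(f) = 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ig = weight_info_gain(f, y, n_bins)
        h_f = _entropy(_codes(f, y, n_bins))
    if h_f == 0.0:
        return 0.0
    return ig / h_f


def weight_symmetric_uncertainty(f, y, n_bins: int = DEFAULT_BINS) -> float:
    """SU = 2 IG / (H(f) + H(y)), in [0, 1]."""
    ycodes = _check_label(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ig = weight_info_gain(f, y, n_bins)
        h_f = _entropy(_codes(f, y, n_bins))
    h_y = _entropy(ycodes)
    denom = h_f + h_y
    if denom == 0.0:
        return 0.0
    return 2.0 * ig / denom


def weight_chi_squared(f, y, n_bins: int = DEFAULT_BINS) -> float:
    """Pearson chi-squared on the bin x label table, no continuity correction."""
    ycodes = _check_label(y)
    fcodes = _codes(f, y, n_bins)
    table = _contingency(fcodes, ycodes)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float(((table - expected)[mask] ** 2 / expected[mask]).sum())


def _gini_impurity(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def weight_gini(f, y, n_bins: int = DEFAULT_BINS) -> float:
    """Gini impurity decrease: gini(y) - sum_v p(v) gini(y | f=v)."""
    ycodes = _check_label(y)
    fcodes = _codes(f, y, n_bins)
    n = len(ycodes)
    cond = 0.0
    for v in np.unique(fcodes):
        mask = fcodes == v
        cond += mask.sum() / n * _gini_impurity(ycodes[mask])
    return max(0.0, _gini_impurity(ycodes) - cond)


def weight_rule(f, y) -> float:
    """Training accuracy of the best single-feature majority rule.

    Categorical: majority label per level. Numeric: best threshold split with
    majority labels on each side (ties resolved toward the lower threshold by
    taking the first maximum).
    """
    ycodes = _check_label(y)
    f = np.asarray(f)
    n = len(ycodes)
    if f.dtype.kind not in "if":
        correct = 0
        for v in np.unique(f):
            mask = f == v
            counts = np.bincount(ycodes[mask], minlength=2)
            correct += counts.max()
        return correct / n
    order = np.argsort(f, kind="mergesort")
    fs, ys = f[order], ycodes[order]
    # cumulative class-1 counts: left side of a split at position i = first i samples
    cum1 = np.cumsum(ys)
    total1 = cum1[-1]
    best = max(total1, n - total1)  # degenerate rule: predict the majority class
    uniq = np.unique(fs)
    for t in range(len(uniq) - 1):
        i = int(np.searchsorted(fs, uniq[t], side="right"))  # left group size
        left1 = cum1[i - 1]
        right1 = total1 - left1
        correct = max(left1, i - left1) + max(right1, (n - i) - right1)
        if correct > best:
            best = correct
    return best / n


def weight_relief(
    table: FeatureTable, k: int = DEFAULT_RELIEF_K, seed: int | None = None
) -> dict[str, float]:
    """Relief weights for every feature of a mixed table.

    Full deterministic pass (m = n): for each sample, the k nearest hits and
    k nearest misses under Manhattan distance (numeric diffs range-normalized
    to [0, 1], categorical diff in {0, 1});
    w(f) = sum(miss diffs)/(n k) - sum(hit diffs)/(n k). k is capped at
    min(class size) - 1. The seed only randomizes distance-tie resolution;
    by default ties break on sample order.
    """
    y = _check_label(table.labels)
    n = len(y)
    class_sizes = np.bincount(y)
    if class_sizes.min() < 2:
        raise ValidationError("Relief requires >=2 samples per class")
    k = max(1, min(k, int(class_sizes.min()) - 1))

    features = table.feature_names
    diffs = np.zeros((len(features), n, n))
    for fi, name in enumerate(features):
        col = table.data[name].to_numpy()
        if col.dtype.kind in "if":
            col = col.astype(float)
            rng_ = col.max() - col.min()
            if rng_ == 0:
                continue
            scaled = (col - col.min()) / rng_
            diffs[fi] = np.abs(scaled[:, None] - scaled[None, :])
        else:
            diffs[fi] = (col[:, None] != col[None, :]).astype(float)
    dist = diffs.sum(axis=0)

    if seed is not None:
        tie_rank = np.random.default_rng(seed).permutation(n)
    else:
        tie_rank = np.arange(n)

    w = np.zeros(len(features))
    for i in range(n):
        for target, sign in ((y == y[i], -1.0), (y != y[i], +1.0)):
            cand = np.flatnonzero(target)
            cand = cand[cand != i]
            order = np.lexsort((tie_rank[cand], dist[i, cand]))
            chosen = cand[order[:k]]
            w += sign * diffs[:, i, chosen].sum(axis=1)
    w /= n * k
    return dict(zip(features, w))


def normalize_weights(wv: WeightVector) -> WeightVector:
    """Min-max normalize raw weights to [0, 1]; all-equal raws map to 0."""
    raws = np.array(list(wv.raw.values()), dtype=float)
    lo, hi = raws.min(), raws.max()
    if hi == lo:
        warnings.warn(
            f"{wv.algorithm}: all raw weights equal ({lo}); normalized to 0",
            stacklevel=2,
        )
        norm = np.zeros_like(raws)
    else:
        norm = (raws - lo) / (hi - lo)
    wv.normalized = dict(zip(wv.raw.keys(), norm))
    return wv


def compute_all_weights(
    table: FeatureTable,
    n_bins: int = DEFAULT_BINS,
    relief_k: int = DEFAULT_RELIEF_K,
    seed: int | None = None,
) -> dict[str, WeightVector]:
    """Run all seven weighters over a feature table and normalize each."""
    y = table.labels.to_numpy()
    per_feature = {
        "info_gain": weight_info_gain,
        "gain_ratio": weight_gain_ratio,
        "uncertainty": weight_symmetric_uncertainty,
        "chi_squared": weight_chi_squared,
        "gini": weight_gini,
    }
    out: dict[str, WeightVector] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for algo, fn in per_feature.items():
            raw = {
                name: fn(table.data[name].to_numpy(), y, n_bins)
                for name in table.feature_names
            }
            out[algo] = normalize_weights(WeightVector(algo, raw))
        raw_rule = {
            name: weight_rule(table.data[name].to_numpy(), y)
            for name in table.feature_names
        }
        out["rule"] = normalize_weights(WeightVector("rule", raw_rule))
        out["relief"] = normalize_weights(
            WeightVector("relief", weight_relief(table, relief_k, seed))
        )
    return {a: out[a] for a in ALGORITHMS}


def weights_frame(wvs: dict[str, WeightVector]) -> pd.DataFrame:
    """Feature x algorithm matrix of normalized weights."""
    return pd.DataFrame({a: pd.Series(wv.normalized) for a, wv in wvs.items()})[
        list(ALGORITHMS)
    ]
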
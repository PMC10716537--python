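"""Bayesian two-group effect model and posterior effect-existence summaries.

Model: y = mu + delta * I(group == CR) + eps, eps ~ Normal(0, sigma^2), with
Normal(0, (10 sd(y))^2) priors on mu and delta and a half-Cauchy(sd(y)) prior
on sigma, sampled by Metropolis-within-Gibbs (4 chains, first half warm-up).

Summaries: posterior median, 95% highest-density interval, probability of
direction (percent), and the proportion of the posterior inside a region of
practical equivalence (ROPE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ValidationError

RHAT_WARN = 1.05


@dataclass
class PosteriorDraws:
    parameter: str
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float).ravel()
        if self.draws.size < 2:
            raise ValidationError("need at least 2 posterior draws")
        if not np.all(np.isfinite(self.draws)):
            raise ValidationError("posterior draws must be finite")


@dataclass
class PosteriorSummary:
    e_m: float
    hdi_low: float
    hdi_high: float
    d_p: float  # percent, in [50, 100]
    rope_p: float
    rope_low: float
    rope_high: float

    def format(self) -> str:
        rope = "< 0.01" if self.rope_p < 0.01 else f"= {self.rope_p:.2f}"
        return (
            f"E_M = {self.e_m:.2f} ({self.hdi_low:.2f}, {self.hdi_high:.2f}), "
            f"D_p = {self.d_p:.0f}%, ROPE_p {rope}"
        )


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an (n_chains, n_draws) array."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    var_w = halves.var(axis=1, ddof=1).mean()
    var_b = n * halves.mean(axis=1).var(ddof=1)
    if var_w == 0:
        return 1.0
    var_hat = (n - 1) / n * var_w + var_b / n
    return float(np.sqrt(var_hat / var_w))


def fit_group_model(
    y,
    group,
    n_draws: int = 4000,
    seed: int | None = None,
    n_chains: int = 4,
) -> PosteriorDraws:
    """Posterior draws of the CR-vs-control shift delta.

    ``group`` holds 'control' / 'CR' per subject. Runs ``n_chains`` chains
    long enough that the pooled post-warm-up draws number ``n_draws``.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if not np.all(np.isfinite(y)):
        raise ValidationError("outcome contains non-finite values")
    is_cr = group == "CR"
    if is_cr.sum() < 2 or (~is_cr).sum() < 2:
        raise ValidationError("need >= 2 subjects per group")
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise ValidationError("zero-variance outcome")

    x = is_cr.astype(float)
    n = y.size
    tau2 = (10.0 * sd_y) ** 2  # prior variance of mu and delta
    cauchy_scale = sd_y
    per_chain = math.ceil(n_draws / n_chains)
    n_iter = 2 * per_chain  # first half discarded as warm-up
    rng = np.random.default_rng(seed)

    sum_x = x.sum()
    kept = np.empty((n_chains, per_chain))
    for c in range(n_chains):
        mu = y.mean() + rng.normal(0, sd_y)
        delta = rng.normal(0, sd_y)
        log_sigma = math.log(sd_y)
        for it in range(n_iter):
            sigma2 = math.exp(2 * log_sigma)
            # mu | delta, sigma  (conjugate normal)
            prec = n / sigma2 + 1 / tau2
            mean = ((y - delta * x).sum() / sigma2) / prec
            mu = rng.normal(mean, math.sqrt(1 / prec))
            # delta | mu, sigma
            prec = sum_x / sigma2 + 1 / tau2
            mean = (((y - mu) * x).sum() / sigma2) / prec
            delta = rng.normal(mean, math.sqrt(1 / prec))
            # sigma: Metropolis on log sigma, half-Cauchy prior
            resid2 = ((y - mu - delta * x) ** 2).sum()

            def logpost(ls: float) -> float:
                s2 = math.exp(2 * ls)
                # includes the log-scale Jacobian (+ls)
                return (
                    -n * ls
                    - resid2 / (2 * s2)
                    - math.log1p(s2 / cauchy_scale**2)
                    + ls
                )

            prop = log_sigma + rng.normal(0, 0.3)
            if math.log(rng.uniform()) < logpost(prop) - logpost(log_sigma):
                log_sigma = prop
            if it >= n_iter - per_chain:
                kept[c, it - (n_iter - per_chain)] = delta
    rhat = _split_rhat(kept)
    if rhat > RHAT_WARN:
        warnings.warn(f"split-Rhat {rhat:.3f} > {RHAT_WARN} for delta", stacklevel=2)
    return PosteriorDraws("delta", kept.ravel()[:n_draws])


def hdi(draws: PosteriorDraws | np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(mass * S) sorted draws."""
    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if not 0 < mass <= 1:
        raise ValidationError("mass must be in (0, 1]")
    s = np.sort(arr)
    n_inc = math.ceil(mass * s.size)
    if n_inc >= s.size:
        return float(s[0]), float(s[-1])
    widths = s[n_inc - 1 :] - s[: s.size - n_inc + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + n_inc - 1])


def probability_of_direction(draws: PosteriorDraws | np.ndarray) -> float:
    """max(P(delta > 0), P(delta < 0)) as a percentage; zeros count to neither."""
    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    pos = (arr > 0).mean()
    neg = (arr < 0).mean()
    return 100.0 * max(pos, neg)


def rope_proportion(
    draws: PosteriorDraws | np.ndarray, rope_low: float, rope_high: float
) -> float:
    """Fraction of all draws inside the closed interval [rope_low, rope_high]."""
    if not rope_low < rope_high:
        raise ValidationError("rope_low must be < rope_high")
    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    return float(((arr >= rope_low) & (arr <= rope_high)).mean())


def summarize(
    draws: PosteriorDraws | np.ndarray,
    rope: tuple[float, float] | None = None,
    mass: float = 0.95,
) -> PosteriorSummary:
    """Full effect-existence summary of a draw vector.

    When ``rope`` is None the bounds default to +/- 0.1 * sd(draws) -- callers
    fitting a group model should pass +/- 0.1 * sd(y) explicitly.
    """
    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if rope is None:
        half = 0.1 * arr.std(ddof=1)
        if half == 0:
            half = 0.1
        rope = (-half, half)
    lo, hi = hdi(arr, mass)
    return PosteriorSummary(
        e_m=float(np.median(arr)),
        hdi_low=lo,
        hdi_high=hi,
        d_p=probability_of_direction(arr),
        rope_p=rope_proportion(arr, rope[0], rope[1]),
        rope_low=rope[0],
        rope_high=rope[1],
    )
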
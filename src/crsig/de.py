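"""Two-group negative-binomial differential expression.

Per tissue: median-of-ratios size factors, gene-wise method-of-moments
dispersion, an NB log-linear model mean = sf * exp(b0 + b1*I(CR)) fitted by
Newton iterations at fixed dispersion, a Wald z-test on b1, and
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SampleTable, ValidationError

DISPERSION_FLOOR = 1e-8


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over genes with all-positive
    counts; each sample's factor is the median ratio of its counts to that
    reference. If no gene is positive in every sample, falls back to
    total-count (library size) factors with a warning.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] == 1:
        return np.array([1.0])
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        warnings.warn(
            "no gene with positive counts in every sample; "
            "falling back to library-size factors",
            stacklevel=2,
        )
        factors = counts.sum(axis=0)
        if np.any(factors <= 0):
            raise ValidationError("sample with zero total count")
    else:
        logc = np.log(counts[all_positive])
        log_ref = logc.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logc - log_ref, axis=0))
    # enforce geometric mean 1 so factors are comparable across runs
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def estimate_dispersion(
    cm: CountMatrix, factors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-wise method-of-moments NB dispersion on normalized counts.

    alpha = max(floor, (s^2 - mean) / mean^2) with s^2 the sample variance
    (ddof=1). Returns ``(alpha, untestable)`` where untestable flags all-zero
    genes (alpha fixed at 0).
    """
    if cm.n_samples < 2:
        raise ValidationError("dispersion estimation requires >= 2 samples")
    norm = cm.counts / np.asarray(factors, dtype=float)
    mu = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    untestable = mu == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(untestable, 0.0, np.maximum(alpha, DISPERSION_FLOOR))
    return alpha, untestable


def _nb_fit(
    y: np.ndarray, design: np.ndarray, sf: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton fit of an NB log-linear model at fixed dispersion.

    Returns (beta, cov, converged); cov is the inverse observed Fisher
    information.
    """
    log_sf = np.log(sf)

    def loglik(b: np.ndarray) -> float:
        eta = np.clip(design @ b + log_sf, -500, 500)
        mu = np.exp(eta)
        return float((y * eta - (y + 1.0 / alpha) * np.log1p(alpha * mu)).sum())

    base = np.log(max(np.mean(y / sf), 1e-8))
    beta = np.zeros(design.shape[1])
    beta[0] = base
    ll = loglik(beta)
    converged = False
    for _ in range(100):
        eta = design @ beta + log_sf
        mu = np.exp(np.clip(eta, -500, 500))
        score = design.T @ ((y - mu) / (1.0 + alpha * mu))
        w = mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving line search keeps the Newton update ascending
        new_ll = None
        for _half in range(30):
            cand = beta + step
            cand_ll = loglik(cand)
            if cand_ll >= ll - 1e-12:
                new_ll = cand_ll
                beta = cand
                break
            step = step / 2.0
        if new_ll is None:
            break
        if np.max(np.abs(step)) < 1e-10 or new_ll - ll < 1e-12:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    eta = design @ beta + log_sf
    mu = np.exp(np.clip(eta, -500, 500))
    w = mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2
    info = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((design.shape[1],) * 2, np.nan)
        converged = False
    return beta, cov, converged


def nb_wald_test(
    cm: CountMatrix,
    st: SampleTable,
    tissue: str | None = None,
    alpha_override: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of CR vs control, optionally within one tissue.

    Returns a data frame with columns gene_id, baseMean, log2FC, se, wald_p,
    fdr_q, dispersion, flags. Genes with all-zero counts get NA statistics and
    are excluded from the FDR denominator; genes with an all-zero treatment
    group are refitted with a 0.5 pseudo-count and flagged ``pseudo``.
    """
    meta = st.data
    if tissue is not None:
        keep = meta.index[meta["tissue"] == tissue].tolist()
        if not keep:
            raise ValidationError(f"no samples for tissue {tissue!r}")
        cm = cm.subset_samples([s for s in cm.sample_ids if s in set(keep)])
        meta = meta.loc[cm.sample_ids]
    else:
        meta = meta.loc[cm.sample_ids]
    is_cr = (meta["treatment"] == "CR").to_numpy()
    if is_cr.sum() < 2 or (~is_cr).sum() < 2:
        raise ValidationError("need >= 2 samples per treatment level")
    sf = size_factors(cm)
    if alpha_override is not None:
        alpha = np.asarray(alpha_override, dtype=float)
        untestable = cm.counts.sum(axis=1) == 0
    else:
        alpha, untestable = estimate_dispersion(cm, sf)
    design = np.column_stack([np.ones(cm.n_samples), is_cr.astype(float)])
    norm = cm.counts / sf

    rows = []
    ln2 = np.log(2.0)
    for i, gene in enumerate(cm.gene_ids):
        y = cm.counts[i].astype(float)
        base_mean = norm[i].mean()
        if untestable[i]:
            rows.append((gene, base_mean, np.nan, np.nan, np.nan, alpha[i], "untestable"))
            continue
        flags = []
        y_fit = y
        if y[is_cr].sum() == 0 or y[~is_cr].sum() == 0:
            y_fit = y + 0.5  # pseudo-count refit when one group is all zero
            flags.append("pseudo")
        beta, cov, ok = _nb_fit(y_fit, design, sf, float(alpha[i]))
        if not ok or not np.isfinite(cov[1, 1]) or cov[1, 1] <= 0:
            flags.append("nonconverged")
            rows.append((gene, base_mean, np.nan, np.nan, np.nan, alpha[i], ";".join(flags)))
            continue
        se_b1 = float(np.sqrt(cov[1, 1]))
        z = beta[1] / se_b1
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            (gene, base_mean, beta[1] / ln2, se_b1 / ln2, p, alpha[i], ";".join(flags))
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "baseMean", "log2FC", "se", "wald_p", "dispersion", "flags"],
    )
    out["fdr_q"] = bh_adjust(out["wald_p"].to_numpy())
    return out[
        ["gene_id", "baseMean", "log2FC", "se", "wald_p", "fdr_q", "dispersion", "flags"]
    ]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, NA-aware.

    NA entries are excluded from the number of tests m and stay NA.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q
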
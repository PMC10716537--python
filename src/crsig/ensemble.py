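"""Ensemble aggregation of the seven weight vectors and signature evaluation.

The overall weight of a feature is the plain sum of its seven normalized
per-algorithm weights (range [0, 7]); features are ranked by descending
overall weight with lexicographic tie-breaking, the top-k genes form the
signature, and the signature is evaluated by correlation-matrix PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationTable, FeatureTable, ValidationError
from .weighting import ALGORITHMS, WeightVector

DEFAULT_SIGNATURE_SIZE = 20


@dataclass
class EnsembleRanking:
    """Feature x algorithm normalized weights + overall weight W and rank."""

    table: pd.DataFrame  # index: feature; columns: ALGORITHMS + overall_weight + rank

    @property
    def features(self) -> list[str]:
        return self.table.index.tolist()

    def overall_weight(self, feature: str) -> float:
        return float(self.table.loc[feature, "overall_weight"])

    def rank(self, feature: str) -> int:
        return int(self.table.loc[feature, "rank"])


@dataclass
class Signature:
    """Ordered top-k gene features with metadata."""

    table: pd.DataFrame  # columns: rank, overall_weight, per-algorithm, protein_class

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # genes x components
    variance_fractions: np.ndarray
    scores: pd.DataFrame  # samples x components


def ensemble_overall_weights(
    wvs: dict[str, WeightVector] | list[WeightVector],
) -> EnsembleRanking:
    """Sum the normalized weights of the seven algorithms into overall weights.

    Requires all seven algorithms over an identical feature set. Features are
    sorted by descending overall weight, ties broken lexicographically.
    """
    if not isinstance(wvs, dict):
        wvs = {wv.algorithm: wv for wv in wvs}
    missing = [a for a in ALGORITHMS if a not in wvs]
    if missing:
        raise ValidationError(f"missing weight vectors for algorithm(s): {missing}")
    feature_sets = {a: frozenset(wvs[a].normalized) for a in ALGORITHMS}
    ref = feature_sets[ALGORITHMS[0]]
    for a, fs in feature_sets.items():
        if fs != ref:
            raise ValidationError(
                f"algorithm {a!r} has a different feature set than {ALGORITHMS[0]!r}"
            )
    df = pd.DataFrame({a: pd.Series(wvs[a].normalized) for a in ALGORITHMS})
    df["overall_weight"] = df[list(ALGORITHMS)].sum(axis=1)
    # descending W, lexicographic tie-break on feature id
    order = sorted(df.index, key=lambda f: (-df.at[f, "overall_weight"], f))
    df = df.loc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return EnsembleRanking(df)


def rank_and_select(
    er: EnsembleRanking,
    k: int = DEFAULT_SIGNATURE_SIZE,
    annotations: AnnotationTable | None = None,
    tissue_feature: str = "tissue",
) -> Signature:
    """Top-k gene features by overall weight (tissue feature excluded)."""
    genes = [f for f in er.features if f != tissue_feature]
    if k > len(genes):
        warnings.warn(
            f"requested k={k} exceeds {len(genes)} gene features; taking all",
            stacklevel=2,
        )
        k = len(genes)
    top = genes[:k]
    table = er.table.loc[top].copy()
    if annotations is not None:
        table["protein_class"] = [annotations.protein_class(g) for g in top]
    return Signature(table)


def tissue_independence_report(
    er: EnsembleRanking, tissue_feature: str = "tissue"
) -> dict:
    """Overall weight, rank and rank-quantile of the tissue feature."""
    if tissue_feature not in er.table.index:
        raise ValidationError(f"feature {tissue_feature!r} absent from ranking")
    n = len(er.table)
    rank = er.rank(tissue_feature)
    return {
        "feature": tissue_feature,
        "overall_weight": er.overall_weight(tissue_feature),
        "rank": rank,
        "n_features": n,
        "quantile": rank / n,
    }


def pca_correlation(table: FeatureTable | pd.DataFrame) -> PCAResult:
    """PCA via eigendecomposition of the gene-gene correlation matrix.

    Input is a samples x genes numeric table (a FeatureTable's gene columns
    are used; the tissue column is ignored). Zero-variance genes are dropped
    with a warning. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if isinstance(table, FeatureTable):
        df = table.data[table.gene_features]
    else:
        df = table.select_dtypes(include=[np.number])
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValidationError("PCA requires >= 2 samples and >= 2 genes")
    sd = df.std(axis=0, ddof=1)
    keep = sd[sd > 0].index.tolist()
    if len(keep) == 0:
        raise ValidationError("all genes have zero variance")
    if len(keep) < df.shape[1]:
        dropped = sorted(set(df.columns) - set(keep))
        warnings.warn(f"dropping zero-variance gene(s): {dropped}", stacklevel=2)
        df = df[keep]
    x = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
    corr = np.corrcoef(x.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] *= -1
    fractions = eigval / eigval.sum()
    comp_names = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=comp_names)
    scores = pd.DataFrame(
        x.to_numpy() @ eigvec, index=df.index, columns=comp_names
    )
    return PCAResult(loadings, fractions, scores)


def separation_on_pc1(pca: PCAResult, labels: pd.Series) -> dict:
    """Standardized group separation of PC1 scores + midpoint split accuracy."""
    pc1 = pca.scores["PC1"]
    labels = labels.loc[pc1.index]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValidationError("separation requires a binary label")
    a = pc1[labels == levels[0]].to_numpy()
    b = pc1[labels == levels[1]].to_numpy()
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    ) if na + nb > 2 else 0.0
    diff = abs(a.mean() - b.mean())
    score = diff / pooled if pooled > 0 else (0.0 if diff == 0 else np.inf)
    if a.mean() == b.mean():
        fraction = 0.5
    else:
        midpoint = (a.mean() + b.mean()) / 2.0
        a_side = a.mean() < midpoint  # True: group a below the threshold
        correct = (a < midpoint).sum() if a_side else (a > midpoint).sum()
        correct += (b > midpoint).sum() if a_side else (b < midpoint).sum()
        fraction = correct / (na + nb)
    return {"score": float(score), "fraction_correct": float(fraction)}
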
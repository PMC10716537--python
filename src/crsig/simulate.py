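"""Seeded synthetic-data generators for every pipeline stage.

Counts are negative-binomial (mean/dispersion parameterization,
Var = mu + alpha mu^2) with per-sample library-size factors, per-gene
per-tissue effects, and a spiked set of treatment-responsive genes with
symmetric up/down log2 fold changes. Also provides toy posterior-draw
vectors and relation corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable, ValidationError

DEFAULT_TISSUES = ("hypothalamus", "amygdala", "pituitary", "prefrontal_cortex")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_per_group: int = 5  # per tissue per treatment
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion_log_mean: float = float(np.log(0.05))
    dispersion_log_sd: float = 0.5
    n_spike: int = 10
    spike_log2fc: float = 2.0
    tissue_effect_sd: float = 0.3
    library_factor_range: tuple[float, float] = (0.7, 1.4)
    duration: str = "short"

    def __post_init__(self) -> None:
        if self.n_spike > self.n_genes:
            raise ValidationError("spike set larger than gene count")
        if self.n_per_group < 1 or self.n_genes < 1:
            raise ValidationError("n_per_group and n_genes must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) via Gamma-Poisson; alpha -> 0 degenerates to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        shape = 1.0 / alpha[~tiny]
        lam = rng.gamma(shape, mean[~tiny] / shape)
        out[~tiny] = rng.poisson(lam)
    return out


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, pd.DataFrame]:
    """Generate counts, sample metadata, and the spike truth table.

    Per gene g and sample j:
    count ~ NB(mean = L_j * 2^(b_g + t_{tissue(j), g} + delta_g * I(CR_j)),
    dispersion alpha_g). The first ``n_spike`` randomly chosen genes carry
    delta = +/- spike_log2fc, alternating sign. Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]

    samples = []
    for tissue in cfg.tissues:
        for treatment in ("control", "CR"):
            for r in range(cfg.n_per_group):
                samples.append(
                    {
                        "sample_id": f"{tissue}_{treatment}_{r + 1}",
                        "treatment": treatment,
                        "tissue": tissue,
                        "duration": cfg.duration,
                    }
                )
    meta = pd.DataFrame(samples).set_index("sample_id")
    n_samples = len(meta)

    b = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    alpha = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, cfg.n_genes))
    tissue_fx = {
        t: rng.normal(0.0, cfg.tissue_effect_sd, cfg.n_genes) for t in cfg.tissues
    }
    spiked = rng.choice(cfg.n_genes, size=cfg.n_spike, replace=False)
    delta = np.zeros(cfg.n_genes)
    for i, g in enumerate(spiked):
        delta[g] = cfg.spike_log2fc if i % 2 == 0 else -cfg.spike_log2fc
    lib = rng.uniform(*cfg.library_factor_range, n_samples)

    counts = np.empty((cfg.n_genes, n_samples), dtype=np.int64)
    is_cr = (meta["treatment"] == "CR").to_numpy()
    for j, sample_id in enumerate(meta.index):
        t = meta.loc[sample_id, "tissue"]
        log2_mu = b + tissue_fx[t] + delta * is_cr[j]
        mu = lib[j] * np.exp2(log2_mu)
        counts[:, j] = _nb_draw(rng, mu, alpha)

    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[g] for g in sorted(spiked)],
            "log2fc": [delta[g] for g in sorted(spiked)],
        }
    )
    cm = CountMatrix(gene_ids, meta.index.tolist(), counts)
    return cm, SampleTable(meta), truth


def simulate_posterior(
    mean: float, sd: float, n_draws: int = 4000, seed: int | None = None
) -> np.ndarray:
    """Normal(mean, sd) posterior-draw stand-in; sd = 0 gives constant draws."""
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n_draws, float(mean))
    return rng.normal(mean, sd, n_draws)


def simulate_relations(
    n_genes: int = 10,
    n_drugs: int = 4,
    n_concepts: int = 6,
    sentence_rate: float = 2.0,
    seed: int | None = None,
    edge_probability: float = 0.35,
) -> pd.DataFrame:
    """Toy relation corpus as rows ready to write to TSV.

    The first gene is a designated hub and receives an edge to every concept.
    Other gene-concept and drug-gene pairs get an edge with probability
    ``edge_probability``. Per-edge sentence counts are 1 + Poisson(rate).
    """
    if sentence_rate < 0:
        raise ValidationError("sentence_rate must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i}" for i in range(n_genes)]
    drugs = [f"DRUG{i}" for i in range(n_drugs)]
    concepts = [f"CONCEPT{i}" for i in range(n_concepts)]
    rows = []

    def add_edge(a: str, at: str, b: str, bt: str) -> None:
        rel = RELATION_CHOICES[rng.integers(len(RELATION_CHOICES))]
        sign = SIGN_CHOICES[rng.integers(len(SIGN_CHOICES))]
        s = 1 + rng.poisson(sentence_rate)
        for i in range(s):
            rows.append(
                {
                    "subject": a,
                    "subject_type": at,
                    "object": b,
                    "object_type": bt,
                    "relation_type": rel,
                    "sign": sign,
                    "sentence": f"{a} {rel} {b} (evidence {i + 1}).",
                }
            )

    for concept in concepts:
        add_edge(genes[0], "gene", concept, "concept")
    for gene in genes[1:]:
        for concept in concepts:
            if rng.uniform() < edge_probability:
                add_edge(gene, "gene", concept, "concept")
    for drug in drugs:
        for gene in genes:
            if rng.uniform() < edge_probability:
                add_edge(drug, "drug", gene, "gene")
    return pd.DataFrame(rows, columns=list(RELATION_ROW_COLUMNS))


RELATION_CHOICES = (
    "regulation",
    "expression",
    "molecular_transport",
    "genetic_change",
    "association",
)
SIGN_CHOICES = ("positive", "negative", "unsigned")
RELATION_ROW_COLUMNS = (
    "subject",
    "subject_type",
    "object",
    "object_type",
    "relation_type",
    "sign",
    "sentence",
)
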
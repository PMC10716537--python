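# crsig

Ensemble attribute-weighting pipeline for discovering tissue-independent
transcriptomic signatures of a two-group treatment (calorie restriction vs
control), together with the supporting analysis stages:

- **I/O & feature assembly** (`crsig.io`) — TSV count matrix / sample table /
  annotation readers; samples × (gene features + categorical tissue) tables
  with a binary treatment label (default expression unit: log2 CPM).
- **Differential expression** (`crsig.de`) — median-of-ratios size factors,
  method-of-moments NB dispersion, per-gene negative-binomial Wald tests,
  Benjamini–Hochberg FDR.
- **Attribute weighting** (`crsig.weighting`) — Info Gain, Info Gain Ratio,
  Rule, chi-squared, Gini Index, Symmetric Uncertainty, and Relief over mixed
  numeric/categorical features, with equal-frequency discretization and
  per-algorithm min-max normalization.
- **Ensemble signature** (`crsig.ensemble`) — overall weight = sum of the
  seven normalized weights, ranking, top-k signature, tissue-independence
  report, correlation-matrix PCA, and PC1 group-separation scoring.
- **Posterior statistics** (`crsig.posterior`) — Bayesian two-group shift
  model (Metropolis-within-Gibbs, 4 chains) and the effect-existence
  summaries: posterior median, 95% HDI, probability of direction, ROPE
  proportion.
- **Relation networks** (`crsig.relations`) — confidence-weighted networks
  from mined relation records (distinct-sentence counts → high/medium/low),
  hub detection, drug ranking by signature coverage, and greedy set-cover
  drug-combination selection.
- **Synthetic data** (`crsig.simulate`) — seeded NB count simulation with
  tissue effects, library-size variation and spiked treatment-responsive
  genes; toy posterior draws and relation corpora.

## CLI

Every stage is a subcommand of `crsig`; `crsig run` chains them end to end
on simulated or ingested data and writes a manifest:

```sh
crsig simulate --preset short_cr --seed 1 --out sim/
crsig de     --counts sim/counts.tsv --samples sim/samples.tsv --tissue hypothalamus --out de.tsv
crsig weigh  --counts sim/counts.tsv --samples sim/samples.tsv --bins 5 --relief-k 10 --out weights.tsv
crsig rank   --weights weights.tsv --k 20 --out signature.tsv
crsig pca    --counts sim/counts.tsv --samples sim/samples.tsv --signature signature.tsv --out pca/
crsig posterior --data behavior.tsv            # subject, group, outcome
crsig network   --relations relations.tsv --out net/
crsig repurpose --relations relations.tsv --signature signature.tsv --max-drugs 4 --out drugs/
crsig run --config run.yaml --out run_out/     # full pipeline + manifest.json
```

`run.yaml` may set: `seed, preset, counts, samples, annotations, relations,
transform, bins, relief_k, k_signature, prefilter_fdr, max_drugs` (unknown
keys are rejected).

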
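"""Core data types and TSV readers/writers.

Canonical on-disk formats are TSV: a genes x samples count matrix with the
gene identifier in the first column and sample identifiers in the header, a
sample table with columns ``sample_id, treatment, tissue, duration``, and an
optional annotation table with columns ``gene_id, symbol, protein_class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENT_LEVELS = ("control", "CR")
DURATION_LEVELS = ("short", "long")
PROTEIN_CLASSES = (
    "TF",
    "kinase",
    "phosphatase",
    "receptor",
    "transporter",
    "secretory",
    "chromatin_associated",
    "RNA_transcript",
    "other",
)

SAMPLE_TABLE_COLUMNS = ("sample_id", "treatment", "tissue", "duration")


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            g, s = neg[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"gene ids not in count matrix: {missing}")
        rows = [index[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"sample ids not in count matrix: {missing}")
        cols = [index[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample metadata: treatment, tissue, duration."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicated sample_id: {dupes}")
        for col in ("treatment", "tissue", "duration"):
            if col not in df.columns:
                raise ValidationError(
                    "sample table requires columns "
                    f"{list(SAMPLE_TABLE_COLUMNS)}; missing {col!r}"
                )
        bad_treat = sorted(set(df["treatment"]) - set(TREATMENT_LEVELS))
        if bad_treat:
            raise ValidationError(
                f"unknown treatment level(s) {bad_treat}; "
                f"expected one of {list(TREATMENT_LEVELS)}"
            )
        bad_dur = sorted(set(df["duration"]) - set(DURATION_LEVELS))
        if bad_dur:
            raise ValidationError(
                f"unknown duration level(s) {bad_dur}; "
                f"expected one of {list(DURATION_LEVELS)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def treatment(self) -> pd.Series:
        return self.data["treatment"]

    @property
    def tissue(self) -> pd.Series:
        return self.data["tissue"]

    def tissues(self) -> list[str]:
        return sorted(self.data["tissue"].unique())


@dataclass
class FeatureTable:
    """Samples x features table: numeric gene features + one categorical 'tissue'.

    ``data`` holds the feature columns (gene features are float, ``tissue`` is
    a plain object column); ``labels`` is the binary treatment label aligned to
    the rows of ``data``.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if "tissue" not in self.data.columns:
            raise ValidationError("feature table must contain a 'tissue' column")
        if self.data.isna().any().any():
            raise ValidationError("feature table contains missing values")
        if not self.labels.index.equals(self.data.index):
            raise ValidationError("labels must be indexed like the feature rows")
        levels = set(self.labels)
        if len(levels) != 2:
            raise ValidationError(f"label must be binary, got levels {sorted(levels)}")

    @property
    def feature_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def gene_features(self) -> list[str]:
        return [c for c in self.data.columns if c != "tissue"]


@dataclass
class AnnotationTable:
    """gene_id -> symbol, protein_class lookup."""

    data: pd.DataFrame  # indexed by gene_id
    allowed_classes: tuple[str, ...] = field(default=PROTEIN_CLASSES)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicated gene_id in annotation: {dupes}")
        bad = sorted(set(self.data["protein_class"]) - set(self.allowed_classes))
        if bad:
            raise ValidationError(
                f"unknown protein class(es) {bad}; allowed: {list(self.allowed_classes)}"
            )

    def protein_class(self, gene_id: str) -> str:
        if gene_id in self.data.index:
            return str(self.data.loc[gene_id, "protein_class"])
        return "other"


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_count_matrix(path, delimiter: str = "\t") -> CountMatrix:
    """Read a genes x samples TSV count matrix.

    First column holds gene ids, header row holds sample ids. Cells must be
    non-negative integers.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError("no genes parsed: file is empty") from None
    if df.shape[0] == 0:
        raise ValidationError("no genes parsed")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad[0] if len(bad) else df.index[0]
            raise ValidationError(
                f"non-numeric count at gene {gene!r}, sample {col!r}"
            )
    return CountMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(),
    )


def write_count_matrix(cm: CountMatrix, path, delimiter: str = "\t") -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter)


def read_sample_table(path, delimiter: str = "\t") -> SampleTable:
    """Read the sample metadata TSV (sample_id, treatment, tissue, duration)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"sample table missing column(s) {missing}; "
            f"required: {list(SAMPLE_TABLE_COLUMNS)}"
        )
    return SampleTable(df.set_index("sample_id"))


def write_sample_table(st: SampleTable, path, delimiter: str = "\t") -> None:
    df = st.data.reset_index()
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})
    df.to_csv(path, sep=delimiter, index=False)


def read_annotation_table(path, delimiter: str = "\t") -> AnnotationTable:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = ("gene_id", "symbol", "protein_class")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"annotation table missing column(s) {missing}; required: {list(required)}"
        )
    return AnnotationTable(df.set_index("gene_id"))


def build_feature_table(
    cm: CountMatrix,
    st: SampleTable,
    transform: str = "log2cpm",
    gene_subset: list[str] | None = None,
) -> FeatureTable:
    """Assemble the samples x features table fed to the attribute weighters.

    Each retained gene becomes one numeric feature; the tissue is appended as
    a single categorical feature; the treatment becomes the binary label.

    transform:
      - ``log2cpm`` (default): log2(1e6 * count / library_size + 1)
      - ``vst_log``: log2(count / size_factor + 1) with median-of-ratios
        size factors
      - ``none``: raw counts
    """
    if set(cm.sample_ids) != set(st.sample_ids):
        raise ValidationError("count matrix and sample table have different samples")
    st_aligned = st.data.loc[cm.sample_ids]
    lib = cm.library_sizes().astype(float)  # over ALL genes, before subsetting
    if gene_subset is not None:
        cm = cm.subset_genes(list(gene_subset))
    counts = cm.counts.astype(float)
    if transform == "log2cpm":
        if np.any(lib == 0):
            raise ValidationError("sample with zero library size under log2cpm")
        values = np.log2(1e6 * counts / lib + 1.0)
    elif transform == "vst_log":
        from .de import size_factors  # deferred: de depends on this module

        sf = size_factors(cm)
        values = np.log2(counts / sf + 1.0)
    elif transform == "none":
        values = counts
    else:
        raise ValidationError(
            f"unknown transform {transform!r}; expected log2cpm, vst_log or none"
        )
    data = pd.DataFrame(values.T, index=cm.sample_ids, columns=cm.gene_ids)
    data["tissue"] = st_aligned["tissue"].to_numpy()
    labels = pd.Series(
        st_aligned["treatment"].to_numpy(), index=cm.sample_ids, name="treatment"
    )
    if labels.nunique() != 2:
        raise ValidationError(
            "treatment must have both levels present to build a feature table"
        )
    if data.isna().any().any():
        raise ValidationError("feature table contains missing values")
    return FeatureTable(data, labels)
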
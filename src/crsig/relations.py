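"""Confidence-weighted relation networks and drug-repurposing selection.

Consumes already-extracted relation records (entity pair, relation type,
effect sign, supporting sentences), aggregates them into edges whose
confidence class is a step function of the distinct-sentence count
(>= 3 high, 2 medium, 1 low by default), finds hub nodes by degree, ranks
drugs by signature coverage, and picks drug combinations by greedy weighted
set cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import ValidationError

ENTITY_TYPES = ("gene", "drug", "concept")
RELATION_TYPES = (
    "regulation",
    "expression",
    "molecular_transport",
    "genetic_change",
    "association",
)
SIGNS = ("positive", "negative", "unsigned")
SIGN_GLYPH = {"positive": "⨁", "negative": "⊣", "unsigned": "-"}

RELATION_COLUMNS = (
    "subject",
    "subject_type",
    "object",
    "object_type",
    "relation_type",
    "sign",
    "sentence",
)

DEFAULT_HIGH_MIN = 3  # distinct sentences needed for a high-confidence call


@dataclass
class RelationRecord:
    subject: str
    subject_type: str
    object: str
    object_type: str
    relation_type: str
    sign: str
    sentences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValidationError("self-relation not allowed")
        if not self.sentences:
            raise ValidationError("relation record needs >= 1 supporting sentence")

    @property
    def key(self) -> tuple:
        return (self.subject, self.object, self.relation_type, self.sign)


@dataclass
class RelationEdge:
    subject: str
    subject_type: str
    object: str
    object_type: str
    relation_type: str
    sign: str
    n_sentences: int
    confidence_class: str


def confidence_class(n_sentences: int, high_min: int = DEFAULT_HIGH_MIN) -> str:
    """high for s >= high_min, medium for 2 <= s < high_min, low for s == 1."""
    if n_sentences < 1:
        raise ValidationError("sentence count must be >= 1")
    if n_sentences >= high_min:
        return "high"
    if n_sentences >= 2:
        return "medium"
    return "low"


def load_relations(path, delimiter: str = "\t") -> list[RelationRecord]:
    """Parse a relation TSV into records grouped per (pair, type, sign).

    Duplicate identical sentences for the same relation are de-duplicated;
    self-loop rows are skipped with a warning; unknown entity/relation/sign
    values raise, naming the offending row.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in RELATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"relation table missing column(s) {missing}; "
            f"required: {list(RELATION_COLUMNS)}"
        )
    grouped: dict[tuple, RelationRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.subject_type not in ENTITY_TYPES or row.object_type not in ENTITY_TYPES:
            raise ValidationError(
                f"row {i}: unknown entity type "
                f"({row.subject_type!r}/{row.object_type!r}); "
                f"allowed: {list(ENTITY_TYPES)}"
            )
        if row.relation_type not in RELATION_TYPES:
            raise ValidationError(
                f"row {i}: unknown relation type {row.relation_type!r}; "
                f"allowed: {list(RELATION_TYPES)}"
            )
        if row.sign not in SIGNS:
            raise ValidationError(
                f"row {i}: unknown sign {row.sign!r}; allowed: {list(SIGNS)}"
            )
        if row.subject == row.object:
            warnings.warn(f"row {i}: self-loop {row.subject!r} skipped", stacklevel=2)
            continue
        key = (row.subject, row.object, row.relation_type, row.sign)
        if key not in grouped:
            grouped[key] = RelationRecord(
                row.subject,
                row.subject_type,
                row.object,
                row.object_type,
                row.relation_type,
                row.sign,
                [row.sentence],
            )
        elif row.sentence not in grouped[key].sentences:
            grouped[key].sentences.append(row.sentence)
    return list(grouped.values())


def aggregate_confidence(
    records: list[RelationRecord], high_min: int = DEFAULT_HIGH_MIN
) -> list[RelationEdge]:
    """Collapse records into edges with distinct-sentence counts and classes."""
    merged: dict[tuple, RelationEdge] = {}
    sentences: dict[tuple, set[str]] = {}
    for rec in records:
        key = rec.key
        sentences.setdefault(key, set()).update(rec.sentences)
        merged[key] = RelationEdge(
            rec.subject,
            rec.subject_type,
            rec.object,
            rec.object_type,
            rec.relation_type,
            rec.sign,
            0,
            "low",
        )
    out = []
    for key, edge in merged.items():
        edge.n_sentences = len(sentences[key])
        edge.confidence_class = confidence_class(edge.n_sentences, high_min)
        out.append(edge)
    return out


def build_network(edges: list[RelationEdge]) -> nx.MultiGraph:
    """Typed multigraph; parallel edges kept per (pair, relation_type, sign)."""
    g = nx.MultiGraph()
    for e in edges:
        g.add_node(e.subject, entity_type=e.subject_type)
        g.add_node(e.object, entity_type=e.object_type)
        g.add_edge(
            e.subject,
            e.object,
            key=(e.relation_type, e.sign),
            relation_type=e.relation_type,
            sign=e.sign,
            glyph=SIGN_GLYPH[e.sign],
            n_sentences=e.n_sentences,
            confidence_class=e.confidence_class,
        )
    return g


def find_hubs(net: nx.MultiGraph, node_type: str | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by distinct-neighbor degree (descending; ties lexicographic)."""
    nodes = [
        n
        for n, d in net.nodes(data=True)
        if node_type is None or d.get("entity_type") == node_type
    ]
    degrees = {n: len(set(net.neighbors(n))) for n in nodes}
    return sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))


def _drug_gene_edges(net: nx.MultiGraph, signature: list[str]) -> dict[str, dict[str, int]]:
    """drug -> {signature gene -> total sentence count over parallel edges}."""
    sig = set(signature)
    out: dict[str, dict[str, int]] = {}
    for u, v, data in net.edges(data=True):
        for drug, gene in ((u, v), (v, u)):
            if (
                net.nodes[drug].get("entity_type") == "drug"
                and net.nodes[gene].get("entity_type") == "gene"
                and gene in sig
            ):
                out.setdefault(drug, {})
                out[drug][gene] = out[drug].get(gene, 0) + int(data["n_sentences"])
    return out


def rank_drugs(net: nx.MultiGraph, signature: list[str]) -> pd.DataFrame:
    """Per drug: distinct signature genes covered, then total sentence support.

    Drugs with no signature edge are excluded. Columns: drug, coverage,
    total_sentences, genes.
    """
    cover = _drug_gene_edges(net, signature)
    rows = [
        (
            drug,
            len(genes),
            sum(genes.values()),
            ",".join(sorted(genes)),
        )
        for drug, genes in cover.items()
    ]
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    df = pd.DataFrame(rows, columns=["drug", "coverage", "total_sentences", "genes"])
    df["rank"] = range(1, len(df) + 1)
    return df


def select_drug_combination(
    net: nx.MultiGraph, signature: list[str], max_drugs: int | None = None
) -> dict:
    """Greedy weighted set cover of the signature by drugs.

    Repeatedly adds the drug covering the most still-uncovered signature genes
    (ties: larger total sentence support over uncovered genes, then
    lexicographic) until the coverable genes are covered or ``max_drugs`` is
    reached.
    """
    cover = _drug_gene_edges(net, signature)
    uncovered = set(signature)
    chosen: list[str] = []
    while uncovered and (max_drugs is None or len(chosen) < max_drugs):
        best_drug = None
        best_key: tuple[int, int] = (0, 0)
        for drug in sorted(cover):
            if drug in chosen:
                continue
            new = uncovered & cover[drug].keys()
            if not new:
                continue
            key = (len(new), sum(cover[drug][g] for g in new))
            if best_drug is None or key > best_key:
                best_drug, best_key = drug, key
        if best_drug is None:
            break
        chosen.append(best_drug)
        uncovered -= cover[best_drug].keys()
    return {
        "drugs": chosen,
        "covered": sorted(set(signature) - uncovered),
        "uncovered": sorted(uncovered),
    }


def edges_frame(edges: list[RelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.subject,
                e.subject_type,
                e.object,
                e.object_type,
                e.relation_type,
                e.sign,
                SIGN_GLYPH[e.sign],
                e.n_sentences,
                e.confidence_class,
            )
            for e in edges
        ],
        columns=[
            "subject",
            "subject_type",
            "object",
            "object_type",
            "relation_type",
            "sign",
            "glyph",
            "n_sentences",
            "confidence_class",
        ],
    )


def write_edges(edges: list[RelationEdge], path, delimiter: str = "\t") -> None:
    edges_frame(edges).to_csv(path, sep=delimiter, index=False)


def read_edges(path, delimiter: str = "\t") -> list[RelationEdge]:
    df = pd.read_csv(path, sep=delimiter, dtype={"n_sentences": int})
    return [
        RelationEdge(
            r.subject,
            r.subject_type,
            r.object,
            r.object_type,
            r.relation_type,
            r.sign,
            int(r.n_sentences),
            r.confidence_class,
        )
        for r in df.itertuples(index=False)
    ]


def write_graphml(net: nx.MultiGraph, path) -> None:
    g = nx.MultiGraph()
    g.add_nodes_from(net.nodes(data=True))
    for u, v, key, data in net.edges(keys=True, data=True):
        g.add_edge(u, v, key="|".join(key), **data)
    nx.write_graphml(g, path)
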
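"""Annotation-derived gene-set construction.

Ontology parent propagation of gene->term annotations, inversion into
term->gene sets with size filtering, and top-fraction selection of genes
ranked by a specificity score.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import GeneSetCollection, Ontology, read_table

__all__ = [
    "read_annotations",
    "read_scores",
    "propagate_annotations",
    "terms_to_sets",
    "top_fraction_by_score",
]

#: evidence codes dropped by default on ingestion (electronic/untraceable)
DEFAULT_DROP_EVIDENCE = frozenset({"IEA", "NAS", "RCA"})


def read_annotations(
    path: str | os.PathLike,
    drop_evidence: frozenset[str] = DEFAULT_DROP_EVIDENCE,
    drop_not_qualifier: bool = True,
) -> dict[str, frozenset[str]]:
    """Read gene->term annotations from TSV (gene_id, term_id[, evidence,
    qualifier]), applying evidence-code and NOT-qualifier pre-filters when the
    optional columns are present."""
    df = read_table(path, required={"gene_id": str, "term_id": str})
    if "evidence" in df.columns and drop_evidence:
        df = df[~df["evidence"].isin(drop_evidence)]
    if "qualifier" in df.columns and drop_not_qualifier:
        df = df[df["qualifier"].fillna("") != "NOT"]
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in out.items()}


def read_scores(path: str | os.PathLike) -> dict[str, float]:
    """Read per-gene specificity scores from TSV (gene_id, score)."""
    df = read_table(path, required={"gene_id": str, "score": float})
    return dict(zip(df["gene_id"], df["score"].astype(float)))


def propagate_annotations(
    ontology: Ontology,
    annotations: Mapping[str, Iterable[str]],
) -> dict[str, frozenset[str]]:
    """Close each gene's term set under the ancestor relation.

    is_a and part_of are treated identically; the operation is idempotent and
    only ever adds terms. Annotation to a term unknown to the ontology is an
    error.
    """
    cache: dict[str, frozenset[str]] = {}

    def closure(term: str) -> frozenset[str]:
        if term not in cache:
            cache[term] = ontology.ancestors(term) | {term}
        return cache[term]

    out: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.items():
        closed: frozenset[str] = frozenset()
        for term in terms:
            if term not in ontology:
                raise ValueError(
                    f"gene {gene!r} annotated to unknown term {term!r}"
                )
            closed |= closure(term)
        out[gene] = closed
    return out


def terms_to_sets(
    annotations: Mapping[str, Iterable[str]],
    min_size: int = 20,
    max_size: int = 2000,
) -> GeneSetCollection:
    """Invert gene->terms into term->genes, keeping terms whose gene count is
    within [min_size, max_size] inclusive."""
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} > max_size {max_size}")
    inverted: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for term in terms:
            inverted.setdefault(term, set()).add(gene)
    collection = GeneSetCollection()
    for term in sorted(inverted):
        genes = inverted[term]
        if min_size <= len(genes) <= max_size:
            collection.add(term, genes)
    return collection


def top_fraction_by_score(
    scores: Mapping[str, float],
    fraction: float = 0.10,
    require_positive: bool = True,
) -> frozenset[str]:
    """Top ``floor(fraction * n_eligible)`` genes ranked by descending score.

    Eligibility requires score > 0 when ``require_positive``; ties at the cut
    are broken by lexicographic gene id so the result is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    eligible = [
        (gene, s) for gene, s in scores.items()
        if pd.notna(s) and (s > 0 or not require_positive)
    ]
    if not eligible:
        raise ValueError("no eligible genes")
    eligible.sort(key=lambda item: (-item[1], item[0]))
    k = int(fraction * len(eligible))
    return frozenset(gene for gene, _ in eligible[:k])
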
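"""Readers and writers for the standard formats the pipeline touches.

GMT gene-set collections, a minimal OBO 1.2 ontology subset (``is_a`` and
``part_of`` only), headered TSV tables, dense-TSV or MTX cell matrices with
sidecars, and a JSON results bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .sc_profiles import SCExpressionMatrix

__all__ = [
    "GeneSetCollection",
    "Ontology",
    "ResultsBundle",
    "GmtParseError",
    "OboParseError",
    "SchemaError",
    "read_gmt",
    "write_gmt",
    "read_obo",
    "read_table",
    "write_table",
    "read_cell_matrix",
    "write_cell_matrix",
]


class GmtParseError(ValueError):
    """Malformed GMT content (line number included in the message)."""


class OboParseError(ValueError):
    """Malformed or inconsistent OBO content (cycles, dangling edges)."""


class SchemaError(ValueError):
    """A table is missing required columns or has unparseable cells."""


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions.

    ``sets`` maps set name -> (description, frozenset of gene ids).
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate set name: {name!r}")
        self.sets[name] = (description, frozenset(genes))

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {k: v[1] for k, v in self.sets.items()} == {
            k: v[1] for k, v in other.sets.items()
        }


@dataclass
class Ontology:
    """Term DAG restricted to ``is_a``/``part_of`` child->parent edges."""

    terms: dict[str, tuple[str, str]]  # term_id -> (name, namespace)
    graph: nx.DiGraph  # edges child -> parent

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All (proper) ancestors of ``term_id`` through is_a/part_of."""
        if term_id not in self.graph:
            if term_id not in self.terms:
                raise KeyError(f"unknown term: {term_id!r}")
            return frozenset()
        return frozenset(nx.descendants(self.graph, term_id))

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: one set per tab-separated line (name, desc, genes...).

    Duplicate gene ids within a line are collapsed; a duplicate set name or a
    line with fewer than two fields is an error.
    """
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields, "
                    f"found {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            try:
                collection.add(name, genes, desc)
            except ValueError as exc:
                raise GmtParseError(f"{path}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> str:
    """Write a GMT file with genes in lexicographic order (deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc, genes = collection.sets[name]
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
    return str(path)


_KEPT_RELATIONSHIPS = frozenset({"part_of"})


def read_obo(path: str | os.PathLike) -> Ontology:
    """Parse an OBO 1.2 subset keeping only is_a/part_of relationships.

    Obsolete terms are dropped along with their edges; the resulting graph
    must be acyclic and every edge endpoint must be a parsed term.
    """
    terms: dict[str, tuple[str, str]] = {}
    obsolete: set[str] = set()
    edges: list[tuple[str, str]] = []

    cur_id: str | None = None
    cur_name = ""
    cur_ns = ""
    in_term = False

    def flush() -> None:
        nonlocal cur_id, cur_name, cur_ns
        if cur_id is not None and cur_id not in obsolete:
            terms[cur_id] = (cur_name, cur_ns)
        cur_id, cur_name, cur_ns = None, "", ""

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line or line.startswith("!"):
                continue
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            if key == "id":
                cur_id = value
            elif key == "name":
                cur_name = value
            elif key == "namespace":
                cur_ns = value
            elif key == "is_obsolete" and value == "true" and cur_id:
                obsolete.add(cur_id)
            elif key == "is_a" and cur_id:
                edges.append((cur_id, value))
            elif key == "relationship" and cur_id:
                parts = value.split()
                if len(parts) >= 2 and parts[0] in _KEPT_RELATIONSHIPS:
                    edges.append((cur_id, parts[1]))
    flush()

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for child, parent in edges:
        if child in obsolete or parent in obsolete:
            continue
        for endpoint in (child, parent):
            if endpoint not in terms:
                raise OboParseError(
                    f"{path}: edge {child} -> {parent} references unknown "
                    f"term {endpoint!r}"
                )
        graph.add_edge(child, parent)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OboParseError(f"{path}: ontology contains a cycle: {pretty}")
    return Ontology(terms=terms, graph=graph)


def read_table(
    path: str | os.PathLike,
    required: Mapping[str, type] | None = None,
) -> pd.DataFrame:
    """Read a headered TSV, checking for required columns and numeric types.

    ``required`` maps column name -> target dtype (``float``, ``int`` or
    ``str``). Extra columns are preserved and row order is kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {missing}")
        for col, typ in required.items():
            if typ is str:
                continue
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
                raise SchemaError(
                    f"{path}: column {col!r}: unparseable numeric value "
                    f"{df[col][bad].iloc[0]!r} at line {row}"
                )
            df[col] = converted.astype(typ)
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def read_cell_matrix(
    matrix_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    labels_path: str | os.PathLike,
    stage_order: list[str] | None = None,
) -> SCExpressionMatrix:
    """Load a genes x cells matrix (dense TSV or MatrixMarket) with sidecars.

    ``genes_path``/``cells_path`` are one-id-per-line text files;
    ``labels_path`` is a TSV with columns (cell_id, label). Every cell must be
    labeled and dimensions must agree with the sidecar lengths.
    """
    genes = _read_lines(genes_path)
    cells = _read_lines(cells_path)
    mpath = str(matrix_path)
    if mpath.endswith(".mtx"):
        values = np.asarray(scipy.io.mmread(mpath).todense(), dtype=float)
    else:
        values = np.loadtxt(mpath, dtype=float, ndmin=2)
    if values.shape != (len(genes), len(cells)):
        raise ValueError(
            f"{matrix_path}: dimension mismatch: expected "
            f"{(len(genes), len(cells))} from sidecars, found {values.shape}"
        )
    labels_df = read_table(labels_path, required={"cell_id": str, "label": str})
    label_map = dict(zip(labels_df["cell_id"], labels_df["label"]))
    unlabeled = [c for c in cells if c not in label_map]
    if unlabeled:
        raise ValueError(f"{labels_path}: unlabeled cell(s): {unlabeled[:5]}")
    labels = {c: label_map[c] for c in cells}
    if stage_order is None:
        seen: list[str] = []
        for c in cells:
            if labels[c] not in seen:
                seen.append(labels[c])
        stage_order = seen
    return SCExpressionMatrix(
        values=values,
        gene_ids=list(genes),
        cell_ids=list(cells),
        labels=labels,
        stage_order=list(stage_order),
    )


def write_cell_matrix(
    matrix: SCExpressionMatrix,
    matrix_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> None:
    """Write a cell matrix as MTX (if ``.mtx``) or dense TSV, with sidecars."""
    mpath = str(matrix_path)
    if mpath.endswith(".mtx"):
        scipy.io.mmwrite(mpath, scipy.sparse.coo_matrix(matrix.values))
    else:
        np.savetxt(mpath, matrix.values, delimiter="\t", fmt="%.10g")
    _write_lines(genes_path, matrix.gene_ids)
    _write_lines(cells_path, matrix.cell_ids)
    pd.DataFrame(
        {"cell_id": matrix.cell_ids,
         "label": [matrix.labels[c] for c in matrix.cell_ids]}
    ).to_csv(labels_path, sep="\t", index=False)


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str | os.PathLike, lines: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


@dataclass
class ResultsBundle:
    """Named result tables plus run metadata; JSON-serializable losslessly."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> str:
        payload = {
            "metadata": self.metadata,
            "tables": {
                name: json.loads(df.to_json(orient="split", index=False))
                for name, df in self.tables.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return str(path)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ResultsBundle":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        tables = {
            name: pd.DataFrame(spec["data"], columns=spec["columns"])
            for name, spec in payload["tables"].items()
        }
        return cls(tables=tables, metadata=payload["metadata"])
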
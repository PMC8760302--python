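"""Single-cell stage profiling of gene programs.

Cell/gene filtering, per-gene z-scoring across all cells, per-cell-type
averaging, program-level mean +/- SEM profiles across an ordered stage list,
paired t-tests between successive stages, and expressed-gene set builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "SCExpressionMatrix",
    "CellTypeMeans",
    "ProgramProfile",
    "StageTestResult",
    "filter_cells",
    "filter_genes",
    "zscore_genes",
    "celltype_gene_means",
    "program_profile",
    "successive_stage_tests",
    "expressed_in_cells",
]


@dataclass
class SCExpressionMatrix:
    """Genes x cells expression values with per-cell stage/cell-type labels."""

    values: np.ndarray  # shape (n_genes, n_cells)
    gene_ids: list[str]
    cell_ids: list[str]
    labels: dict[str, str]  # cell_id -> stage name
    stage_order: list[str]
    constant_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        missing = [c for c in self.cell_ids if c not in self.labels]
        if missing:
            raise ValueError(f"unlabeled cell(s): {missing[:5]}")
        unknown = {self.labels[c] for c in self.cell_ids} - set(self.stage_order)
        if unknown:
            raise ValueError(f"labels missing from stage_order: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_stages(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.cell_ids])

    def subset(self, gene_mask: np.ndarray | None = None,
               cell_mask: np.ndarray | None = None) -> "SCExpressionMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else gene_mask
        cm = np.ones(self.n_cells, bool) if cell_mask is None else cell_mask
        cells = [c for c, keep in zip(self.cell_ids, cm) if keep]
        return replace(
            self,
            values=self.values[np.ix_(gm, cm)],
            gene_ids=[g for g, keep in zip(self.gene_ids, gm) if keep],
            cell_ids=cells,
            labels={c: self.labels[c] for c in cells},
        )


@dataclass
class CellTypeMeans:
    """Genes x stages matrix of averaged (z-scored) expression."""

    values: np.ndarray  # shape (n_genes, n_stages)
    gene_ids: list[str]
    stages: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.stages)


@dataclass
class ProgramProfile:
    """Per-stage mean and SEM of gene-level averages for one program."""

    stages: list[str]
    mean: np.ndarray
    sem: np.ndarray
    n_genes: int


@dataclass
class StageTestResult:
    stage_a: str
    stage_b: str
    t: float
    p_raw: float
    p_corrected: float
    n_genes: int


def filter_cells(
    matrix: SCExpressionMatrix,
    min_frac_genes: float = 0.05,
    tpm_min: float = 1.0,
) -> SCExpressionMatrix:
    """Drop cells expressing (TPM >= ``tpm_min``) fewer than ``min_frac_genes``
    of all genes. The removal rule is strict "less than": a cell at exactly the
    threshold is retained."""
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    frac = (matrix.values >= tpm_min).mean(axis=0)
    keep = frac >= min_frac_genes
    if not keep.any():
        raise ValueError("all cells removed by filter_cells")
    return matrix.subset(cell_mask=keep)


def filter_genes(
    matrix: SCExpressionMatrix, min_frac_cells: float = 0.05
) -> SCExpressionMatrix:
    """Drop genes with nonzero expression in fewer than ``min_frac_cells`` of
    the (surviving) cells; run after :func:`filter_cells`."""
    frac = (matrix.values > 0).mean(axis=1)
    keep = frac >= min_frac_cells
    if not keep.any():
        raise ValueError("all genes removed by filter_genes")
    return matrix.subset(gene_mask=keep)


def zscore_genes(matrix: SCExpressionMatrix, ddof: int = 0) -> SCExpressionMatrix:
    """Z-score each gene across all cells; constant genes become all-zero rows
    and are flagged in ``constant_genes``."""
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=ddof, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    values = (matrix.values - mean) / sd
    values[constant] = 0.0
    out = matrix.subset()
    out.values = values
    out.constant_genes = frozenset(
        g for g, c in zip(matrix.gene_ids, constant) if c
    )
    return out


def celltype_gene_means(matrix: SCExpressionMatrix) -> CellTypeMeans:
    """Average (z-scored) expression of each gene within each stage."""
    stages = matrix.cell_stages()
    out = np.empty((matrix.n_genes, len(matrix.stage_order)))
    for j, stage in enumerate(matrix.stage_order):
        members = stages == stage
        if not members.any():
            raise ValueError(f"stage {stage!r} has no cells")
        out[:, j] = matrix.values[:, members].mean(axis=1)
    return CellTypeMeans(values=out, gene_ids=list(matrix.gene_ids),
                         stages=list(matrix.stage_order))


def _program_rows(means: CellTypeMeans, program: Iterable[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(means.gene_ids)}
    return np.array(sorted(index[g] for g in program if g in index), dtype=int)


def program_profile(means: CellTypeMeans, program: Iterable[str]) -> ProgramProfile:
    """Mean and SEM (sd/sqrt(n), ddof=1) of gene-level stage averages over the
    program genes present in the data."""
    rows = _program_rows(means, program)
    if len(rows) < 2:
        raise ValueError(
            f"need >= 2 program genes present in data, found {len(rows)}"
        )
    sub = means.values[rows]
    return ProgramProfile(
        stages=list(means.stages),
        mean=sub.mean(axis=0),
        sem=sub.std(axis=0, ddof=1) / np.sqrt(len(rows)),
        n_genes=len(rows),
    )


def successive_stage_tests(
    means: CellTypeMeans,
    program: Iterable[str],
    pairs: Sequence[tuple[str, str]] | None = None,
    paired: bool = True,
    m: int | None = None,
) -> list[StageTestResult]:
    """Two-tailed t-tests on a program's gene-level averages between stage
    pairs (successive stages by default), Bonferroni-corrected over the number
    of pairs.

    ``paired=True`` pairs the per-gene averages across the two stages
    (the same genes are measured in both); ``paired=False`` runs an
    equal-variance two-sample Student's t.
    """
    if pairs is None:
        pairs = list(zip(means.stages[:-1], means.stages[1:]))
    if not pairs:
        raise ValueError("no stage pairs to test")
    rows = _program_rows(means, program)
    if len(rows) < 3:
        raise ValueError(f"need >= 3 program genes, found {len(rows)}")
    m = len(pairs) if m is None else m
    col = {s: j for j, s in enumerate(means.stages)}
    results = []
    for a, b in pairs:
        if a not in col or b not in col:
            raise ValueError(f"unknown stage in pair ({a!r}, {b!r})")
        xa = means.values[rows, col[a]]
        xb = means.values[rows, col[b]]
        if paired:
            if np.allclose(xa, xb):
                t, p = 0.0, 1.0
            else:
                t, p = scipy.stats.ttest_rel(xa, xb)
        else:
            t, p = scipy.stats.ttest_ind(xa, xb, equal_var=True)
        results.append(StageTestResult(
            stage_a=a, stage_b=b, t=float(t), p_raw=float(p),
            p_corrected=min(1.0, float(p) * m), n_genes=len(rows),
        ))
    return results


def expressed_in_cells(
    matrix: SCExpressionMatrix,
    stages: Iterable[str],
    min_frac: float = 0.05,
    mode: Literal["tpm", "nonzero-any"] = "tpm",
    tpm_min: float = 1.0,
) -> frozenset[str]:
    """Build an expressed-gene set from the cells of the listed stages.

    ``mode="tpm"`` (stringent): genes at TPM >= ``tpm_min`` in at least
    ``min_frac`` of the cells of *any one* listed stage.
    ``mode="nonzero-any"`` (relaxed): genes with nonzero expression in at
    least one cell across the listed stages.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("empty stage subset")
    cell_stages = matrix.cell_stages()
    unknown = set(stages) - set(matrix.stage_order)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    genes = np.asarray(matrix.gene_ids)
    if mode == "nonzero-any":
        members = np.isin(cell_stages, stages)
        keep = (matrix.values[:, members] > 0).any(axis=1)
        return frozenset(genes[keep])
    keep = np.zeros(matrix.n_genes, bool)
    for stage in stages:
        members = cell_stages == stage
        if members.any():
            frac = (matrix.values[:, members] >= tpm_min).mean(axis=1)
            keep |= frac >= min_frac
    return frozenset(genes[keep])
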
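"""Competitive gene-set enrichment on gene-level association statistics.

Per-gene Z-scores are regressed on a set-membership indicator with optional
conditioning gene sets and covariates (ordinary least squares); conditioning
by covariate inclusion is equivalent, by Frisch-Waugh-Lovell, to
residualizing first. Includes a coefficient-difference z-test between two
enrichment fits and a partition-wide scan with Bonferroni control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .programs import ProgramPartition

__all__ = [
    "GeneAssocStats",
    "EnrichmentResult",
    "CoefficientComparison",
    "DegenerateDesignError",
    "z_from_p",
    "competitive_enrichment",
    "compare_coefficients",
    "partition_enrichment",
]

Sidedness = Literal["greater", "two-sided"]


class DegenerateDesignError(ValueError):
    """The regression design is rank-deficient (collinear indicators)."""


@dataclass
class GeneAssocStats:
    """Per-gene association Z-scores plus optional named covariates."""

    table: pd.DataFrame  # columns: gene_id, z [, cov_*]

    def __post_init__(self) -> None:
        for col in ("gene_id", "z"):
            if col not in self.table.columns:
                raise ValueError(f"gene stats missing column {col!r}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in stats")
        z = self.table["z"].to_numpy(float)
        if not np.isfinite(z).all():
            raise ValueError("non-finite z scores")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene_id"])

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(float)

    def covariate(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EnrichmentResult:
    set_name: str
    beta: float
    se: float
    stat: float
    p: float
    n_genes: int
    sidedness: Sidedness
    p_corrected: float | None = None
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class CoefficientComparison:
    d: float
    se_d: float
    z: float
    p: float
    alternative: Sidedness


def z_from_p(p: float, direction: int = 1) -> float:
    """Probit map of a one-sided gene p-value to a signed Z-score.

    z = Phi^{-1}(1 - p) with the sign of ``direction``; p must lie in (0, 1)
    (both endpoints map to infinite z).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p} (infinite z)")
    return float(np.sign(direction) * scipy.stats.norm.isf(p))


def _indicator(genes: Sequence[str], members: frozenset[str]) -> np.ndarray:
    return np.fromiter((g in members for g in genes), dtype=float,
                       count=len(genes))


def competitive_enrichment(
    stats: GeneAssocStats,
    gene_set: Iterable[str],
    conditioning: Sequence[Iterable[str]] = (),
    covariates: Sequence[str] = (),
    sidedness: Sidedness = "greater",
    set_name: str = "",
    min_genes: int = 10,
) -> EnrichmentResult:
    """OLS of z on [intercept, set indicator, conditioning indicators,
    covariates]; beta is the set-indicator coefficient and p comes from the t
    distribution with residual degrees of freedom.

    Raises :class:`DegenerateDesignError` when the set indicator is collinear
    with the other columns (e.g. set == universe) and ``ValueError`` when the
    set has fewer than ``min_genes`` genes in or out of the universe.
    """
    genes = stats.genes
    universe = frozenset(genes)
    members = frozenset(gene_set) & universe
    n_in = len(members)
    n_out = len(universe) - n_in
    if n_in == 0 or n_out == 0:
        raise DegenerateDesignError(
            f"set {set_name!r}: indicator is constant (set covers "
            f"{'all' if n_out == 0 else 'none'} of the universe)"
        )
    if n_in < min_genes or n_out < min_genes:
        raise ValueError(
            f"set {set_name!r}: needs >= {min_genes} genes in and out of the "
            f"universe (got {n_in} in, {n_out} out)"
        )
    cols = [np.ones(len(genes)), _indicator(genes, members)]
    for cond in conditioning:
        cols.append(_indicator(genes, frozenset(cond) & universe))
    for cov in covariates:
        cols.append(stats.covariate(cov))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"set {set_name!r}: design matrix is rank-deficient "
            f"(rank {rank} < {X.shape[1]} columns)"
        )
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")
    y = stats.z
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(beta_hat[1])
    tstat = beta / se
    if sidedness == "greater":
        p = float(scipy.stats.t.sf(tstat, dof))
    else:
        p = float(2 * scipy.stats.t.sf(abs(tstat), dof))
    return EnrichmentResult(
        set_name=set_name, beta=beta, se=se, stat=tstat, p=p,
        n_genes=n_in, sidedness=sidedness,
    )


def compare_coefficients(
    r1: EnrichmentResult,
    r2: EnrichmentResult,
    alternative: Sidedness = "two-sided",
) -> CoefficientComparison:
    """z = (beta1 - beta2) / sqrt(SE1^2 + SE2^2) against a standard normal."""
    d = r1.beta - r2.beta
    se_d = float(np.hypot(r1.se, r2.se))
    if se_d == 0:
        raise ValueError("se_d is zero; comparison undefined")
    z = d / se_d
    if alternative == "greater":
        p = float(scipy.stats.norm.sf(z))
    else:
        p = float(2 * scipy.stats.norm.sf(abs(z)))
    return CoefficientComparison(d=float(d), se_d=se_d, z=float(z), p=p,
                                 alternative=alternative)


def partition_enrichment(
    stats: GeneAssocStats,
    partition: ProgramPartition | Mapping[str, frozenset[str]],
    conditioning: Sequence[Iterable[str]] = (),
    sidedness: Sidedness = "greater",
    extra_condition_per_segment: Iterable[str] | None = None,
    covariates: Sequence[str] = (),
    min_genes: int = 10,
) -> list[EnrichmentResult]:
    """One competitive test per partition segment with shared conditioning.

    Bonferroni correction uses the number of segments actually tested;
    segments below the size floor are reported as skipped, not errors.
    """
    segs = partition.segments if isinstance(partition, ProgramPartition) else dict(partition)
    cond = list(conditioning)
    if extra_condition_per_segment is not None:
        cond = cond + [frozenset(extra_condition_per_segment)]
    results: list[EnrichmentResult] = []
    for name, genes in segs.items():
        try:
            res = competitive_enrichment(
                stats, genes, conditioning=cond, covariates=covariates,
                sidedness=sidedness, set_name=name, min_genes=min_genes,
            )
        except ValueError as exc:
            if isinstance(exc, DegenerateDesignError):
                raise
            res = EnrichmentResult(
                set_name=name, beta=float("nan"), se=float("nan"),
                stat=float("nan"), p=float("nan"),
                n_genes=len(frozenset(genes) & frozenset(stats.genes)),
                sidedness=sidedness, skipped=True, skip_reason=str(exc),
            )
        results.append(res)
    m = sum(not r.skipped for r in results)
    for r in results:
        if not r.skipped:
            r.p_corrected = min(1.0, r.p * m)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "segment": [r.set_name for r in results],
            "n_genes": [r.n_genes for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "p_corrected": [r.p_corrected for r in results],
            "skipped": [r.skipped for r in results],
        }
    )
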
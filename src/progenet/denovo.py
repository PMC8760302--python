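"""Exact de novo loss-of-function burden tests.

Expected mutation counts come from per-gene LoF mutation rates (2 * trios *
sum of rates); gene-set segments are compared against all other expressed
genes with an exact two-sided Poisson rate-ratio test (conditional binomial,
minimum-likelihood two-sided convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .programs import GeneUniverse, ProgramPartition

__all__ = [
    "DenovoDataset",
    "RateRatioResult",
    "expected_counts",
    "rate_ratio_test",
    "denovo_partition_scan",
]

# relative slack when comparing pmf values, as in R's poisson.test
_REL_ERR = 1 + 1e-7


@dataclass
class Cohort:
    n_trios: int
    counts: dict[str, int]  # gene_id -> observed de novo LoF count


@dataclass
class DenovoDataset:
    """Per-cohort trio counts and per-gene observed de novo LoF counts."""

    cohorts: dict[str, Cohort] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cohort in self.cohorts.items():
            for gene, count in cohort.counts.items():
                if count < 0 or count != int(count):
                    raise ValueError(
                        f"cohort {name!r}: non-integer or negative count for "
                        f"{gene!r}: {count}"
                    )


@dataclass
class RateRatioResult:
    segment: str
    cohort: str
    obs_in: int
    exp_in: float
    obs_out: int
    exp_out: float
    rate_ratio: float
    p: float
    p_corrected: float | None = None
    degenerate: bool = False


def expected_counts(
    rates: Mapping[str, float],
    n_trios: int,
    genes: Iterable[str],
) -> float:
    """Expected de novo count: 2 * n_trios * sum of per-gene mutation rates
    (two transmitted haplotypes per trio)."""
    genes = list(genes)
    missing = [g for g in genes if g not in rates]
    if missing:
        raise ValueError(f"missing mutation rate(s) for: {sorted(missing)[:10]}")
    return 2.0 * n_trios * float(sum(rates[g] for g in genes))


def _binom_two_sided(x: int, n: int, p: float) -> float:
    """Exact two-sided binomial p: sum of all outcome probabilities not
    exceeding the observed one (with relative slack for float ties)."""
    pmf = scipy.stats.binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[(pmf <= pmf[x] * _REL_ERR)].sum()))


def rate_ratio_test(
    obs_in: int,
    exp_in: float,
    obs_out: int,
    exp_out: float,
    segment: str = "",
    cohort: str = "",
) -> RateRatioResult:
    """Exact two-sided Poisson rate-ratio test.

    Conditional on T = obs_in + obs_out, obs_in ~ Binomial(T,
    exp_in/(exp_in+exp_out)) under the null of equal rates; the two-sided p
    sums binomial probabilities <= that of the observed count. T == 0 is
    degenerate (rate ratio reported as 1, p = 1).
    """
    if exp_in <= 0 or exp_out <= 0:
        raise ValueError(
            f"expected counts must be positive (got {exp_in}, {exp_out})"
        )
    if obs_in < 0 or obs_out < 0:
        raise ValueError("negative observed counts")
    total = obs_in + obs_out
    if total == 0:
        return RateRatioResult(
            segment=segment, cohort=cohort, obs_in=0, exp_in=exp_in,
            obs_out=0, exp_out=exp_out, rate_ratio=1.0, p=1.0,
            degenerate=True,
        )
    if obs_out == 0:
        ratio = float("inf")
    else:
        ratio = (obs_in / exp_in) / (obs_out / exp_out)
    p = _binom_two_sided(obs_in, total, exp_in / (exp_in + exp_out))
    return RateRatioResult(
        segment=segment, cohort=cohort, obs_in=obs_in, exp_in=exp_in,
        obs_out=obs_out, exp_out=exp_out, rate_ratio=float(ratio), p=p,
    )


def denovo_partition_scan(
    dataset: DenovoDataset,
    partition: ProgramPartition | Mapping[str, frozenset[str]],
    universe: GeneUniverse | Iterable[str],
    rates: Mapping[str, float],
) -> list[RateRatioResult]:
    """Rate-ratio test of every cohort x segment against all other expressed
    genes, Bonferroni-corrected per cohort over the number of segments."""
    segs = partition.segments if isinstance(partition, ProgramPartition) else dict(partition)
    uni = list(universe.genes) if isinstance(universe, GeneUniverse) else list(universe)
    uni_set = frozenset(uni)
    for name, genes in segs.items():
        stray = frozenset(genes) - uni_set
        if stray:
            raise ValueError(
                f"segment {name!r} outside universe: {sorted(stray)[:5]}"
            )
    results: list[RateRatioResult] = []
    m = len(segs)
    for cohort_name, cohort in dataset.cohorts.items():
        for seg_name, seg_genes in segs.items():
            inside = frozenset(seg_genes)
            outside = uni_set - inside
            obs_in = int(sum(cohort.counts.get(g, 0) for g in inside))
            obs_out = int(sum(cohort.counts.get(g, 0) for g in outside))
            res = rate_ratio_test(
                obs_in,
                expected_counts(rates, cohort.n_trios, inside),
                obs_out,
                expected_counts(rates, cohort.n_trios, outside),
                segment=seg_name,
                cohort=cohort_name,
            )
            res.p_corrected = min(1.0, res.p * m)
            results.append(res)
    return results


def rate_ratio_frame(results: Iterable[RateRatioResult]) -> pd.DataFrame:
    results = list(results)
    return pd.DataFrame(
        {
            "cohort": [r.cohort for r in results],
            "segment": [r.segment for r in results],
            "obs_in": [r.obs_in for r in results],
            "exp_in": [r.exp_in for r in results],
            "obs_out": [r.obs_out for r in results],
            "exp_out": [r.exp_out for r in results],
            "RR": [r.rate_ratio for r in results],
            "p": [r.p for r in results],
            "p_corrected": [r.p_corrected for r in results],
        }
    )
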
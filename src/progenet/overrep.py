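"""Fisher's-exact over-representation and iterative term refinement.

Over-representation of a query gene set in annotation terms is tested against
an expressed-gene background; the refinement loop repeatedly selects the
surviving term with the largest odds ratio, strips its genes from the other
terms, re-tests, and Bonferroni-drops until nothing survives — yielding a
semi-independent subset of enriched terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd
import scipy.stats

from .io_formats import GeneSetCollection

__all__ = ["OverrepResult", "fisher_overrep", "bonferroni", "refine_terms"]

Alternative = Literal["greater", "two-sided"]


@dataclass
class OverrepResult:
    """One query-vs-term over-representation test."""

    term_name: str
    n_overlap: int
    odds_ratio: float
    p_raw: float
    p_corrected: float
    alternative: Alternative
    n_query: int = 0
    n_term: int = 0
    iteration_selected: int | None = None


def fisher_overrep(
    query: Iterable[str],
    term: Iterable[str],
    background: Iterable[str],
    alternative: Alternative = "greater",
    term_name: str = "",
) -> OverrepResult:
    """Fisher's exact test of query/term overlap against a background.

    The 2x2 table is (a, b; c, d) = (|q&t|, |q-t|; |t-q|, |bg-(q|t)|). The
    odds ratio is the sample OR a*d/(b*c), with OR = inf when b*c == 0 and
    a*d > 0, and OR = nan when both products vanish. The p-value is the exact
    hypergeometric tail for the stated alternative (two-sided by the
    minimum-likelihood convention).
    """
    q, t, bg = frozenset(query), frozenset(term), frozenset(background)
    if not bg:
        raise ValueError("empty background")
    offenders = (q | t) - bg
    if offenders:
        raise ValueError(
            f"query/term gene(s) outside background: {sorted(offenders)[:10]}"
        )
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(bg) - a - b - c
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if a == 0 and (b or c) else math.nan)
    else:
        odds = (a * d) / (b * c)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return OverrepResult(
        term_name=term_name,
        n_overlap=a,
        odds_ratio=float(odds),
        p_raw=float(min(p, 1.0)),
        p_corrected=float(min(p, 1.0)),
        alternative=alternative,
        n_query=len(q),
        n_term=len(t),
    )


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """min(1, p * m) for each p, order preserved; m defaults to len(pvals)."""
    m = len(pvals) if m is None else m
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    out = []
    for p in pvals:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, p * m))
    return out


def refine_terms(
    query: Iterable[str],
    terms: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
    alternative: Alternative = "greater",
) -> list[OverrepResult]:
    """Iteratively select semi-independent over-represented terms.

    Each iteration: test every surviving term against the query, Bonferroni
    correct by the number of sets tested this iteration, drop corrected
    p >= ``alpha``; among the survivors select the term with the largest odds
    ratio (ties: smaller raw p, then lexicographic name), emit it, and remove
    its current genes from all other surviving terms. Repeats until no term
    survives. Deterministic and invariant to input ordering.
    """
    q = frozenset(query)
    bg = frozenset(background)
    surviving: dict[str, frozenset[str]] = {
        name: terms.genes(name) for name in terms.names()
    }
    selected: list[OverrepResult] = []
    iteration = 0
    while surviving:
        iteration += 1
        m = len(surviving)
        tested: list[OverrepResult] = []
        for name in sorted(surviving):
            res = fisher_overrep(q, surviving[name], bg,
                                 alternative=alternative, term_name=name)
            res.p_corrected = min(1.0, res.p_raw * m)
            tested.append(res)
        significant = [r for r in tested if r.p_corrected < alpha]
        if not significant:
            break
        best = min(
            significant,
            key=lambda r: (-r.odds_ratio, r.p_raw, r.term_name),
        )
        best.iteration_selected = iteration
        selected.append(best)
        removed = surviving.pop(best.term_name)
        surviving = {
            name: genes - removed for name, genes in surviving.items()
        }
    return selected


def results_to_frame(results: Sequence[OverrepResult]) -> pd.DataFrame:
    """Tabulate results with the standard report columns."""
    return pd.DataFrame(
        {
            "term": [r.term_name for r in results],
            "N_overlap": [r.n_overlap for r in results],
            "OR": [r.odds_ratio for r in results],
            "P_overlap": [r.p_raw for r in results],
            "P_corrected": [r.p_corrected for r in results],
            "iteration_selected": [r.iteration_selected for r in results],
        }
    )
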
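import math
from fractions import Fraction

import numpy as np
import pytest

from progenet.synthetic import SimulationConfig


def hypergeom_pmf(a: int, n_term: int, n_query: int, n_bg: int) -> Fraction:
    """Exact hypergeometric pmf via integer arithmetic (independent oracle)."""
    return Fraction(
        math.comb(n_term, a) * math.comb(n_bg - n_term, n_query - a),
        math.comb(n_bg, n_query),
    )


def fisher_oracle(a: int, n_query: int, n_term: int, n_bg: int,
                  alternative: str = "greater") -> float:
    """Full-enumeration Fisher p for the (query, term, background) layout."""
    lo = max(0, n_query + n_term - n_bg)
    hi = min(n_query, n_term)
    obs = hypergeom_pmf(a, n_term, n_query, n_bg)
    if alternative == "greater":
        total = sum(hypergeom_pmf(k, n_term, n_query, n_bg)
                    for k in range(a, hi + 1))
    elif alternative == "less":
        total = sum(hypergeom_pmf(k, n_term, n_query, n_bg)
                    for k in range(lo, a + 1))
    else:
        total = sum(p for k in range(lo, hi + 1)
                    if (p := hypergeom_pmf(k, n_term, n_query, n_bg)) <= obs)
    return float(min(total, Fraction(1)))


def binom_two_sided_oracle(x: int, n: int, p: float) -> float:
    """Minimum-likelihood two-sided binomial p by full pmf enumeration."""
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[x] * (1 + 1e-7)].sum()))


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A fast config: 600 genes, 40-gene programs, 20 cells per stage."""
    return SimulationConfig(
        n_genes=600,
        program_sizes={"early-transient": 40, "early-stable": 40,
                       "early-increasing": 40, "late": 40},
        sc_celltypes={stage: 20 for stage in
                      ("RG-early", "RG", "IPC", "Transitioning", "Newborn",
                       "Developing")},
        seed=7,
    )
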
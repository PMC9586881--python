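"""Frequentist null-hypothesis tests on the population prevalence.

Under the binomial model, a prevalence null ``gamma <= gamma0`` is most
conservative at ``gamma = gamma0``, where each participant is significant
with probability ``theta(gamma0) = alpha + gamma0 * (1 - alpha)``.  The
p-value is the exact upper binomial tail P(X >= k | n, theta(gamma0)).
The global null is ``gamma0 = 0`` (success probability alpha); the
majority null is ``gamma0 = 0.5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import PrevalencePosterior, TestOutcomes, map_estimate, theta_of_gamma

__all__ = [
    "PrevalenceNullResult",
    "global_null_pvalue",
    "prevalence_null_pvalue",
    "contour_grid",
    "write_contour_grid",
]

LOG10 = math.log(10.0)

#: TSV header used by :func:`write_contour_grid`
GRID_COLUMNS = ["n", "k", "neglog10p_global", "neglog10p_majority", "map", "hpdi_lower"]


@dataclass(frozen=True)
class PrevalenceNullResult:
    p_value: float
    neg_log10_p: float
    null_prevalence: float
    outcomes: TestOutcomes


def _binom_tail_logp(k: int, n: int, theta: float) -> float:
    """log P(X >= k | n, theta), summed in log space from the pmf terms.

    Accumulating via logsumexp keeps tails as small as 1e-300 exact to
    machine precision; the convention P(X >= 0) = 1 holds.
    """
    if k == 0:
        return 0.0
    j = np.arange(k, n + 1)
    return float(special.logsumexp(stats.binom.logpmf(j, n, theta)))


def prevalence_null_pvalue(outcomes: TestOutcomes, gamma0: float) -> PrevalenceNullResult:
    """Exact binomial test of the null ``prevalence <= gamma0``.

    Parameters
    ----------
    outcomes : TestOutcomes
        k significant of n at within-participant rate alpha.
    gamma0 : float
        Null prevalence in [0, 1); 0 is the global null, 0.5 the majority
        null.
    """
    if not 0.0 <= gamma0 < 1.0:
        raise ValueError(f"gamma0 must lie in [0, 1), got {gamma0}")
    theta0 = float(theta_of_gamma(gamma0, outcomes.alpha))
    logp = _binom_tail_logp(outcomes.k, outcomes.n, theta0)
    return PrevalenceNullResult(
        p_value=float(math.exp(logp)),
        neg_log10_p=-logp / LOG10,
        null_prevalence=gamma0,
        outcomes=outcomes,
    )


def global_null_pvalue(outcomes: TestOutcomes) -> PrevalenceNullResult:
    """Exact binomial test of the global null (prevalence is 0)."""
    return prevalence_null_pvalue(outcomes, 0.0)


def contour_grid(n_values, alpha: float = 0.05, mass: float = 0.96) -> pd.DataFrame:
    """Long-format table of prevalence evidence over all (n, k) pairs.

    For every ``n`` in ``n_values`` and every ``k`` in 0..n, tabulates the
    global- and majority-null -log10 p-values, the MAP prevalence estimate
    and the lower edge of the ``mass`` HPD interval — the surfaces shown as
    contour plots of evidence against participant count.
    """
    n_values = list(n_values)
    if not n_values:
        raise ValueError("n_values must be nonempty")
    rows = []
    for n in n_values:
        for k in range(0, n + 1):
            outcomes = TestOutcomes(k, n, alpha)
            rows.append(
                {
                    "n": n,
                    "k": k,
                    "neglog10p_global": global_null_pvalue(outcomes).neg_log10_p,
                    "neglog10p_majority": prevalence_null_pvalue(outcomes, 0.5).neg_log10_p,
                    "map": map_estimate(outcomes),
                    "hpdi_lower": PrevalencePosterior(outcomes).hpdi(mass).lower,
                }
            )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def write_contour_grid(df: pd.DataFrame, path) -> None:
    """Write a contour grid as TSV with the fixed header."""
    df.to_csv(path, sep="\t", index=False, columns=GRID_COLUMNS, float_format="%.10g")
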
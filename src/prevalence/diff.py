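"""Monte-Carlo posteriors for differences in population prevalence.

Two designs are supported:

* *between groups* — the same within-participant test applied to samples
  from two populations; the posteriors are independent and the difference
  delta = gamma_a - gamma_b is sampled by subtracting independent draws.

* *paired tests* — two tests applied to the same participants.  Each
  participant falls in one of four latent classes (true effect on both
  tests / only A / only B / neither) with probabilities
  (rho11, rho10, rho01, rho00) on the simplex.  A class with a true effect
  on a test is always significant on it; a class without is significant
  with that test's false-positive rate.  The observed joint counts
  (k11, k10, k01, k00) are multinomial with cell probabilities

      P11 = rho11 + rho10*a2 + rho01*a1 + rho00*a1*a2
      P10 = rho10*(1 - a2) + rho00*a1*(1 - a2)
      P01 = rho01*(1 - a1) + rho00*(1 - a1)*a2
      P00 = rho00*(1 - a1)*(1 - a2)

  and the prevalence difference is delta = gammaA - gammaB = rho10 - rho01.
  The posterior under a uniform Dirichlet prior is approximated by
  sampling-importance-resampling (SIR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .core import PrevalencePosterior, TestOutcomes

__all__ = [
    "PairedCounts",
    "DifferenceSamples",
    "sample_posterior",
    "between_groups_difference",
    "paired_difference",
    "paired_cell_probabilities",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedCounts:
    """Joint outcome counts for two tests on the same participants."""

    k11: int
    k10: int
    k01: int
    k00: int
    alpha1: float = 0.05
    alpha2: float = 0.05

    def __post_init__(self) -> None:
        counts = (self.k11, self.k10, self.k01, self.k00)
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be >= 0, got {counts}")
        if sum(counts) < 1:
            raise ValueError("total participant count must be >= 1")
        for a in (self.alpha1, self.alpha2):
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha must lie in (0, 1), got {a}")

    @property
    def n(self) -> int:
        return self.k11 + self.k10 + self.k01 + self.k00

    def swapped(self) -> "PairedCounts":
        """Counts with the roles of the two tests exchanged."""
        return PairedCounts(self.k11, self.k01, self.k10, self.k00,
                            self.alpha2, self.alpha1)


@dataclass(frozen=True)
class DifferenceSamples:
    """Posterior draws of a prevalence difference delta in [-1, 1]."""

    draws: np.ndarray
    seed: int
    mass: float = 0.96
    ess: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "draws", np.asarray(self.draws, dtype=float))
        if self.draws.size < 1:
            raise ValueError("draws must be nonempty")
        if np.any(self.draws < -1.0) or np.any(self.draws > 1.0):
            raise ValueError("delta draws must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return int(self.draws.size)

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    def interval(self, mass: float | None = None) -> tuple[float, float]:
        """Central (equal-tail) credible interval from sorted draws."""
        m = self.mass if mass is None else mass
        lo, hi = np.quantile(self.draws, [(1.0 - m) / 2.0, (1.0 + m) / 2.0])
        return (float(lo), float(hi))

    @property
    def prob_positive(self) -> float:
        return float(np.mean(self.draws > 0.0))

    def summary(self) -> dict:
        lo, hi = self.interval()
        out = {
            "median": self.median,
            "interval_mass": self.mass,
            "interval_lower": lo,
            "interval_upper": hi,
            "prob_delta_positive": self.prob_positive,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }
        if self.ess is not None:
            out["effective_sample_size"] = self.ess
        return out


def sample_posterior(outcomes: TestOutcomes, n_samples: int, seed) -> np.ndarray:
    """I.i.d. prevalence draws by inverse-cdf sampling; reproducible by seed."""
    return PrevalencePosterior(outcomes).sample(n_samples, seed=seed)


def between_groups_difference(
    outcomes_a: TestOutcomes,
    outcomes_b: TestOutcomes,
    n_samples: int = 10000,
    seed: int = 0,
    mass: float = 0.96,
) -> DifferenceSamples:
    """Posterior of delta = gamma_a - gamma_b for two independent samples.

    Independent sub-streams for the two groups are derived from the root
    seed, so results are bit-reproducible.
    """
    seed_a, seed_b = np.random.SeedSequence(seed).spawn(2)
    draws_a = sample_posterior(outcomes_a, n_samples, seed_a)
    draws_b = sample_posterior(outcomes_b, n_samples, seed_b)
    return DifferenceSamples(draws_a - draws_b, seed=seed, mass=mass)


def paired_cell_probabilities(rho: np.ndarray, alpha1: float, alpha2: float) -> np.ndarray:
    """Observed-cell probabilities (P11, P10, P01, P00) from latent-class
    probabilities ``rho = (rho11, rho10, rho01, rho00)``.

    Accepts an (..., 4) array; the output sums to 1 along the last axis for
    any rho on the simplex.
    """
    rho = np.asarray(rho, dtype=float)
    r11, r10, r01, r00 = (rho[..., i] for i in range(4))
    a1, a2 = alpha1, alpha2
    return np.stack(
        [
            r11 + r10 * a2 + r01 * a1 + r00 * a1 * a2,
            r10 * (1.0 - a2) + r00 * a1 * (1.0 - a2),
            r01 * (1.0 - a1) + r00 * (1.0 - a1) * a2,
            r00 * (1.0 - a1) * (1.0 - a2),
        ],
        axis=-1,
    )


def paired_difference(
    counts: PairedCounts,
    n_samples: int = 10000,
    seed: int = 0,
    mass: float = 0.96,
    proposal_factor: int = 50,
) -> DifferenceSamples:
    """SIR posterior of delta = rho10 - rho01 for two tests, same participants.

    Proposals are drawn from the Dirichlet(counts + 1) posterior of an
    error-free multinomial model (which dominates the target and matches it
    as alpha -> 0) and weighted by the likelihood ratio against the true
    cell probabilities; ``n_samples`` draws are then resampled in
    proportion to the weights.  The importance effective sample size is
    reported with the summaries; below 1% of the proposal count a
    diagnostic warning is logged.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss_prop, ss_res = np.random.SeedSequence(seed).spawn(2)
    rng_prop = np.random.default_rng(ss_prop)
    rng_res = np.random.default_rng(ss_res)

    n_prop = proposal_factor * n_samples
    kvec = np.array([counts.k11, counts.k10, counts.k01, counts.k00], dtype=float)
    rho = rng_prop.dirichlet(kvec + 1.0, size=n_prop)
    cells = paired_cell_probabilities(rho, counts.alpha1, counts.alpha2)
    # weight = target kernel / proposal kernel = prod (P_c / rho_c)^{k_c}
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = np.sum(kvec * (np.log(cells) - np.log(rho)), axis=-1)
    logw = np.where(np.isnan(logw), -np.inf, logw)  # 0 * (-inf) cells with k_c = 0
    logw -= special.logsumexp(logw)
    w = np.exp(logw)
    ess = float(1.0 / np.sum(w**2))
    if ess < 0.01 * n_prop:
        logger.warning(
            "paired_difference: low importance effective sample size "
            "(ESS=%.1f of %d proposals, %.2f%%); summaries may be noisy",
            ess, n_prop, 100.0 * ess / n_prop,
        )
    idx = rng_res.choice(n_prop, size=n_samples, p=w)
    delta = rho[idx, 1] - rho[idx, 2]
    return DifferenceSamples(delta, seed=seed, mass=mass, ess=ess)
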
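"""Bayesian posterior over population prevalence.

The model: each participant is tested separately with a within-participant
test of false-positive rate ``alpha``.  A participant drawn from the
population carries a detectable effect with probability ``gamma`` (the
population prevalence).  A participant with the effect is significant with
probability 1; one without, with probability ``alpha``.  The probability
that any one participant is significant is therefore

    theta = alpha + gamma * (1 - alpha)

and the number of significant participants ``k`` out of ``n`` is
binomial(n, theta).  With a uniform prior on ``gamma`` the posterior on
``theta`` is Beta(k + 1, n - k + 1) truncated to [alpha, 1]; pushing it
back through the (linear) change of variables gives the prevalence
posterior on [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "TestOutcomes",
    "HpdInterval",
    "PrevalencePosterior",
    "theta_of_gamma",
    "gamma_of_theta",
    "map_estimate",
]


@dataclass(frozen=True)
class TestOutcomes:
    """Summary of a within-participant testing campaign.

    Parameters
    ----------
    k : int
        Number of participants significant on the within-participant test.
    n : int
        Total number of participants tested.
    alpha : float
        False-positive rate of the within-participant test, in (0, 1).
    """

    __test__ = False  # not a test case despite the Test* name

    k: int
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and isinstance(self.n, (int, np.integer))):
            raise TypeError("k and n must be integers")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k must satisfy 0 <= k <= n, got k={self.k}, n={self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class HpdInterval:
    """Highest-posterior-density credible interval for the prevalence."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")
        if not 0.0 < self.mass < 1.0:
            raise ValueError(f"mass must lie in (0, 1), got {self.mass}")

    def as_percent(self) -> tuple[int, int]:
        """Endpoints as integer percentages (nearest integer)."""
        return (round(self.lower * 100.0), round(self.upper * 100.0))


def theta_of_gamma(gamma, alpha):
    """Map prevalence to the per-participant probability of significance."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0.0) or np.any(gamma > 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha + gamma * (1.0 - alpha)


def gamma_of_theta(theta, alpha):
    """Inverse of :func:`theta_of_gamma` on [alpha, 1]."""
    theta = np.asarray(theta, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if np.any(theta < alpha - 1e-12) or np.any(theta > 1.0 + 1e-12):
        raise ValueError("theta must lie in [alpha, 1]")
    return np.clip((theta - alpha) / (1.0 - alpha), 0.0, 1.0)


def map_estimate(outcomes: TestOutcomes) -> float:
    """Maximum a posteriori prevalence: clamp((k/n - alpha)/(1 - alpha), 0, 1)."""
    k, n, alpha = outcomes.k, outcomes.n, outcomes.alpha
    return float(min(max((k / n - alpha) / (1.0 - alpha), 0.0), 1.0))


class PrevalencePosterior:
    """Truncated-beta posterior over the population prevalence.

    All cumulative work goes through the regularized incomplete beta
    function on the theta scale, so densities and quantiles stay accurate
    for large ``n``.
    """

    def __init__(self, outcomes: TestOutcomes):
        self.outcomes = outcomes
        self.a = outcomes.k + 1.0
        self.b = outcomes.n - outcomes.k + 1.0
        self.alpha = outcomes.alpha
        # Posterior mass of the untruncated Beta(a, b) below the truncation
        # bound theta = alpha; the truncated normalizer is 1 - this.
        self._cdf_at_alpha = float(special.betainc(self.a, self.b, self.alpha))
        self._norm = 1.0 - self._cdf_at_alpha
        if self._norm <= 0.0:
            # Only reachable through floating underflow (alpha ~ 1).
            raise FloatingPointError("truncated posterior has vanishing mass")
        self._log_norm = math.log(self._norm)
        self._log_beta = special.betaln(self.a, self.b)

    # -- densities ---------------------------------------------------------

    def logpdf(self, gamma):
        gamma = np.asarray(gamma, dtype=float)
        theta = theta_of_gamma(gamma, self.alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (
                (self.a - 1.0) * np.log(theta)
                + (self.b - 1.0) * np.log1p(-theta)
                - self._log_beta
                - self._log_norm
                + math.log1p(-self.alpha)
            )
        # 0*log(0) conventions at the endpoints
        if self.a == 1.0:
            lp = np.where(theta == 0.0, -self._log_beta - self._log_norm + math.log1p(-self.alpha), lp)
        if self.b == 1.0:
            lp = np.where(theta == 1.0, (self.a - 1.0) * np.log(theta) - self._log_beta - self._log_norm + math.log1p(-self.alpha), lp)
        return lp

    def pdf(self, gamma):
        """Posterior density of the prevalence at ``gamma``."""
        return np.exp(self.logpdf(gamma))

    # -- cumulative --------------------------------------------------------

    def cdf(self, gamma):
        """P(prevalence <= gamma | k, n, alpha)."""
        theta = theta_of_gamma(gamma, self.alpha)
        raw = special.betainc(self.a, self.b, theta)
        return np.clip((raw - self._cdf_at_alpha) / self._norm, 0.0, 1.0)

    def quantile(self, q):
        """Inverse of :meth:`cdf`; accepts scalars or arrays in [0, 1]."""
        q = np.asarray(q, dtype=float)
        if np.any(q < 0.0) or np.any(q > 1.0):
            raise ValueError("q must lie in [0, 1]")
        p_theta = self._cdf_at_alpha + q * self._norm
        theta = special.betaincinv(self.a, self.b, p_theta)
        out = gamma_of_theta(np.clip(theta, self.alpha, 1.0), self.alpha)
        if out.ndim == 0:
            return float(out)
        return out

    ppf = quantile

    # -- point and interval summaries -------------------------------------

    def map(self) -> float:
        return map_estimate(self.outcomes)

    def mean(self) -> float:
        """Posterior mean, by Gauss-Legendre quadrature of gamma * pdf."""
        nodes, weights = np.polynomial.legendre.leggauss(200)
        x = 0.5 * (nodes + 1.0)
        return float(np.sum(0.5 * weights * x * self.pdf(x)))

    def hpdi(self, mass: float = 0.96) -> HpdInterval:
        """Shortest interval containing ``mass`` posterior probability.

        Parameterized by the lower-endpoint cdf value t in [0, 1 - mass]:
        the candidate interval is [quantile(t), quantile(t + mass)] and its
        width is minimized by bounded scalar optimization.  When the mode
        sits at a boundary the interval is one-sided.
        """
        if not 0.0 < mass < 1.0:
            raise ValueError(f"mass must lie in (0, 1), got {mass}")
        k, n = self.outcomes.k, self.outcomes.n
        if k == n:
            # density increasing on [0, 1]; one-sided upper interval
            return HpdInterval(self.quantile(1.0 - mass), 1.0, mass)
        if k / n <= self.alpha:
            # theta-scale mode at the truncation bound; density decreasing
            return HpdInterval(0.0, self.quantile(mass), mass)

        def width(t: float) -> float:
            return self.quantile(t + mass) - self.quantile(t)

        res = optimize.minimize_scalar(
            width, bounds=(0.0, 1.0 - mass), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            raise RuntimeError(f"HPD interval search failed to converge: {res.message}")
        t = float(res.x)
        return HpdInterval(self.quantile(t), self.quantile(t + mass), mass)

    def sample(self, n_samples: int, seed=None) -> np.ndarray:
        """I.i.d. posterior draws by inverse-cdf sampling."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n_samples)
        return np.asarray(self.quantile(u), dtype=float)

    def __repr__(self) -> str:
        o = self.outcomes
        return (
            f"PrevalencePosterior(k={o.k}, n={o.n}, alpha={o.alpha}, "
            f"map={self.map():.4f})"
        )
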
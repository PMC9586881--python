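"""Model / Results interface for prevalence inference.

``PrevalenceModel`` holds the observed within-participant outcomes;
``fit()`` returns a ``PrevalenceResults`` carrying the posterior, point
and interval estimates, frequentist null tests, and a ``summary()`` table.
Difference analyses follow the same pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import HpdInterval, PrevalencePosterior, TestOutcomes, map_estimate
from .diff import (DifferenceSamples, PairedCounts, between_groups_difference,
                   paired_difference)
from .freq import PrevalenceNullResult, global_null_pvalue, prevalence_null_pvalue

__all__ = [
    "PrevalenceModel",
    "PrevalenceResults",
    "PrevalenceDifferenceModel",
    "PairedPrevalenceModel",
    "DifferenceResults",
]

DEFAULT_MASSES = (0.50, 0.96)


class PrevalenceModel:
    """Bayesian population-prevalence model for k-of-n test outcomes.

    Parameters
    ----------
    k : int
        Participants significant on the within-participant test.
    n : int
        Participants tested.
    alpha : float
        False-positive rate of the within-participant test.

    Examples
    --------
    >>> res = PrevalenceModel(10, 20, alpha=0.05).fit()
    >>> round(res.map, 4)
    0.4737
    >>> res.hpdi(0.96).as_percent()
    (25, 70)
    """

    def __init__(self, k: int, n: int, alpha: float = 0.05):
        self.outcomes = TestOutcomes(int(k), int(n), float(alpha))

    @classmethod
    def from_outcomes(cls, outcomes: TestOutcomes) -> "PrevalenceModel":
        return cls(outcomes.k, outcomes.n, outcomes.alpha)

    @classmethod
    def from_pvalues(cls, pvalues: Sequence[float], alpha: float = 0.05) -> "PrevalenceModel":
        """Build from per-participant p-values: k = #{p < alpha}."""
        p = np.asarray(list(pvalues), dtype=float)
        if p.size == 0:
            raise ValueError("need at least one participant")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        return cls(int(np.sum(p < alpha)), int(p.size), alpha)

    @classmethod
    def from_flags(cls, significant: Sequence[int], alpha: float = 0.05) -> "PrevalenceModel":
        """Build from per-participant 0/1 significance flags."""
        f = np.asarray(list(significant))
        if f.size == 0:
            raise ValueError("need at least one participant")
        if not np.isin(f, (0, 1)).all():
            raise ValueError("significance flags must be 0 or 1")
        return cls(int(f.sum()), int(f.size), alpha)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, alpha: float = 0.05) -> "PrevalenceModel":
        """Build from a participant table with a ``p_value`` or
        ``significant`` column (see :func:`prevalence.io.read_participant_table`)."""
        from .io import outcomes_from_dataframe

        return cls.from_outcomes(outcomes_from_dataframe(df, alpha))

    def fit(self, masses: Sequence[float] = DEFAULT_MASSES) -> "PrevalenceResults":
        return PrevalenceResults(self, tuple(masses))


class PrevalenceResults:
    """Fitted prevalence posterior with point, interval and test summaries."""

    def __init__(self, model: PrevalenceModel, masses: Sequence[float] = DEFAULT_MASSES):
        self.model = model
        self.outcomes = model.outcomes
        self.masses = tuple(masses)
        self.posterior = PrevalencePosterior(self.outcomes)
        self.map = map_estimate(self.outcomes)
        self._hpdi: dict[float, HpdInterval] = {}

    def hpdi(self, mass: float = 0.96) -> HpdInterval:
        if mass not in self._hpdi:
            self._hpdi[mass] = self.posterior.hpdi(mass)
        return self._hpdi[mass]

    @property
    def global_null(self) -> PrevalenceNullResult:
        return global_null_pvalue(self.outcomes)

    @property
    def majority_null(self) -> PrevalenceNullResult:
        return prevalence_null_pvalue(self.outcomes, 0.5)

    def prevalence_null(self, gamma0: float) -> PrevalenceNullResult:
        return prevalence_null_pvalue(self.outcomes, gamma0)

    def sample(self, n_samples: int, seed=None) -> np.ndarray:
        return self.posterior.sample(n_samples, seed=seed)

    def to_dict(self) -> dict:
        """Flat, JSON-ready report of the fit."""
        o = self.outcomes
        out = {
            "k": o.k,
            "n": o.n,
            "alpha": o.alpha,
            "map": round(self.map, 4),
            "posterior_mean": round(self.posterior.mean(), 4),
            "neglog10p_global": self.global_null.neg_log10_p,
            "neglog10p_majority": self.majority_null.neg_log10_p,
            "hpdi": {},
        }
        for mass in self.masses:
            h = self.hpdi(mass)
            out["hpdi"][f"{mass:g}"] = {
                "lower": round(h.lower, 4),
                "upper": round(h.upper, 4),
                "percent": list(h.as_percent()),
            }
        return out

    def summary(self) -> str:
        """Plain-text summary table."""
        o = self.outcomes
        lines = [
            "Population Prevalence Inference",
            "=" * 45,
            f"significant participants (k): {o.k:>12d}",
            f"participants tested (n):      {o.n:>12d}",
            f"within-participant alpha:     {o.alpha:>12g}",
            "-" * 45,
            f"MAP prevalence:               {self.map:>12.4f}",
            f"posterior mean:               {self.posterior.mean():>12.4f}",
        ]
        for mass in self.masses:
            h = self.hpdi(mass)
            pct = h.as_percent()
            lines.append(
                f"{100 * mass:.0f}% HPDI:                    "
                f"[{h.lower:.4f}, {h.upper:.4f}]  ({pct[0]}-{pct[1]}%)"
            )
        lines += [
            "-" * 45,
            f"global null    -log10(p):     {self.global_null.neg_log10_p:>12.2f}",
            f"majority null  -log10(p):     {self.majority_null.neg_log10_p:>12.2f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        o = self.outcomes
        return f"<PrevalenceResults k={o.k} n={o.n} alpha={o.alpha} map={self.map:.4f}>"


@dataclass(frozen=True)
class DifferenceResults:
    """Results wrapper around posterior draws of a prevalence difference."""

    samples: DifferenceSamples
    label: str

    @property
    def median(self) -> float:
        return self.samples.median

    @property
    def prob_positive(self) -> float:
        return self.samples.prob_positive

    def interval(self, mass: float | None = None) -> tuple[float, float]:
        return self.samples.interval(mass)

    def to_dict(self) -> dict:
        return {"model": self.label, **self.samples.summary()}

    def summary(self) -> str:
        s = self.samples.summary()
        lines = [
            f"Prevalence Difference ({self.label})",
            "=" * 45,
            f"median delta:                 {s['median']:>12.4f}",
            f"{100 * s['interval_mass']:.0f}% central interval:         "
            f"[{s['interval_lower']:.4f}, {s['interval_upper']:.4f}]",
            f"P(delta > 0):                 {s['prob_delta_positive']:>12.4f}",
            f"posterior draws:              {s['n_samples']:>12d}",
        ]
        if "effective_sample_size" in s:
            lines.append(f"importance ESS:               {s['effective_sample_size']:>12.1f}")
        return "\n".join(lines)


class PrevalenceDifferenceModel:
    """Difference in prevalence between two independent samples."""

    def __init__(self, k_a: int, n_a: int, k_b: int, n_b: int,
                 alpha_a: float = 0.05, alpha_b: float = 0.05):
        self.outcomes_a = TestOutcomes(int(k_a), int(n_a), float(alpha_a))
        self.outcomes_b = TestOutcomes(int(k_b), int(n_b), float(alpha_b))

    def fit(self, n_samples: int = 10000, seed: int = 0, mass: float = 0.96) -> DifferenceResults:
        draws = between_groups_difference(
            self.outcomes_a, self.outcomes_b, n_samples=n_samples, seed=seed, mass=mass
        )
        return DifferenceResults(draws, "between groups")


class PairedPrevalenceModel:
    """Difference in prevalence between two tests on the same participants."""

    def __init__(self, k11: int, k10: int, k01: int, k00: int,
                 alpha1: float = 0.05, alpha2: float = 0.05):
        self.counts = PairedCounts(int(k11), int(k10), int(k01), int(k00),
                                   float(alpha1), float(alpha2))

    def fit(self, n_samples: int = 10000, seed: int = 0, mass: float = 0.96) -> DifferenceResults:
        draws = paired_difference(self.counts, n_samples=n_samples, seed=seed, mass=mass)
        return DifferenceResults(draws, "paired tests")
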
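"""Simulated event-related-potential experiments for prevalence inference.

Each participant contributes ``n_trials`` noisy time courses of
``n_timepoints`` samples.  Participants carrying an effect add, to every
trial, a Gaussian bump in time with a per-participant amplitude ``A_p``
(drawn once, Normal(amplitude_mean, amplitude_sd)) and latency ``L_p``
(Normal(latency_mean, latency_sd), rounded to a valid sample); the rest
are pure Gaussian noise.  Within-participant inference is a one-sample
t-test of trial values against zero at every timepoint, Bonferroni
corrected over time; population-mean inference applies the same test
across participants' trial means.  The within-participant significance
counts feed the prevalence posterior — overall (any-timepoint test, whose
false-positive rate is the family alpha) and per timepoint (where the rate
actually controlled is family_alpha / n_timepoints).

The four shipped scenario presets emulate qualitatively distinct regimes:
signed heterogeneous amplitudes that cancel in the mean (A), a fixed
amplitude at widely variable latency (B), few participants (C), and an
effect confined to half of the population (D).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core import HpdInterval, PrevalencePosterior, TestOutcomes

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "WithinParticipantResult",
    "PopulationMeanResult",
    "PrevalenceTimecourse",
    "simulate_scenario",
    "within_participant_test",
    "population_mean_test",
    "prevalence_timecourse",
    "scenario_presets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for one simulated experiment.

    Signal units are arbitrary; noise_sd sets the scale.  Latencies and
    effect_width are in timepoint samples.
    """

    n_participants: int
    n_trials: int
    n_timepoints: int
    noise_sd: float = 1.0
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.0
    latency_mean: float = 30.0
    latency_sd: float = 0.0
    effect_width: float = 3.0
    effect_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_trials", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if not 0 <= self.latency_mean < self.n_timepoints:
            raise ValueError("latency_mean must lie in [0, n_timepoints)")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedDataset:
    """Participant x trial x timepoint signal array plus ground truth."""

    data: np.ndarray
    has_effect: np.ndarray      # (n_participants,) bool
    amplitudes: np.ndarray      # (n_participants,) A_p; 0 where no effect
    latencies: np.ndarray       # (n_participants,) int L_p; -1 where no effect
    config: ScenarioConfig

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class WithinParticipantResult:
    """Per-participant, per-timepoint one-sample t-tests with Bonferroni."""

    t_values: np.ndarray        # (participants, timepoints)
    p_values: np.ndarray
    significant_mask: np.ndarray
    overall_significant: np.ndarray   # (participants,) any-timepoint flag
    family_alpha: float

    @property
    def n_participants(self) -> int:
        return self.t_values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.t_values.shape[1]

    @property
    def k_overall(self) -> int:
        return int(self.overall_significant.sum())

    def overall_outcomes(self) -> TestOutcomes:
        """Counts for the any-timepoint test; its false-positive rate is the
        family alpha (Bonferroni controls the familywise rate at that level)."""
        return TestOutcomes(self.k_overall, self.n_participants, self.family_alpha)


@dataclass(frozen=True)
class PopulationMeanResult:
    t_values: np.ndarray
    p_values: np.ndarray
    significant_mask: np.ndarray
    family_alpha: float

    @property
    def any_significant(self) -> bool:
        return bool(self.significant_mask.any())


@dataclass(frozen=True)
class PrevalenceTimecourse:
    k: np.ndarray              # significant participants per timepoint
    n: int
    alpha: float               # per-timepoint false-positive rate
    map: np.ndarray
    hpdi_lower: np.ndarray
    hpdi_upper: np.ndarray
    mass: float


def _gaussian_bump(n_timepoints: int, latency: int, width: float) -> np.ndarray:
    t = np.arange(n_timepoints, dtype=float)
    return np.exp(-0.5 * ((t - latency) / width) ** 2)


def simulate_scenario(config: ScenarioConfig) -> SimulatedDataset:
    """Generate one experiment; bit-reproducible given the config seed."""
    rng = np.random.default_rng(config.seed)
    p, tr, s = config.n_participants, config.n_trials, config.n_timepoints

    n_effect = round(config.effect_fraction * p)
    has_effect = np.zeros(p, dtype=bool)
    has_effect[:n_effect] = True

    amplitudes = np.zeros(p)
    latencies = np.full(p, -1, dtype=int)
    amplitudes[:n_effect] = rng.normal(config.amplitude_mean, config.amplitude_sd, size=n_effect)
    raw_lat = rng.normal(config.latency_mean, config.latency_sd, size=n_effect)
    lat = np.rint(raw_lat).astype(int)
    clipped = (lat < 0) | (lat > s - 1)
    if clipped.any():
        logger.warning(
            "simulate_scenario: clipped %d of %d latency draws to [0, %d]",
            int(clipped.sum()), n_effect, s - 1,
        )
    latencies[:n_effect] = np.clip(lat, 0, s - 1)

    data = rng.normal(0.0, config.noise_sd, size=(p, tr, s))
    for i in range(n_effect):
        data[i] += amplitudes[i] * _gaussian_bump(s, latencies[i], config.effect_width)
    return SimulatedDataset(data, has_effect, amplitudes, latencies, config)


def _ttest_vs_zero(values: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t-test against 0; zero-variance cells get p = 1."""
    degenerate = values.var(axis=axis) == 0.0
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(values, 0.0, axis=axis)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    bad = degenerate | ~np.isfinite(p)
    if bad.any():
        logger.warning("t-test: %d cells with zero variance; p set to 1", int(bad.sum()))
        p = np.where(bad, 1.0, p)
        t = np.where(bad | ~np.isfinite(t), 0.0, t)
    return t, p


def within_participant_test(dataset: SimulatedDataset, family_alpha: float = 0.05) -> WithinParticipantResult:
    """Per-timepoint t-tests within each participant, Bonferroni over time."""
    if dataset.data.shape[1] < 2:
        raise ValueError("need at least 2 trials per participant")
    t, p = _ttest_vs_zero(dataset.data, axis=1)
    threshold = family_alpha / dataset.data.shape[2]
    mask = p < threshold
    return WithinParticipantResult(t, p, mask, mask.any(axis=1), family_alpha)


def population_mean_test(dataset: SimulatedDataset, family_alpha: float = 0.05) -> PopulationMeanResult:
    """Per-timepoint t-tests of participant trial means, Bonferroni over time."""
    if dataset.data.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    trial_means = dataset.data.mean(axis=1)
    t, p = _ttest_vs_zero(trial_means, axis=0)
    mask = p < family_alpha / dataset.data.shape[2]
    return PopulationMeanResult(t, p, mask, family_alpha)


def prevalence_timecourse(results: WithinParticipantResult, mass: float = 0.96) -> PrevalenceTimecourse:
    """Prevalence posterior summaries at every timepoint.

    The per-timepoint test is applied at family_alpha / n_timepoints, so
    that is the false-positive rate entering the prevalence model here.
    """
    alpha = results.family_alpha / results.n_timepoints
    k_t = results.significant_mask.sum(axis=0)
    n = results.n_participants
    cache: dict[int, tuple[float, HpdInterval]] = {}
    maps = np.empty(results.n_timepoints)
    lo = np.empty(results.n_timepoints)
    hi = np.empty(results.n_timepoints)
    for t, k in enumerate(k_t):
        k = int(k)
        if k not in cache:
            post = PrevalencePosterior(TestOutcomes(k, n, alpha))
            cache[k] = (post.map(), post.hpdi(mass))
        m, h = cache[k]
        maps[t], lo[t], hi[t] = m, h.lower, h.upper
    return PrevalenceTimecourse(k_t, n, alpha, maps, lo, hi, mass)


def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named scenario configurations.

    ``A``: signed, highly variable amplitudes (mean 0) at a consistent
    latency — individual effects are strong but cancel in the population
    mean.  ``B``: fixed amplitude, widely variable latency — every
    participant shows the effect somewhere, but misalignment washes the
    mean out.  ``C``: five participants with moderate amplitude
    variability.  ``D``: an effect confined to half of twenty
    participants.
    """
    common = dict(n_trials=100, n_timepoints=60, noise_sd=1.0,
                  latency_mean=30.0, effect_width=3.0)
    return {
        "A": ScenarioConfig(n_participants=20, amplitude_mean=0.0,
                            amplitude_sd=1.5, latency_sd=1.0,
                            effect_fraction=1.0, **common),
        "B": ScenarioConfig(n_participants=20, amplitude_mean=1.0,
                            amplitude_sd=0.0, latency_sd=15.0,
                            effect_fraction=1.0, **common),
        "C": ScenarioConfig(n_participants=5, amplitude_mean=1.0,
                            amplitude_sd=0.5, latency_sd=1.0,
                            effect_fraction=1.0, **common),
        "D": ScenarioConfig(n_participants=20, amplitude_mean=1.2,
                            amplitude_sd=0.0, latency_sd=8.0,
                            effect_fraction=0.5, **common),
    }
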
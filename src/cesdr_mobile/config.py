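"""Configuration objects for the synthetic EMA cohort and the pipeline.

``CohortConfig`` holds the generative parameters of a simulated two-week
daily diary study: a latent depression severity per participant, a
two-parameter logistic link from severity to each item's daily Yes
probability, and a response-latency model with item means, a person speed
offset, Gaussian trial noise and a concave ("inverted-U") component in the
participant's expected total score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError


def _default_difficulty(n_items: int) -> np.ndarray:
    # Wide difficulty spread with mostly hard-to-endorse items: a
    # non-clinical cohort endorses few symptoms (right-skewed totals), and
    # the hardest items stay unendorsed even at severe latent severity,
    # keeping expected totals in the range where the latency curve is
    # physically sensible (predicted latencies stay positive).
    return np.linspace(0.8, 4.0, n_items)


def _default_item_rt_means(n_items: int) -> np.ndarray:
    # Spread of per-item mean latencies (ms) standing in for item length
    # and vocabulary-level effects; baselines large enough that the concave
    # severity component rarely drives predicted latencies to the floor.
    return np.linspace(2400.0, 4000.0, n_items)


@dataclass
class CohortConfig:
    """Generative parameters for :func:`cesdr_mobile.simulate.simulate_cohort`.

    Parameters
    ----------
    n_participants, n_items, n_days
        Cohort dimensions. Defaults mirror a 70-person, 20-item,
        14-day daily-diary design.
    severity_mean, severity_sd
        Latent severity theta is drawn Normal(severity_mean, severity_sd).
    item_difficulty, item_discrimination
        Per-item 2PL parameters b_i and a_i; daily Yes probability is
        logistic(a_i * (theta - b_i)).
    rt_item_mean
        Per-item mean latency mu_i in milliseconds.
    rt_person_sd
        SD of the person speed offset delta_p (ms), shared by all of a
        participant's responses.
    rt_noise_sd
        SD of independent trial noise epsilon (ms).
    rt_quad_height, rt_quad_center, rt_quad_curvature
        Concave severity->latency component
        f(T) = rt_quad_height - rt_quad_curvature * (T - rt_quad_center)**2
        evaluated at the participant's expected total score. Positive
        curvature gives the inverted-U; zero removes the link entirely.
    miss_prob
        Marginal probability that a daily session is missed.
    mnar_slope
        Severity dependence of missingness on the logit scale (0 = MCAR;
        positive values make more-severe participants miss more days).
    seed
        Seed for all randomness in the generator.
    """

    n_participants: int = 70
    n_items: int = 20
    n_days: int = 14
    severity_mean: float = 0.0
    severity_sd: float = 1.0
    item_difficulty: Optional[Sequence[float]] = None
    item_discrimination: Optional[Sequence[float]] = None
    rt_item_mean: Optional[Sequence[float]] = None
    rt_person_sd: float = 300.0
    rt_noise_sd: float = 600.0
    rt_quad_height: float = 400.0
    rt_quad_center: float = 8.0
    rt_quad_curvature: float = 2.0
    miss_prob: float = 0.1
    mnar_slope: float = 0.0
    rt_floor_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_items", "n_days"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("severity_sd", "rt_person_sd", "rt_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ConfigurationError(f"miss_prob must lie in [0, 1], got {self.miss_prob!r}")
        if self.rt_floor_ms <= 0:
            raise ConfigurationError(f"rt_floor_ms must be positive, got {self.rt_floor_ms!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

        if self.item_difficulty is None:
            self.item_difficulty = _default_difficulty(self.n_items)
        self.item_difficulty = np.asarray(self.item_difficulty, dtype=float)
        if self.item_difficulty.shape != (self.n_items,):
            raise ConfigurationError(
                f"item_difficulty must have length n_items={self.n_items}, "
                f"got shape {self.item_difficulty.shape}"
            )

        if self.item_discrimination is None:
            self.item_discrimination = np.full(self.n_items, 2.0)
        self.item_discrimination = np.asarray(self.item_discrimination, dtype=float)
        if self.item_discrimination.shape != (self.n_items,):
            raise ConfigurationError(
                f"item_discrimination must have length n_items={self.n_items}, "
                f"got shape {self.item_discrimination.shape}"
            )
        if np.any(self.item_discrimination <= 0):
            raise ConfigurationError("item_discrimination entries must be positive")

        if self.rt_item_mean is None:
            self.rt_item_mean = _default_item_rt_means(self.n_items)
        self.rt_item_mean = np.asarray(self.rt_item_mean, dtype=float)
        if self.rt_item_mean.shape != (self.n_items,):
            raise ConfigurationError(
                f"rt_item_mean must have length n_items={self.n_items}, "
                f"got shape {self.rt_item_mean.shape}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("item_difficulty", "item_discrimination", "rt_item_mean"):
            d[key] = np.asarray(d[key]).tolist()
        return d


@dataclass
class ScoringConfig:
    """Adherence and risk thresholds for the conversion algorithm."""

    min_days: int = 7
    cutoff: int = 13

    def __post_init__(self) -> None:
        if not isinstance(self.min_days, (int, np.integer)) or self.min_days < 1:
            raise ConfigurationError(f"min_days must be >= 1, got {self.min_days!r}")
        if not (0 <= self.cutoff <= 80):
            raise ConfigurationError(f"cutoff must lie in 0..80, got {self.cutoff!r}")


@dataclass
class PipelineConfig:
    """Full pipeline configuration: cohort generator, scoring thresholds,
    latency winsorizing cap and model alpha."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    winsorize_ms: Optional[float] = None
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.winsorize_ms is not None and self.winsorize_ms <= 0:
            raise ConfigurationError(f"winsorize_ms must be positive, got {self.winsorize_ms!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        cohort = CohortConfig(**raw.pop("cohort", {}))
        scoring = ScoringConfig(**raw.pop("scoring", {}))
        known = {"winsorize_ms", "alpha", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(cohort=cohort, scoring=scoring, **raw)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "scoring": asdict(self.scoring),
            "winsorize_ms": self.winsorize_ms,
            "alpha": self.alpha,
            "log_level": self.log_level,
        }
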
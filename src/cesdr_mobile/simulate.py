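"""Synthetic EMA cohort generator.

Emulates a two-week daily binary symptom diary: a latent severity theta_p
per participant, a 2PL logistic link from severity to each item's daily Yes
probability, day-level missingness (optionally severity-dependent, i.e.
MNAR), and response latencies

    rt = mu_item + delta_person + f(T_hat_p) + epsilon,
    f(T) = height - curvature * (T - center)^2,

where T_hat_p is the participant's *expected* total converted score under
theta_p, so the concave latency component lives on the same axis the
downstream regression uses. All draws are controlled by a single seed.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binom

from .config import CohortConfig
from .scoring import bin_item_scores

_SECONDS_PER_DAY = 86_400.0
_WINDOW_SECONDS = 6 * 3600.0  # +/- 6 h completion window around the daily anchor

SESSION_COLUMNS = ["participant_id", "day_index", "timestamp", "item_id", "response", "rt_ms"]


def _participant_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"P{i + 1:0{width}d}" for i in range(n)])


def yes_probabilities(theta: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Daily Yes probability per (participant, item): logistic(a_i*(theta-b_i))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    a = config.item_discrimination
    b = config.item_difficulty
    return expit(a[None, :] * (theta[:, None] - b[None, :]))


def expected_total_score(theta: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Expected converted total score T_hat for participants with severity theta.

    Assumes full adherence (P = n_days completed days): each item's Yes count
    is Binomial(n_days, pi_i), and the expectation of its 0-4 converted score
    is taken over that distribution, then summed over items.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    p_days = config.n_days
    pi = yes_probabilities(theta, config)  # (n_p, n_items)
    q = np.arange(p_days + 1)
    bin_values = bin_item_scores(q / p_days)  # (p_days+1,)
    pmf = binom.pmf(q[None, None, :], p_days, pi[:, :, None])  # (n_p, n_items, p_days+1)
    return (pmf * bin_values).sum(axis=2).sum(axis=1)


def _completion_probability(theta: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Per-day session completion probability for each participant.

    MCAR when mnar_slope == 0 (constant 1 - miss_prob); with positive slope
    the miss probability rises with standardised severity on the logit scale,
    mimicking symptom-dependent nonresponse.
    """
    if config.miss_prob == 0.0:
        return np.ones_like(theta)
    if config.miss_prob == 1.0:
        return np.zeros_like(theta)
    if config.mnar_slope == 0.0 or config.severity_sd == 0.0:
        return np.full_like(theta, 1.0 - config.miss_prob)
    z = (theta - config.severity_mean) / config.severity_sd
    p_miss = expit(logit(config.miss_prob) + config.mnar_slope * z)
    return 1.0 - p_miss


def simulate_cohort(config: CohortConfig) -> Tuple[pd.DataFrame, Dict]:
    """Generate one synthetic cohort.

    Returns
    -------
    records : DataFrame
        Long-format session records with columns
        participant_id, day_index, timestamp, item_id, response, rt_ms;
        one row per answered item, missed days absent.
    truth : dict
        Sidecar with the generative truth needed for recovery tests:
        per-participant theta, delta, expected total, f value, and the
        latency-curve parameters.
    """
    rng = np.random.default_rng(config.seed)
    n_p, n_d, n_i = config.n_participants, config.n_days, config.n_items
    pids = _participant_ids(n_p)

    theta = rng.normal(config.severity_mean, config.severity_sd, n_p)
    completion_p = _completion_probability(theta, config)
    completed = rng.random((n_p, n_d)) < completion_p[:, None]

    pi = yes_probabilities(theta, config)
    responses = rng.random((n_p, n_d, n_i)) < pi[:, None, :]

    t_hat = expected_total_score(theta, config)
    f_val = config.rt_quad_height - config.rt_quad_curvature * (t_hat - config.rt_quad_center) ** 2
    delta = rng.normal(0.0, config.rt_person_sd, n_p)
    noise = rng.normal(0.0, config.rt_noise_sd, (n_p, n_d, n_i))
    rt = config.rt_item_mean[None, None, :] + (delta + f_val)[:, None, None] + noise
    rt = np.maximum(rt, config.rt_floor_ms)

    jitter = rng.uniform(-_WINDOW_SECONDS, _WINDOW_SECONDS, (n_p, n_d))
    timestamps = np.arange(1, n_d + 1)[None, :] * _SECONDS_PER_DAY + jitter

    p_idx, d_idx = np.nonzero(completed)
    n_sessions = len(p_idx)
    item_ids = np.tile(np.arange(1, n_i + 1), n_sessions)
    records = pd.DataFrame(
        {
            "participant_id": np.repeat(pids[p_idx], n_i),
            "day_index": np.repeat(d_idx + 1, n_i),
            "timestamp": np.repeat(timestamps[p_idx, d_idx], n_i),
            "item_id": item_ids,
            "response": responses[p_idx[:, None], d_idx[:, None], :].reshape(-1).astype(int),
            "rt_ms": rt[p_idx[:, None], d_idx[:, None], :].reshape(-1),
        },
        columns=SESSION_COLUMNS,
    )

    truth = {
        "participant_id": pids.tolist(),
        "theta": theta.tolist(),
        "delta": delta.tolist(),
        "expected_total": t_hat.tolist(),
        "f_value": f_val.tolist(),
        "completed_days": completed.sum(axis=1).astype(int).tolist(),
        "rt_quad_height": config.rt_quad_height,
        "rt_quad_center": config.rt_quad_center,
        "rt_quad_curvature": config.rt_quad_curvature,
        "config": config.to_dict(),
    }
    return records, truth


# Auxiliary-scale ranges: retrospective 5-point total, QIDS-SR-like, PHQ-9-like.
AUX_RANGES = {"standard_total": 80.0, "kqids_total": 26.0, "phq9_total": 27.0}


def simulate_auxiliary_scales(
    truth: Dict,
    config: CohortConfig,
    noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-participant totals on concurrent depression scales.

    Each total is a strictly monotone transform of the latent severity plus
    Gaussian noise, clipped to its scale range; totals are kept real-valued
    so the noiseless map is tie-free. The retrospective 5-point total reuses
    the expected converted total (same 0-80 metric as the mobile total).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd!r}")
    rng = np.random.default_rng(config.seed + 10_007)
    theta = np.asarray(truth["theta"], dtype=float)
    t_hat = np.asarray(truth["expected_total"], dtype=float)
    n = len(theta)

    standard = np.clip(t_hat + rng.normal(0.0, noise_sd, n), 0.0, AUX_RANGES["standard_total"])
    kqids = np.clip(
        AUX_RANGES["kqids_total"] * expit(0.8 * theta - 0.5) + rng.normal(0.0, noise_sd, n),
        0.0,
        AUX_RANGES["kqids_total"],
    )
    phq9 = np.clip(
        AUX_RANGES["phq9_total"] * expit(0.8 * theta - 0.8) + rng.normal(0.0, noise_sd, n),
        0.0,
        AUX_RANGES["phq9_total"],
    )
    return pd.DataFrame(
        {
            "participant_id": truth["participant_id"],
            "standard_total": standard,
            "kqids_total": kqids,
            "phq9_total": phq9,
        }
    )
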
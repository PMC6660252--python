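"""Trial speed ratios, trial filtering, speed normalization and task outcomes.

A trial's speed is the straight-line target distance divided by the movement
time (MoveOnset to HitTarget), expressed as a ratio to the subject's
calibration speed and clipped to [0, 1].  For modeling, the ratios of all
completed, unperturbed trials are mapped to a standard normal scale by
z-scoring their natural logarithms (sample standard deviation).  Decoded
speeds are mapped back to the ratio scale with the stored constants and turned
into task outcomes using the instructed-speed windows: a fast trial is correct
when the ratio falls within 66.7 ± 13.3% of calibration, a slow trial within
33.3 ± 13.3% (endpoints inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAST_WINDOW = (0.534, 0.800)
SLOW_WINDOW = (0.200, 0.466)


class BehaviorError(ValueError):
    pass


@dataclass(frozen=True)
class SpeedNormalization:
    """Constants of the log-z speed transform over the modeled trials."""

    log_mean: float
    log_sd: float

    def __post_init__(self):
        if not self.log_sd > 0:
            raise BehaviorError("log_sd must be positive")


def compute_trial_speed(target_distance: float, move_onset: float,
                        hit_target: float, calibration_speed: float) -> float:
    """Speed ratio in [0, 1]: (distance/movement time)/calibration, clipped at 1."""
    duration = hit_target - move_onset
    if duration <= 0:
        raise BehaviorError(f"non-positive movement duration {duration}")
    if calibration_speed <= 0:
        raise BehaviorError(f"non-positive calibration speed {calibration_speed}")
    return min((target_distance / duration) / calibration_speed, 1.0)


def filter_trials(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Completed, unperturbed trials (the modeled subset of size T_n)."""
    keep = trial_table[trial_table["completed"] & ~trial_table["perturbed"]]
    if len(keep) == 0:
        raise BehaviorError("no completed, unperturbed trials remain")
    logger.info("modeling %d of %d trials (T_n)", len(keep), len(trial_table))
    return keep.copy()


def normalize_speeds(ratios: np.ndarray) -> tuple[np.ndarray, SpeedNormalization]:
    """z-score of ln(ratio) using the sample standard deviation (N−1)."""
    r = np.asarray(ratios, dtype=np.float64)
    if r.size < 3:
        raise BehaviorError(f"need at least 3 trials, got {r.size}")
    if np.any(r <= 0) or np.any(r > 1):
        raise BehaviorError("speed ratios must lie in (0, 1]")
    logr = np.log(r)
    mu = float(logr.mean())
    sd = float(logr.std(ddof=1))
    if sd == 0:
        raise BehaviorError("zero variance of log speed ratios")
    norm = SpeedNormalization(log_mean=mu, log_sd=sd)
    return (logr - mu) / sd, norm


def denormalize_speed(y, norm: SpeedNormalization) -> np.ndarray:
    """Inverse transform back to the [0, 1] ratio scale (clipped)."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise BehaviorError("non-finite normalized speed")
    return np.clip(np.exp(y * norm.log_sd + norm.log_mean), 0.0, 1.0)


def classify_outcome(ratio: float, instruction: str) -> str:
    """'correct' when the ratio sits inside the instructed-speed window."""
    if not 0 <= ratio <= 1:
        raise BehaviorError(f"ratio {ratio} outside [0, 1]")
    if instruction == "fast":
        lo, hi = FAST_WINDOW
    elif instruction == "slow":
        lo, hi = SLOW_WINDOW
    else:
        raise BehaviorError(f"unknown instruction {instruction!r}")
    return "correct" if lo <= ratio <= hi else "incorrect"


def build_trial_speed_table(trial_table: pd.DataFrame
                            ) -> tuple[pd.DataFrame, SpeedNormalization]:
    """Modeled-trial table with ratio, normalized speed and actual outcome.

    Ratios are recomputed from the event times; trials with a ratio of exactly
    0 cannot be log-transformed and are dropped with a warning.
    """
    modeled = filter_trials(trial_table)
    ratios = np.array([
        compute_trial_speed(row.target_distance, row.move_onset, row.hit_target,
                            row.calibration_speed)
        for row in modeled.itertuples()
    ])
    if np.any(ratios == 0):
        n0 = int((ratios == 0).sum())
        logger.warning("dropping %d trial(s) with zero speed ratio", n0)
        modeled = modeled[ratios > 0]
        ratios = ratios[ratios > 0]
    y, norm = normalize_speeds(ratios)
    out = pd.DataFrame({
        "trial_id": modeled["trial_id"].to_numpy(),
        "speed_ratio": ratios,
        "normalized_speed": y,
        "instruction": modeled["instruction"].to_numpy(),
        "actual_outcome": [classify_outcome(r, i)
                           for r, i in zip(ratios, modeled["instruction"])],
    })
    return out, norm
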
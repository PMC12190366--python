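"""Time-pressure calibration: RT preprocessing and available-time computation.

Time pressure in the BS paradigm is set through the ratio of required time
(RT, the mean reaction time measured without any response deadline) to
available time (AT, the response deadline): a ratio of 0.8 produces a felt
sense of time pressure, so AT = 1.25 x mean RT, rounded to a 100 ms quantum.

Preprocessing is a one-shot three-stage sweep over unlimited-time sessions:

1. drop incorrect trials per participant;
2. drop trials outside mean +/- 3 SD within each (participant, condition)
   cell, using the cell's pre-removal mean/SD in a single pass;
3. drop whole participants whose per-condition mean falls outside the group
   mean +/- 3 SD for any condition.

SDs are sample SDs (n-1 denominator) at both levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ("participant_id", "condition", "rt_ms", "correct")

#: Default multiplier on mean required time (RT/AT = 0.8).
DEFAULT_PRESSURE_FACTOR = 1.25

#: Default rounding quantum for available times, ms.
DEFAULT_ROUNDING_QUANTUM_MS = 100


@dataclass
class CalibrationResult:
    """Per-condition required/available times plus the exclusion audit trail."""

    mean_rt_ms: dict[int, float]
    available_time_ms: dict[int, int]
    pressure_factor: float = DEFAULT_PRESSURE_FACTOR
    rounding_quantum_ms: int = DEFAULT_ROUNDING_QUANTUM_MS
    n_participants_input: int = 0
    n_participants_retained: int = 0
    excluded_participants: list = field(default_factory=list)
    n_trials_removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_rt_ms": {str(k): v for k, v in self.mean_rt_ms.items()},
            "available_time_ms": {str(k): v for k, v in self.available_time_ms.items()},
            "pressure_factor": self.pressure_factor,
            "rounding_quantum_ms": self.rounding_quantum_ms,
            "n_participants_input": self.n_participants_input,
            "n_participants_retained": self.n_participants_retained,
            "excluded_participants": list(self.excluded_participants),
            "n_trials_removed": dict(self.n_trials_removed),
        }


def _check_frame(observations: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"observations missing columns {missing}")
    if len(observations) and (observations["rt_ms"] <= 0).any():
        raise ValueError("rt_ms must be positive")


def filter_correct(observations: pd.DataFrame) -> pd.DataFrame:
    """Keep only correct trials, preserving order."""
    _check_frame(observations)
    return observations.loc[observations["correct"].astype(bool)].copy()


def remove_trial_outliers(observations: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Single-pass 3 SD trial rejection within each (participant, condition) cell.

    Bounds use each cell's pre-removal mean and sample SD.  Singleton cells
    (SD undefined) are retained unchanged with a warning.
    """
    _check_frame(observations)
    if observations.empty:
        return observations.copy()
    keep = pd.Series(True, index=observations.index)
    for (pid, cond), cell in observations.groupby(["participant_id", "condition"], sort=False):
        if len(cell) < 2:
            warnings.warn(
                f"singleton RT cell (participant={pid!r}, condition={cond}): retained, SD undefined",
                stacklevel=2,
            )
            continue
        mean = cell["rt_ms"].mean()
        sd = cell["rt_ms"].std(ddof=1)
        keep.loc[cell.index] = (cell["rt_ms"] - mean).abs() <= n_sd * sd
    return observations.loc[keep].copy()


def participant_condition_means(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per (participant, condition), one row per pair."""
    _check_frame(observations)
    out = (
        observations.groupby(["participant_id", "condition"], sort=True)["rt_ms"]
        .mean()
        .reset_index()
        .rename(columns={"rt_ms": "mean_rt_ms"})
    )
    return out


def remove_group_outliers(
    means: pd.DataFrame, n_sd: float = 3.0
) -> tuple[pd.DataFrame, list]:
    """Participant-wise group-level exclusion.

    A participant is dropped entirely if any of their condition means falls
    outside the group's mean +/- 3 SD for that condition.  Returns the
    retained mean table and the list of excluded participant ids.
    """
    if "mean_rt_ms" not in means.columns:
        raise ValueError("expected a per-(participant, condition) mean table with column 'mean_rt_ms'")
    n_participants = means["participant_id"].nunique()
    if n_participants < 2:
        raise ValueError("group-level outlier removal needs at least 2 participants")
    excluded: set = set()
    for cond, cell in means.groupby("condition", sort=True):
        mean = cell["mean_rt_ms"].mean()
        sd = cell["mean_rt_ms"].std(ddof=1)
        flagged = cell.loc[(cell["mean_rt_ms"] - mean).abs() > n_sd * sd, "participant_id"]
        excluded.update(flagged.tolist())
    retained = means.loc[~means["participant_id"].isin(excluded)].copy()
    return retained, sorted(excluded)


def compute_available_time(
    mean_rt_ms: float,
    pressure_factor: float = DEFAULT_PRESSURE_FACTOR,
    rounding_quantum_ms: int = DEFAULT_ROUNDING_QUANTUM_MS,
) -> int:
    """AT = pressure_factor x mean RT, rounded to the nearest quantum (half-up).

    With the defaults, a condition whose unlimited-time mean RT is 1815.63 ms
    gets a 2300 ms deadline (1.25 x 1815.63 = 2269.5 -> nearest 100).
    """
    if mean_rt_ms <= 0:
        raise ValueError(f"mean_rt_ms must be positive, got {mean_rt_ms}")
    if pressure_factor <= 0:
        raise ValueError(f"pressure_factor must be positive, got {pressure_factor}")
    if rounding_quantum_ms <= 0:
        raise ValueError(f"rounding_quantum_ms must be positive, got {rounding_quantum_ms}")
    raw = pressure_factor * mean_rt_ms
    return int(math.floor(raw / rounding_quantum_ms + 0.5)) * rounding_quantum_ms


def calibrate(
    observations: pd.DataFrame,
    pressure_factor: float = DEFAULT_PRESSURE_FACTOR,
    rounding_quantum_ms: int = DEFAULT_ROUNDING_QUANTUM_MS,
    n_sd: float = 3.0,
) -> CalibrationResult:
    """Full calibration pipeline on unlimited-response-time observations.

    filter_correct -> remove_trial_outliers -> per-participant condition means
    -> remove_group_outliers -> group condition means -> available time per
    condition.  The result records how much each stage removed.
    """
    _check_frame(observations)
    n_input = observations["participant_id"].nunique()
    correct = filter_correct(observations)
    trimmed = remove_trial_outliers(correct, n_sd=n_sd)
    means = participant_condition_means(trimmed)
    retained_means, excluded = remove_group_outliers(means, n_sd=n_sd)
    group_means = retained_means.groupby("condition", sort=True)["mean_rt_ms"].mean()
    available = {
        int(cond): compute_available_time(m, pressure_factor, rounding_quantum_ms)
        for cond, m in group_means.items()
    }
    return CalibrationResult(
        mean_rt_ms={int(c): float(m) for c, m in group_means.items()},
        available_time_ms=available,
        pressure_factor=pressure_factor,
        rounding_quantum_ms=rounding_quantum_ms,
        n_participants_input=n_input,
        n_participants_retained=retained_means["participant_id"].nunique(),
        excluded_participants=excluded,
        n_trials_removed={
            "incorrect": int(len(observations) - len(correct)),
            "trial_outliers": int(len(correct) - len(trimmed)),
        },
    )
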
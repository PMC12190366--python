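"""Validated session configuration for the three protocols.

Defaults encode the published task parameters: 8-block / 8-scored-trial
workload-comparison sessions with 20 s rests, a 30-minute 6-block fatigue
induction run with VAS after every block and a 3-minute PVT before and after,
condition deadlines of 2300/3000/2600/2800 ms, 500 ms ISI feedback, and a 90%
practice accuracy gate.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

#: Calibrated response deadlines (ms) per condition.
DEFAULT_AVAILABLE_TIMES: dict[int, float] = {1: 2300.0, 2: 3000.0, 3: 2600.0, 4: 2800.0}


class VasSchedule(BaseModel):
    pre_first_block: bool = True
    after_each_block: bool = True


class SessionConfig(BaseModel):
    """Parameters for one headless session run."""

    protocol: Literal["hmw_blocks", "tot_induction", "pvt"]
    block_count: int = Field(ge=1)
    per_block_counts: Optional[dict[int, int]] = None
    block_duration_ms: Optional[float] = Field(default=None, gt=0)
    rest_duration_ms: float = Field(default=20_000.0, ge=0)
    isi_feedback_ms: float = Field(default=500.0, ge=0)
    lead_in_exposure_ms: float = Field(default=1000.0, ge=0)
    practice_accuracy_gate: float = Field(default=0.90, ge=0.0, le=1.0)
    available_times: Optional[dict[int, float]] = None
    vas_schedule: VasSchedule = Field(default_factory=VasSchedule)
    pvt_duration_ms: float = Field(default=180_000.0, gt=0)
    pvt_interval_bounds: tuple[float, float] = (2000.0, 10_000.0)
    max_run_length: int = Field(default=4, ge=1)
    count_no_response_as_error: bool = True
    task_order: tuple[str, ...] = ("bs", "2back")
    twoback_letter_ms: float = 500.0
    twoback_blank_ms: float = 2000.0

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        lo, hi = self.pvt_interval_bounds
        if lo > hi:
            raise ValueError("pvt_interval_bounds must be ordered")
        if self.protocol == "tot_induction" and self.block_duration_ms is None:
            raise ValueError("tot_induction requires block_duration_ms")
        if self.protocol == "hmw_blocks" and self.per_block_counts is None:
            raise ValueError("hmw_blocks requires per_block_counts")
        return self


def tot_config(**overrides) -> SessionConfig:
    """The 30-minute fatigue-induction protocol: 6 five-minute blocks."""
    base = dict(
        protocol="tot_induction",
        block_count=6,
        block_duration_ms=300_000.0,
        available_times=dict(DEFAULT_AVAILABLE_TIMES),
    )
    base.update(overrides)
    return SessionConfig(**base)


def hmw_config(**overrides) -> SessionConfig:
    """The workload-comparison protocol: 8 blocks x 8 scored trials per task."""
    base = dict(
        protocol="hmw_blocks",
        block_count=8,
        per_block_counts={1: 2, 2: 2, 3: 2, 4: 2},
        available_times=dict(DEFAULT_AVAILABLE_TIMES),
    )
    base.update(overrides)
    return SessionConfig(**base)


def pvt_config(**overrides) -> SessionConfig:
    """A standalone 3-minute psychomotor vigilance run."""
    base = dict(protocol="pvt", block_count=1)
    base.update(overrides)
    return SessionConfig(**base)
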
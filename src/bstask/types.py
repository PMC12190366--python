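"""Core domain objects for the 1-back Stroop (BS) task engine.

The BS paradigm crosses a spatial 1-back judgment (does the current stimulus
occupy the same cell of a 3x3 grid as the previous one?) with a color-word
Stroop judgment (does the word's meaning match its ink color?).  The four
resulting conditions share one of two response keys, so the required key is a
function of the XNOR of the two judgments.

Hot-path objects (:class:`Trial`, :class:`ResponseRecord`, :class:`PVTTrial`)
are slotted dataclasses; configuration objects live in :mod:`bstask.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The four ink colors / word meanings of the Stroop component.
COLORS: tuple[str, ...] = ("red", "yellow", "blue", "green")

#: Front-end rendering table: color identity -> Chinese character.
COLOR_CHARACTERS: dict[str, str] = {
    "red": "红",     # 红
    "yellow": "黄",  # 黄
    "blue": "蓝",    # 蓝
    "green": "绿",   # 绿
}

#: Number of cells in the 3x3 stimulus grid (0-based, row-major indexing).
N_GRID_CELLS = 9

#: The four VAS self-report items administered around each task block.
VAS_ITEMS: tuple[str, ...] = ("mental_fatigue", "mental_effort", "mental_stress", "boredom")

#: The six NASA-TLX workload dimensions, each scored 0-20.
TLX_DIMENSIONS: tuple[str, ...] = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)

FEEDBACK_CORRECT = "√"      # √
FEEDBACK_INCORRECT = "×"    # ×
FEEDBACK_NO_RESPONSE = "–"  # –
FEEDBACK_SYMBOLS = (FEEDBACK_CORRECT, FEEDBACK_INCORRECT, FEEDBACK_NO_RESPONSE)


@dataclass(frozen=True, slots=True)
class StimulusSpec:
    """One trial's display content.

    ``word`` stores the color identity; a front-end renders it as the
    corresponding Chinese character (see :data:`COLOR_CHARACTERS`).
    """

    grid_cell: int
    ink_color: str
    word: str

    def __post_init__(self) -> None:
        if not (0 <= self.grid_cell < N_GRID_CELLS):
            raise ValueError(f"grid_cell must be in [0, {N_GRID_CELLS - 1}], got {self.grid_cell}")
        if self.ink_color not in COLORS:
            raise ValueError(f"unknown ink_color {self.ink_color!r}")
        if self.word not in COLORS:
            raise ValueError(f"unknown word {self.word!r}")


@dataclass(frozen=True, slots=True)
class Trial:
    """A realized trial: stimulus plus latent flags and derived condition.

    The first trial of a sequence (or of a block) is an unscored lead-in: it
    has no 1-back referent, so ``back_consistent`` and ``condition`` are
    ``None`` and ``scored`` is False.
    """

    index: int
    stimulus: StimulusSpec
    back_consistent: Optional[bool]
    stroop_congruent: bool
    condition: Optional[int]
    available_time_ms: Optional[float]
    scored: bool


@dataclass(frozen=True, slots=True)
class KeyMapping:
    """Counterbalanced response mapping.

    Variant A answers conditions 1-2 with "F" and 3-4 with "J"; variant B is
    the swap.
    """

    variant: str
    same_key: str
    diff_key: str

    @classmethod
    def from_variant(cls, variant: str) -> "KeyMapping":
        if variant == "A":
            return cls("A", "F", "J")
        if variant == "B":
            return cls("B", "J", "F")
        raise ValueError(f"variant must be 'A' or 'B', got {variant!r}")


@dataclass(frozen=True)
class SequenceSpec:
    """Constraints for constrained pseudo-random condition sequencing."""

    per_condition_counts: dict[int, int] = field(
        default_factory=lambda: {1: 30, 2: 30, 3: 30, 4: 30}
    )
    lead_in: bool = True
    seed: int = 0
    max_run_length: int = 4

    def __post_init__(self) -> None:
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")
        for cond, count in self.per_condition_counts.items():
            if cond not in (1, 2, 3, 4):
                raise ValueError(f"unknown condition {cond!r}")
            if count < 0:
                raise ValueError("per-condition counts must be nonnegative")

    @property
    def total_scored(self) -> int:
        return sum(self.per_condition_counts.values())


@dataclass(frozen=True, slots=True)
class TwoBackTrial:
    """One letter trial of the 2-back comparison task.

    ``is_match`` is None for the two lead-in letters (no 2-back referent).
    """

    index: int
    letter: str
    is_match: Optional[bool]


@dataclass(frozen=True, slots=True)
class ResponseRecord:
    """Outcome of one scored trial.

    Feedback is "√" for a correct key within the available time, "×" for a
    wrong key within the available time, and "–" when no key arrived before
    the deadline.
    """

    trial_index: int
    key: Optional[str]
    rt_ms: Optional[float]
    correct: Optional[bool]
    feedback: str


@dataclass(frozen=True, slots=True)
class PVTTrial:
    """One psychomotor vigilance trial.

    A reaction of >= 100 ms is a valid response; >= 500 ms is an attention
    lapse (so every lapse is also valid).
    """

    foreperiod_ms: float
    rt_ms: Optional[float]
    valid: bool
    lapse: bool


@dataclass(frozen=True)
class ScaleRecord:
    """A subjective-scale administration anchored to a block or task.

    VAS items are integers 0-100 (minimum unit 1) over the four items in
    :data:`VAS_ITEMS`; NASA-TLX items are 0-20 over :data:`TLX_DIMENSIONS`.
    """

    kind: str  # "VAS" | "NASA_TLX"
    anchor: str  # e.g. "baseline", "block_3", "task_bs"
    items: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind == "VAS":
            lo, hi, expected = 0, 100, set(VAS_ITEMS)
        elif self.kind == "NASA_TLX":
            lo, hi, expected = 0, 20, set(TLX_DIMENSIONS)
        else:
            raise ValueError(f"unknown scale kind {self.kind!r}")
        unknown = set(self.items) - expected
        if unknown:
            raise ValueError(f"unknown {self.kind} items: {sorted(unknown)}")
        for name, score in self.items.items():
            if not (lo <= score <= hi):
                raise ValueError(f"{self.kind} item {name!r} score {score} outside [{lo}, {hi}]")


@dataclass
class Block:
    """One task block: realized trials with their response records."""

    task: str  # "bs" | "2back"
    trials: list  # list[Trial] or list[TwoBackTrial]
    records: list[ResponseRecord]


@dataclass
class SessionLog:
    """Everything one session produced; the unit all analysis consumes."""

    participant_id: str
    protocol: str  # "hmw_blocks" | "tot_induction" | "pvt"
    config: dict
    blocks: list[Block] = field(default_factory=list)
    scale_records: list[ScaleRecord] = field(default_factory=list)
    pvt_pre: list[PVTTrial] = field(default_factory=list)
    pvt_post: list[PVTTrial] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    truncated: bool = False

    @property
    def vas_records(self) -> list[ScaleRecord]:
        return [r for r in self.scale_records if r.kind == "VAS"]

    @property
    def tlx_records(self) -> list[ScaleRecord]:
        return [r for r in self.scale_records if r.kind == "NASA_TLX"]
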
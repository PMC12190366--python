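"""Headless, event-driven execution of the task protocols.

The engine runs on a virtual clock (milliseconds), so a 30-minute session
executes in milliseconds of wall time; millisecond-accurate display and
keyboard timing is a front-end adapter's job.  Any object satisfying the
:class:`Responder` protocol can be plugged in — the stochastic simulated
participant from :mod:`bstask.responders` or an adapter around a human-facing
front-end.

Clock accounting per scored BS trial: ``min(RT, available_time)`` of display
time followed by 500 ms ISI feedback ("√" correct, "×" incorrect, "–" no
response before the deadline).  PVT trials consume the random foreperiod, the
reaction time, and 1 s of feedback display.  VAS administration is
instantaneous on the task clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

from ._rng import RandomPool
from .config import SessionConfig
from .paradigm import (
    expected_key,
    generate_condition_sequence,
    next_stimulus,
    random_stimulus,
    realize_trials,
)
from .types import (
    FEEDBACK_CORRECT,
    FEEDBACK_INCORRECT,
    FEEDBACK_NO_RESPONSE,
    VAS_ITEMS,
    Block,
    KeyMapping,
    PVTTrial,
    ResponseRecord,
    ScaleRecord,
    SequenceSpec,
    SessionLog,
    Trial,
    TwoBackTrial,
)


class Responder(Protocol):
    """What the engine needs from a participant (simulated or adapted)."""

    key_mapping: KeyMapping

    def respond_bs(self, trial: Trial, block_index: int) -> tuple[str, float]:
        """Return (key, rt_ms) for a scored BS trial."""
        ...

    def respond_2back(self, trial: TwoBackTrial, block_index: int) -> tuple[Optional[bool], float]:
        """Return (match_judgment_or_None, rt_ms) for a scorable 2-back trial."""
        ...

    def respond_pvt(self, phase: str) -> float:
        """Reaction time (ms) to a PVT stimulus; phase is 'pre' or 'post'."""
        ...

    def report_vas(self, block_index: int, item: str) -> int:
        """VAS self-report 0-100 for one item; block_index 0 = baseline."""
        ...

    def report_tlx(self, task: str) -> dict[str, float]:
        """NASA-TLX ratings (six dimensions, 0-20) after a task."""
        ...


class ProtocolError(RuntimeError):
    """The responder violated the engine contract (e.g. negative RT)."""


@dataclass
class PracticeOutcome:
    passed: bool
    accuracy: float
    attempts: int
    accuracies: list[float]


def run_practice(
    responder: Responder,
    gate: float = 0.90,
    max_attempts: int = 10,
    seed: int = 0,
    trials_per_block: int = 16,
) -> PracticeOutcome:
    """Repeat 16-trial practice blocks until accuracy reaches the gate.

    Each attempt draws a fresh balanced sequence (4 trials per condition for
    the default block size).  Exhausting ``max_attempts`` flags a failed
    outcome — in the live protocol such a participant would not proceed.
    """
    if not (0.0 <= gate <= 1.0):
        raise ValueError("gate must be in [0, 1]")
    per_cond = trials_per_block // 4
    accuracies: list[float] = []
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        spec = SequenceSpec(per_condition_counts={c: per_cond for c in (1, 2, 3, 4)})
        seq = generate_condition_sequence(spec, rng=rng)
        pool = RandomPool(rng)
        trials = realize_trials(seq, available_times=None, pool=pool)
        records, _ = run_bs_block(responder, trials, isi_ms=500.0, block_index=0)
        scored = [r for r in records if r.correct is not None]
        accuracy = sum(r.correct for r in scored) / len(scored)
        accuracies.append(accuracy)
        if accuracy >= gate:
            return PracticeOutcome(True, accuracy, attempt, accuracies)
    return PracticeOutcome(False, accuracies[-1], max_attempts, accuracies)


def run_bs_block(
    responder: Responder,
    trials: Sequence[Trial],
    isi_ms: float = 500.0,
    block_index: int = 0,
    lead_in_exposure_ms: float = 1000.0,
    no_response_is_error: bool = True,
) -> tuple[list[ResponseRecord], float]:
    """Present realized trials to a responder; return records and elapsed ms.

    Scored trials with a deadline record "–" (no response) when the
    responder's RT exceeds the available time; the clock then advances by the
    full available time.  Otherwise the clock advances by the RT.  Every
    scored trial adds the ISI feedback duration.  In unlimited mode
    (``available_time_ms`` None) the engine waits for the key.
    """
    records: list[ResponseRecord] = []
    clock = 0.0
    for trial in trials:
        if not trial.scored:
            clock += lead_in_exposure_ms
            continue
        key, rt = responder.respond_bs(trial, block_index)
        if rt < 0:
            raise ProtocolError(f"responder returned negative RT {rt} on trial {trial.index}")
        deadline = trial.available_time_ms
        if deadline is not None and rt > deadline:
            records.append(
                ResponseRecord(trial.index, None, None, False if no_response_is_error else None, FEEDBACK_NO_RESPONSE)
            )
            clock += deadline
        else:
            correct = key == expected_key(trial.condition, responder.key_mapping)
            records.append(
                ResponseRecord(
                    trial.index, key, rt, correct, FEEDBACK_CORRECT if correct else FEEDBACK_INCORRECT
                )
            )
            clock += rt
        clock += isi_ms
    return records, clock


def run_2back_block(
    responder: Responder,
    trials: Sequence[TwoBackTrial],
    block_index: int = 0,
    letter_ms: float = 500.0,
    blank_ms: float = 2000.0,
) -> tuple[list[ResponseRecord], float]:
    """Fixed-pace 2-back block: 0.5 s letter + 2 s blank, no displayed feedback.

    Responses are accepted any time within the 2.5 s window; the recorded
    feedback symbol is internal scoring only.
    """
    window = letter_ms + blank_ms
    records: list[ResponseRecord] = []
    for trial in trials:
        if trial.is_match is None:
            continue
        judgment, rt = responder.respond_2back(trial, block_index)
        if rt < 0:
            raise ProtocolError(f"responder returned negative RT {rt} on 2-back trial {trial.index}")
        if judgment is None or rt > window:
            records.append(ResponseRecord(trial.index, None, None, False, FEEDBACK_NO_RESPONSE))
        else:
            correct = judgment == trial.is_match
            records.append(
                ResponseRecord(
                    trial.index,
                    "match" if judgment else "nonmatch",
                    rt,
                    correct,
                    FEEDBACK_CORRECT if correct else FEEDBACK_INCORRECT,
                )
            )
    return records, window * len(trials)


def run_pvt(
    responder: Responder,
    phase: str,
    duration_ms: float = 180_000.0,
    interval_bounds: tuple[float, float] = (2000.0, 10_000.0),
    pool: Optional[RandomPool] = None,
    seed: int = 0,
) -> list[PVTTrial]:
    """Run one PVT bout on the virtual clock.

    Foreperiods are uniform within ``interval_bounds``; each trial consumes
    foreperiod + RT + 1000 ms of feedback display.  A trial only happens if
    its stimulus onset falls inside the bout duration.  RT >= 100 ms is
    valid; RT >= 500 ms is an attention lapse.
    """
    if pool is None:
        pool = RandomPool(np.random.default_rng(seed))
    lo, hi = interval_bounds
    trials: list[PVTTrial] = []
    clock = 0.0
    while True:
        foreperiod = lo + (hi - lo) * pool.uniform()
        if clock + foreperiod >= duration_ms:
            break
        rt = responder.respond_pvt(phase)
        if rt < 0:
            raise ProtocolError(f"responder returned negative PVT RT {rt}")
        trials.append(
            PVTTrial(foreperiod_ms=foreperiod, rt_ms=rt, valid=rt >= 100.0, lapse=rt >= 500.0)
        )
        clock += foreperiod + rt + 1000.0
    return trials


def _collect_vas(responder: Responder, block_index: int, anchor: str) -> ScaleRecord:
    items = {item: int(responder.report_vas(block_index, item)) for item in VAS_ITEMS}
    return ScaleRecord(kind="VAS", anchor=anchor, items=items)


def run_tot_protocol(
    responder: Responder,
    config: SessionConfig,
    seed: int = 0,
    participant_id: str = "sim",
) -> SessionLog:
    """The 30-minute time-on-task fatigue-induction session.

    Baseline VAS, pre PVT, then ``block_count`` blocks each filled with
    balanced four-condition mini-batches (one trial per condition, shuffled)
    until the block clock passes ``block_duration_ms``; VAS after every block;
    post PVT after the last block.  Checking the clock only at batch
    boundaries keeps realized condition counts exactly 1:1:1:1 within each
    block.
    """
    if config.protocol != "tot_induction":
        raise ValueError("config.protocol must be 'tot_induction'")
    ss = np.random.SeedSequence(seed)
    task_seed, pvt_pre_seed, pvt_post_seed = ss.spawn(3)
    pool = RandomPool(np.random.default_rng(task_seed))
    log = SessionLog(
        participant_id=participant_id,
        protocol="tot_induction",
        config=config.model_dump(mode="json"),
        seeds={"session": seed},
    )
    if config.vas_schedule.pre_first_block:
        log.scale_records.append(_collect_vas(responder, 0, "baseline"))
    log.pvt_pre = run_pvt(
        responder,
        "pre",
        duration_ms=config.pvt_duration_ms,
        interval_bounds=config.pvt_interval_bounds,
        pool=RandomPool(np.random.default_rng(pvt_pre_seed)),
    )
    available = config.available_times or {}
    try:
        for b in range(1, config.block_count + 1):
            block_index = b - 1
            lead = random_stimulus(pool)
            trials: list[Trial] = [
                Trial(0, lead, None, lead.word == lead.ink_color, None, None, False)
            ]
            records: list[ResponseRecord] = []
            clock = config.lead_in_exposure_ms
            previous = lead
            index = 1
            while clock < config.block_duration_ms:
                batch = [1, 2, 3, 4]
                # Fisher-Yates shuffle from the pooled stream keeps the whole
                # session a pure function of the seed.
                for i in range(3, 0, -1):
                    j = pool.randint(i + 1)
                    batch[i], batch[j] = batch[j], batch[i]
                for cond in batch:
                    stim = next_stimulus(previous, cond, pool)
                    trial = Trial(
                        index=index,
                        stimulus=stim,
                        back_consistent=stim.grid_cell == previous.grid_cell,
                        stroop_congruent=stim.word == stim.ink_color,
                        condition=cond,
                        available_time_ms=available.get(cond),
                        scored=True,
                    )
                    trials.append(trial)
                    key, rt = responder.respond_bs(trial, block_index)
                    if rt < 0:
                        raise ProtocolError(f"negative RT {rt} in block {b}")
                    deadline = trial.available_time_ms
                    if deadline is not None and rt > deadline:
                        records.append(
                            ResponseRecord(
                                index,
                                None,
                                None,
                                False if config.count_no_response_as_error else None,
                                FEEDBACK_NO_RESPONSE,
                            )
                        )
                        clock += deadline
                    else:
                        correct = key == expected_key(cond, responder.key_mapping)
                        records.append(
                            ResponseRecord(
                                index,
                                key,
                                rt,
                                correct,
                                FEEDBACK_CORRECT if correct else FEEDBACK_INCORRECT,
                            )
                        )
                        clock += rt
                    clock += config.isi_feedback_ms
                    previous = stim
                    index += 1
            log.blocks.append(Block(task="bs", trials=trials, records=records))
            if config.vas_schedule.after_each_block:
                log.scale_records.append(_collect_vas(responder, b, f"block_{b}"))
    except ProtocolError:
        log.truncated = True
        raise
    log.pvt_post = run_pvt(
        responder,
        "post",
        duration_ms=config.pvt_duration_ms,
        interval_bounds=config.pvt_interval_bounds,
        pool=RandomPool(np.random.default_rng(pvt_post_seed)),
    )
    return log


def run_hmw_protocol(
    responder: Responder,
    config: SessionConfig,
    seed: int = 0,
    participant_id: str = "sim",
) -> SessionLog:
    """The workload-comparison session: blocked BS task and 2-back task.

    Each task runs ``block_count`` blocks (default 8) of the configured
    per-block condition counts (default 8 scored trials, two per condition)
    with rests between blocks, followed by a NASA-TLX administration.  Task
    order comes from ``config.task_order`` (counterbalanced across
    participants by the caller).
    """
    if config.protocol != "hmw_blocks":
        raise ValueError("config.protocol must be 'hmw_blocks'")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    log = SessionLog(
        participant_id=participant_id,
        protocol="hmw_blocks",
        config=config.model_dump(mode="json"),
        seeds={"session": seed},
    )
    available = config.available_times or {}
    for task, child in zip(config.task_order, children):
        rng = np.random.default_rng(child)
        pool = RandomPool(rng)
        if task == "bs":
            for b in range(config.block_count):
                spec = SequenceSpec(
                    per_condition_counts=dict(config.per_block_counts),
                    max_run_length=config.max_run_length,
                )
                seq = generate_condition_sequence(spec, rng=rng)
                trials = realize_trials(seq, available_times=available, pool=pool)
                records, _ = run_bs_block(
                    responder,
                    trials,
                    isi_ms=config.isi_feedback_ms,
                    block_index=b,
                    lead_in_exposure_ms=config.lead_in_exposure_ms,
                    no_response_is_error=config.count_no_response_as_error,
                )
                log.blocks.append(Block(task="bs", trials=trials, records=records))
            log.scale_records.append(
                ScaleRecord(kind="NASA_TLX", anchor="task_bs", items=responder.report_tlx("bs"))
            )
        elif task == "2back":
            from .paradigm import generate_2back_sequence

            n_scored = sum(config.per_block_counts.values())
            for b in range(config.block_count):
                trials2 = generate_2back_sequence(n_scored + 2, match_rate=0.5, rng=rng)
                records, _ = run_2back_block(
                    responder,
                    trials2,
                    block_index=b,
                    letter_ms=config.twoback_letter_ms,
                    blank_ms=config.twoback_blank_ms,
                )
                log.blocks.append(Block(task="2back", trials=list(trials2), records=records))
            log.scale_records.append(
                ScaleRecord(kind="NASA_TLX", anchor="task_2back", items=responder.report_tlx("2back"))
            )
        else:
            raise ValueError(f"unknown task {task!r}")
    return log
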
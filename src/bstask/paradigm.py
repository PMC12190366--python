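"""Combinatorial structure of the BS paradigm and the 2-back comparison task.

Conditions
----------
Each scored trial makes two binary judgments — 1-back spatial consistency and
Stroop color-word congruency — and falls into one of four conditions:

====  ===============  ================
cond  1-back            Stroop
====  ===============  ================
1     consistent        congruent
2     inconsistent      incongruent
3     consistent        incongruent
4     inconsistent      congruent
====  ===============  ================

Conditions 1-2 share one response key and 3-4 the other, so the required key
depends only on XNOR(back_consistent, stroop_congruent).

Sequences are constrained pseudo-random: exact per-condition counts with no
run of identical conditions longer than ``max_run_length``, generated by
rejection sampling (permute, check, retry).
"""

from __future__ import annotations

import string
from typing import Optional, Sequence

import numpy as np

from ._rng import RandomPool, pool_from_seed
from .types import (
    COLORS,
    N_GRID_CELLS,
    KeyMapping,
    SequenceSpec,
    StimulusSpec,
    Trial,
    TwoBackTrial,
)

#: Retry cap for rejection-sampled sequence generation.
DEFAULT_MAX_ATTEMPTS = 10_000

_CONDITION_TABLE = {
    (True, True): 1,
    (False, False): 2,
    (True, False): 3,
    (False, True): 4,
}

_FLAGS_BY_CONDITION = {v: k for k, v in _CONDITION_TABLE.items()}


class InfeasibleSequenceError(ValueError):
    """No sequence satisfies the requested counts and run-length constraint."""


def classify_condition(back_consistent: bool, stroop_congruent: bool) -> int:
    """Map the two latent judgments to the condition label 1-4."""
    return _CONDITION_TABLE[(bool(back_consistent), bool(stroop_congruent))]


def condition_flags(condition: int) -> tuple[bool, bool]:
    """Inverse of :func:`classify_condition`: (back_consistent, stroop_congruent)."""
    try:
        return _FLAGS_BY_CONDITION[condition]
    except KeyError:
        raise ValueError(f"condition must be in 1..4, got {condition!r}") from None


def expected_key(condition: int, mapping: KeyMapping) -> str:
    """The correct response key for a condition under a counterbalancing variant."""
    if condition in (1, 2):
        return mapping.same_key
    if condition in (3, 4):
        return mapping.diff_key
    raise ValueError(f"condition must be in 1..4, got {condition!r}")


def _run_lengths_ok(seq: np.ndarray, max_run: int) -> bool:
    run = 1
    for i in range(1, seq.shape[0]):
        if seq[i] == seq[i - 1]:
            run += 1
            if run > max_run:
                return False
        else:
            run = 1
    return True


def generate_condition_sequence(
    spec: SequenceSpec,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> list[int]:
    """Generate the scored condition sequence for one task.

    Rejection sampling: shuffle the exact multiset of conditions, accept the
    first permutation with no run longer than ``spec.max_run_length``.  Raises
    :class:`InfeasibleSequenceError` when the retry cap is exhausted (e.g. one
    condition dominates so heavily that no bounded-run arrangement exists).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    multiset = np.concatenate(
        [np.full(count, cond, dtype=np.int64) for cond, count in sorted(spec.per_condition_counts.items())]
        or [np.empty(0, dtype=np.int64)]
    )
    if multiset.size == 0:
        return []
    # Quick necessary condition: the most frequent condition must fit between
    # the others even with maximal-length runs.
    counts = sorted(spec.per_condition_counts.values(), reverse=True)
    n_max, n_rest = counts[0], sum(counts[1:])
    if int(np.ceil(n_max / spec.max_run_length)) > n_rest + 1:
        raise InfeasibleSequenceError(
            f"counts {spec.per_condition_counts} admit no sequence with max_run_length={spec.max_run_length}"
        )
    for _ in range(max_attempts):
        perm = rng.permutation(multiset)
        if _run_lengths_ok(perm, spec.max_run_length):
            return [int(c) for c in perm]
    raise InfeasibleSequenceError(
        f"no valid sequence found in {max_attempts} attempts for {spec.per_condition_counts} "
        f"with max_run_length={spec.max_run_length}"
    )


def random_stimulus(pool: RandomPool) -> StimulusSpec:
    """Unconstrained stimulus (used for unscored lead-in trials)."""
    return StimulusSpec(
        grid_cell=pool.randint(N_GRID_CELLS),
        ink_color=COLORS[pool.randint(4)],
        word=COLORS[pool.randint(4)],
    )


def next_stimulus(previous: StimulusSpec, condition: int, pool: RandomPool) -> StimulusSpec:
    """Realize the stimulus that puts the next trial into ``condition``.

    Back-consistent trials reuse the previous grid cell; inconsistent trials
    draw uniformly from the 8 other cells.  Ink color is drawn uniformly;
    congruent trials set the word to the ink, incongruent trials draw the word
    uniformly from the 3 other colors.
    """
    back_consistent, stroop_congruent = condition_flags(condition)
    if back_consistent:
        cell = previous.grid_cell
    else:
        cell = pool.choice_excluding(N_GRID_CELLS, previous.grid_cell)
    ink_idx = pool.randint(4)
    if stroop_congruent:
        word_idx = ink_idx
    else:
        word_idx = pool.choice_excluding(4, ink_idx)
    return StimulusSpec(grid_cell=cell, ink_color=COLORS[ink_idx], word=COLORS[word_idx])


def realize_trials(
    condition_seq: Sequence[int],
    available_times: Optional[dict[int, float]] = None,
    seed: int = 0,
    pool: Optional[RandomPool] = None,
    lead_in_stimulus: Optional[StimulusSpec] = None,
    index_offset: int = 0,
) -> list[Trial]:
    """Turn a condition sequence into concrete trials.

    Prepends one unscored lead-in trial (uniform random stimulus unless
    ``lead_in_stimulus`` is given) so the first scored trial has a 1-back
    referent; the full default task therefore yields 121 trials for 120
    scored conditions.  ``available_times`` maps condition -> deadline in ms
    (None = unlimited, the calibration mode).
    """
    if len(condition_seq) == 0:
        raise ValueError("condition_seq must be non-empty")
    for cond in condition_seq:
        if cond not in (1, 2, 3, 4):
            raise ValueError(f"unknown condition label {cond!r}")
    if pool is None:
        pool = pool_from_seed(seed)
    lead = lead_in_stimulus if lead_in_stimulus is not None else random_stimulus(pool)
    trials = [
        Trial(
            index=index_offset,
            stimulus=lead,
            back_consistent=None,
            stroop_congruent=lead.word == lead.ink_color,
            condition=None,
            available_time_ms=None,
            scored=False,
        )
    ]
    previous = lead
    for i, cond in enumerate(condition_seq, start=1):
        stim = next_stimulus(previous, cond, pool)
        back_consistent, stroop_congruent = condition_flags(cond)
        trials.append(
            Trial(
                index=index_offset + i,
                stimulus=stim,
                back_consistent=back_consistent,
                stroop_congruent=stroop_congruent,
                condition=cond,
                available_time_ms=None if available_times is None else available_times.get(cond),
                scored=True,
            )
        )
        previous = stim
    return trials


def rescore_trials(trials: Sequence[Trial]) -> list[Optional[int]]:
    """Recompute each trial's condition from raw stimuli alone.

    Independent consistency check: derives 1-back consistency from grid-cell
    equality with the preceding stimulus and congruency from word/ink
    equality, ignoring the stored flags.  Entry 0 (no referent) is None.
    """
    out: list[Optional[int]] = [None]
    for prev, cur in zip(trials[:-1], trials[1:]):
        back = cur.stimulus.grid_cell == prev.stimulus.grid_cell
        congruent = cur.stimulus.word == cur.stimulus.ink_color
        out.append(classify_condition(back, congruent))
    return out


def generate_2back_sequence(
    n_trials: int,
    match_rate: float = 0.5,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[TwoBackTrial]:
    """Generate the letter stream for the 2-back comparison task.

    Uses the 26 uppercase letters.  Among the ``n_trials - 2`` scorable
    trials, ``round(match_rate * scorable)`` repeat the letter from two trials
    back; the rest draw uniformly from the 25 other letters.
    """
    if n_trials < 3:
        raise ValueError("n_trials must be >= 3")
    if not (0.0 <= match_rate <= 1.0):
        raise ValueError(f"match_rate must be in [0, 1], got {match_rate}")
    if rng is None:
        rng = np.random.default_rng(seed)
    alphabet = string.ascii_uppercase
    n_scorable = n_trials - 2
    n_matches = int(round(match_rate * n_scorable))
    match_positions = set(rng.choice(n_scorable, size=n_matches, replace=False) + 2)
    letters: list[str] = [alphabet[int(rng.integers(26))] for _ in range(2)]
    flags: list[Optional[bool]] = [None, None]
    for i in range(2, n_trials):
        referent = letters[i - 2]
        if i in match_positions:
            letters.append(referent)
            flags.append(True)
        else:
            # map a draw from [0, 25) onto the 25 letters != referent
            k = int(rng.integers(25))
            ref_idx = alphabet.index(referent)
            letters.append(alphabet[k if k < ref_idx else k + 1])
            flags.append(False)
    return [TwoBackTrial(index=i, letter=letters[i], is_match=flags[i]) for i in range(n_trials)]
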
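"""Session engine contracts: feedback trichotomy, clocks, PVT, protocol shape."""

import numpy as np
import pytest
from scipy import stats

from bstask.config import hmw_config
from bstask.engine import (
    ProtocolError,
    run_2back_block,
    run_bs_block,
    run_hmw_protocol,
    run_practice,
    run_pvt,
    run_tot_protocol,
)
from bstask.io import session_log_to_dict
from bstask.paradigm import generate_2back_sequence, realize_trials
from bstask.responders import ResponderParams, ScriptedResponder, SimulatedParticipant, tot_preset
from bstask.types import FEEDBACK_SYMBOLS


def test_perfect_responder_all_correct_feedback():
    trials = realize_trials([1, 2, 3, 4], available_times={c: 2500.0 for c in (1, 2, 3, 4)}, seed=0)
    records, _ = run_bs_block(ScriptedResponder(fixed_rt_ms=1.0), trials)
    assert [r.feedback for r in records] == ["√"] * 4
    assert all(r.correct for r in records)


def test_slow_responder_all_no_response():
    trials = realize_trials([1, 2, 3, 4], available_times={1: 2300.0, 2: 3000.0, 3: 2600.0, 4: 2800.0}, seed=0)
    responder = ScriptedResponder(fixed_rt_ms=5000.0)
    records, _ = run_bs_block(responder, trials)
    assert [r.feedback for r in records] == ["–"] * 4
    assert all(r.key is None and r.rt_ms is None for r in records)
    assert all(r.correct is False for r in records)


def test_block_clock_matches_hand_sum():
    """Elapsed time = lead-in + sum(min(RT, AT)) + n x ISI, summed by hand."""
    trials = realize_trials([1, 1, 1], available_times={1: 2300.0}, seed=2)
    key = "F"  # condition 1 under variant A
    script = [(key, 1000.0), (key, 5000.0), (key, 800.0)]  # middle one times out
    records, elapsed = run_bs_block(
        ScriptedResponder(bs_script=script), trials, isi_ms=500.0, lead_in_exposure_ms=1000.0
    )
    assert elapsed == 1000.0 + (1000.0 + 500.0) + (2300.0 + 500.0) + (800.0 + 500.0)
    assert [r.feedback for r in records] == ["√", "–", "√"]


def test_feedback_trichotomy_and_wrong_key():
    trials = realize_trials([1, 3], available_times={1: 2300.0, 3: 2600.0}, seed=4)
    script = [("J", 500.0), ("J", 700.0)]  # wrong for cond 1, right for cond 3
    records, _ = run_bs_block(ScriptedResponder(bs_script=script), trials)
    assert [r.feedback for r in records] == ["×", "√"]
    assert all(r.feedback in FEEDBACK_SYMBOLS for r in records)


def test_negative_rt_rejected():
    trials = realize_trials([1], seed=0)
    with pytest.raises(ProtocolError):
        run_bs_block(ScriptedResponder(bs_script=[("F", -1.0)]), trials)


def test_unlimited_mode_waits_for_key():
    trials = realize_trials([2], available_times=None, seed=0)
    records, elapsed = run_bs_block(
        ScriptedResponder(bs_script=[("F", 9000.0)]), trials, lead_in_exposure_ms=0.0
    )
    assert records[0].feedback == "√"
    assert elapsed == 9000.0 + 500.0


def test_practice_perfect_responder_passes_first_attempt():
    outcome = run_practice(ScriptedResponder(fixed_rt_ms=1.0), gate=0.9, seed=0)
    assert outcome.passed and outcome.attempts == 1 and outcome.accuracy == 1.0


def test_practice_gate_zero_always_passes():
    params = tot_preset()
    poor = ResponderParams(
        rt_mean_ms=params.rt_mean_ms,
        rt_sd_ms=params.rt_sd_ms,
        accuracy={c: 0.5 for c in (1, 2, 3, 4)},
    )
    outcome = run_practice(SimulatedParticipant(poor, seed=0), gate=0.0, seed=0)
    assert outcome.passed and outcome.attempts == 1


def test_practice_coin_flip_responder_fails_gate():
    """P(>= 15/16 correct | p=0.5) = 17/2^16, so 10 attempts fail essentially surely."""
    p_pass_one = stats.binom.sf(14, 16, 0.5)  # accuracy >= 0.9 means >= 15 correct
    assert p_pass_one < 3e-4
    params = tot_preset()
    poor = ResponderParams(
        rt_mean_ms=params.rt_mean_ms,
        rt_sd_ms=params.rt_sd_ms,
        accuracy={c: 0.5 for c in (1, 2, 3, 4)},
    )
    outcome = run_practice(SimulatedParticipant(poor, seed=1), gate=0.9, max_attempts=10, seed=2)
    assert not outcome.passed and outcome.attempts == 10


def test_pvt_thresholds_on_scripted_rts():
    trials = run_pvt(ScriptedResponder(pvt_script=[250.0, 99.0, 600.0]), "pre", duration_ms=25_000.0, seed=0)
    assert len(trials) >= 3
    assert [t.valid for t in trials[:3]] == [True, False, True]
    assert [t.lapse for t in trials[:3]] == [False, False, True]
    assert all(t.lapse <= t.valid for t in trials)
    assert all(2000.0 <= t.foreperiod_ms <= 10_000.0 for t in trials)


def test_pvt_fast_responder_no_lapses():
    trials = run_pvt(ScriptedResponder(fixed_rt_ms=250.0), "pre", seed=3)
    assert all(t.valid and not t.lapse for t in trials)


def test_pvt_trial_count_matches_event_clock():
    """Trial count tracks duration / (mean foreperiod + RT + 1 s feedback)."""
    rt = 300.0
    trials = run_pvt(ScriptedResponder(fixed_rt_ms=rt), "pre", duration_ms=180_000.0, seed=9)
    # replay the event clock by hand from the recorded foreperiods
    clock = sum(t.foreperiod_ms + rt + 1000.0 for t in trials)
    assert clock < 180_000.0
    expected = 180_000.0 / (6000.0 + rt + 1000.0)
    assert abs(len(trials) - expected) <= 2 + 3 * np.sqrt(expected)  # scheduling noise


def test_tot_protocol_structure(one_tot_log, tot_cfg):
    log = one_tot_log
    assert len(log.vas_records) == 7  # baseline + 6 blocks
    assert [r.anchor for r in log.vas_records] == ["baseline"] + [f"block_{b}" for b in range(1, 7)]
    assert len(log.blocks) == 6
    assert log.pvt_pre and log.pvt_post
    for block in log.blocks:
        scored = [t for t in block.trials if t.scored]
        assert len(scored) == len(block.records)
        counts = [sum(1 for t in scored if t.condition == c) for c in (1, 2, 3, 4)]
        assert len(set(counts)) == 1  # exact 1:1:1:1 via whole mini-batches
        assert all(r.feedback in FEEDBACK_SYMBOLS for r in block.records)


def test_tot_block_counts_balanced_across_blocks(one_tot_log):
    per_block = [sum(1 for t in b.trials if t.scored) for b in one_tot_log.blocks]
    assert all(n % 4 == 0 for n in per_block)
    assert all(n > 0 for n in per_block)


def test_tot_replay_determinism(tot_cfg):
    logs = []
    for _ in range(2):
        responder = SimulatedParticipant(tot_preset(), seed=77)
        logs.append(run_tot_protocol(responder, tot_cfg, seed=78, participant_id="p"))
    assert session_log_to_dict(logs[0]) == session_log_to_dict(logs[1])


def test_tot_rejects_wrong_protocol(tot_cfg):
    cfg = hmw_config()
    with pytest.raises(ValueError):
        run_tot_protocol(ScriptedResponder(), cfg, seed=0)


def test_2back_block_scoring_and_pacing():
    trials = generate_2back_sequence(10, match_rate=0.5, seed=6)
    records, elapsed = run_2back_block(ScriptedResponder(fixed_rt_ms=400.0), trials)
    assert len(records) == 8
    assert all(r.correct for r in records)
    assert elapsed == 10 * 2500.0  # fixed pacing covers the two lead-in letters too


def test_hmw_protocol_structure():
    cfg = hmw_config()
    responder = SimulatedParticipant(tot_preset(), seed=21)
    log = run_hmw_protocol(responder, cfg, seed=22)
    bs_blocks = [b for b in log.blocks if b.task == "bs"]
    tb_blocks = [b for b in log.blocks if b.task == "2back"]
    assert len(bs_blocks) == 8 and len(tb_blocks) == 8
    for b in bs_blocks:
        assert sum(1 for t in b.trials if t.scored) == 8
    anchors = [r.anchor for r in log.tlx_records]
    assert anchors == ["task_bs", "task_2back"]
    for rec in log.tlx_records:
        assert all(0 <= v <= 20 for v in rec.items.values())
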
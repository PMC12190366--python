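"""Serialization of session logs, trial tables, and scale records.

JSON is the lossless canonical form (nested, schema-checked on read); flat
CSV exports carry explicit units in column names (``rt_ms``,
``available_time_ms``, ``score_0_100`` ...) for spreadsheet-side use.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .types import (
    Block,
    PVTTrial,
    ResponseRecord,
    ScaleRecord,
    SessionLog,
    StimulusSpec,
    Trial,
    TwoBackTrial,
)

PathLike = Union[str, Path]

TRIAL_CSV_COLUMNS = [
    "index",
    "grid_cell",
    "ink_color",
    "word",
    "back_consistent",
    "stroop_congruent",
    "condition",
    "available_time_ms",
    "scored",
]


class SchemaError(ValueError):
    """A serialized artifact violated the data model; message carries the location."""


def _trial_to_dict(t: Trial) -> dict:
    return {
        "index": t.index,
        "grid_cell": t.stimulus.grid_cell,
        "ink_color": t.stimulus.ink_color,
        "word": t.stimulus.word,
        "back_consistent": t.back_consistent,
        "stroop_congruent": t.stroop_congruent,
        "condition": t.condition,
        "available_time_ms": t.available_time_ms,
        "scored": t.scored,
    }


def _trial_from_dict(d: dict) -> Trial:
    return Trial(
        index=d["index"],
        stimulus=StimulusSpec(d["grid_cell"], d["ink_color"], d["word"]),
        back_consistent=d["back_consistent"],
        stroop_congruent=d["stroop_congruent"],
        condition=d["condition"],
        available_time_ms=d["available_time_ms"],
        scored=d["scored"],
    )


def _twoback_to_dict(t: TwoBackTrial) -> dict:
    return {"index": t.index, "letter": t.letter, "is_match": t.is_match}


def _record_to_dict(r: ResponseRecord) -> dict:
    return {
        "trial_index": r.trial_index,
        "key": r.key,
        "rt_ms": r.rt_ms,
        "correct": r.correct,
        "feedback": r.feedback,
    }


def _pvt_to_dict(t: PVTTrial) -> dict:
    return {"foreperiod_ms": t.foreperiod_ms, "rt_ms": t.rt_ms, "valid": t.valid, "lapse": t.lapse}


def session_log_to_dict(log: SessionLog) -> dict:
    return {
        "participant_id": log.participant_id,
        "protocol": log.protocol,
        "config": log.config,
        "blocks": [
            {
                "task": b.task,
                "trials": [
                    _trial_to_dict(t) if isinstance(t, Trial) else _twoback_to_dict(t)
                    for t in b.trials
                ],
                "records": [_record_to_dict(r) for r in b.records],
            }
            for b in log.blocks
        ],
        "scale_records": [
            {"kind": s.kind, "anchor": s.anchor, "items": dict(s.items)} for s in log.scale_records
        ],
        "pvt_pre": [_pvt_to_dict(t) for t in log.pvt_pre],
        "pvt_post": [_pvt_to_dict(t) for t in log.pvt_post],
        "seeds": dict(log.seeds),
        "truncated": log.truncated,
    }


def session_log_from_dict(d: dict) -> SessionLog:
    try:
        blocks = []
        for bi, b in enumerate(d.get("blocks", [])):
            task = b["task"]
            if task == "bs":
                trials = [_trial_from_dict(t) for t in b["trials"]]
            else:
                trials = [TwoBackTrial(t["index"], t["letter"], t["is_match"]) for t in b["trials"]]
            records = []
            for ri, r in enumerate(b["records"]):
                records.append(
                    ResponseRecord(r["trial_index"], r["key"], r["rt_ms"], r["correct"], r["feedback"])
                )
            blocks.append(Block(task=task, trials=trials, records=records))
        scale_records = []
        for si, s in enumerate(d.get("scale_records", [])):
            try:
                scale_records.append(ScaleRecord(kind=s["kind"], anchor=s["anchor"], items=s["items"]))
            except ValueError as exc:
                raise SchemaError(f"scale_records[{si}]: {exc}") from exc
        pvt_pre = [PVTTrial(**t) for t in d.get("pvt_pre", [])]
        pvt_post = [PVTTrial(**t) for t in d.get("pvt_post", [])]
        return SessionLog(
            participant_id=d["participant_id"],
            protocol=d["protocol"],
            config=d.get("config", {}),
            blocks=blocks,
            scale_records=scale_records,
            pvt_pre=pvt_pre,
            pvt_post=pvt_post,
            seeds=d.get("seeds", {}),
            truncated=d.get("truncated", False),
        )
    except KeyError as exc:
        raise SchemaError(f"missing field {exc} in session log") from exc


def save_session_log(log: SessionLog, path: PathLike) -> None:
    Path(path).write_text(json.dumps(session_log_to_dict(log), ensure_ascii=False, indent=1))


def load_session_log(path: PathLike) -> SessionLog:
    return session_log_from_dict(json.loads(Path(path).read_text()))


def trials_to_frame(trials) -> pd.DataFrame:
    """Flat trial table with the canonical column set (units in names)."""
    return pd.DataFrame([_trial_to_dict(t) for t in trials], columns=TRIAL_CSV_COLUMNS)


def write_trials_csv(trials, path: PathLike) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def session_to_trial_frame(log: SessionLog) -> pd.DataFrame:
    """Flatten a session's BS blocks into one tidy trial-level table."""
    rows = []
    for bi, block in enumerate(log.blocks, start=1):
        if block.task != "bs":
            continue
        by_index = {r.trial_index: r for r in block.records}
        for t in block.trials:
            row = _trial_to_dict(t)
            row["participant_id"] = log.participant_id
            row["block"] = bi
            rec = by_index.get(t.index)
            row["key"] = rec.key if rec else None
            row["rt_ms"] = rec.rt_ms if rec else None
            row["correct"] = rec.correct if rec else None
            row["feedback"] = rec.feedback if rec else None
            rows.append(row)
    return pd.DataFrame(rows)


def scales_to_frame(logs) -> pd.DataFrame:
    """Tidy scale-record table: (participant, kind, anchor, item, score)."""
    if isinstance(logs, SessionLog):
        logs = [logs]
    rows = []
    for log in logs:
        for rec in log.scale_records:
            for item, score in rec.items.items():
                rows.append(
                    {
                        "participant_id": log.participant_id,
                        "kind": rec.kind,
                        "anchor": rec.anchor,
                        "item": item,
                        "score": score,
                    }
                )
    return pd.DataFrame(rows, columns=["participant_id", "kind", "anchor", "item", "score"])


def read_rt_observations(path: PathLike) -> pd.DataFrame:
    """Read a calibration RT table, validating ranges row-by-row.

    Expected columns: participant_id, condition (1-4), rt_ms (> 0),
    correct (bool/0/1).  Violations raise :class:`SchemaError` naming the row.
    """
    df = pd.read_csv(path)
    required = ["participant_id", "condition", "rt_ms", "correct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        if row["condition"] not in (1, 2, 3, 4):
            raise SchemaError(f"{path}: row {i}: condition {row['condition']!r} not in 1..4")
        if not row["rt_ms"] > 0:
            raise SchemaError(f"{path}: row {i}: rt_ms {row['rt_ms']!r} must be positive")
    df["correct"] = df["correct"].astype(bool)
    return df
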
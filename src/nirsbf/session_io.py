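"""Session-log persistence: lossless JSON round trips plus a tabular CSV
export (one row per set) for downstream analysis."""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import pandas as pd

from .game import SessionLog, SetResult

__all__ = ["write_session_log", "read_session_log", "sessions_to_csv"]

CSV_COLUMNS = ["day", "set", "achieved", "remaining_s", "maintain_s",
               "score", "level"]


def write_session_log(log: SessionLog, path) -> None:
    payload = {
        "date_index": log.date_index,
        "seed": log.seed,
        "signal_kind": log.signal_kind,
        "user_level_before": log.user_level_before,
        "user_level_after": log.user_level_after,
        "set_results": [
            {"achieved": r.achieved, "remaining_time_s": r.remaining_time_s,
             "maintain_time_s": r.maintain_time_s, "score": r.score}
            for r in log.set_results
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_session_log(path) -> SessionLog:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(
                f"malformed session log {path} at line {exc.lineno}, "
                f"column {exc.colno}: {exc.msg}") from exc
    try:
        results = [SetResult(achieved=r["achieved"],
                             remaining_time_s=r["remaining_time_s"],
                             maintain_time_s=r["maintain_time_s"],
                             score=r["score"]) for r in d["set_results"]]
        return SessionLog(date_index=d["date_index"], set_results=results,
                          user_level_before=d["user_level_before"],
                          user_level_after=d["user_level_after"],
                          seed=d["seed"], signal_kind=d["signal_kind"])
    except KeyError as exc:
        raise ValueError(f"session log {path} is missing key {exc}") from exc


def sessions_to_csv(logs: Sequence[SessionLog] | SessionLog, path) -> None:
    if isinstance(logs, SessionLog):
        logs = [logs]
    rows = []
    for log in logs:
        for i, r in enumerate(log.set_results):
            rows.append({
                "day": log.date_index, "set": i,
                "achieved": r.achieved,
                "remaining_s": r.remaining_time_s,
                "maintain_s": r.maintain_time_s,
                "score": r.score,
                "level": log.user_level_before,
            })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False,
                                                   float_format="%.12g")
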
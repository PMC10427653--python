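"""Readers and writers for session logs, SV profiles, study tables and EMG.

All formats are plain text.  Money is written with two decimals (the
on-screen values); the exact internal titration values are multiples of
1/32 EUR and are never serialized — a session log is fully replayable
from the displayed values alone.  Schema violations are reported with
the offending line number.
"""

from __future__ import annotations

import csv
import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .strategies import Strategy, canonical_sort, pair_id, parse_strategy
from .titration import (
    FIXED_VALUE,
    N_EQUAL,
    N_TITRATION,
    ChoiceRecord,
    Offer,
    PairingResult,
    SessionLog,
    PHASE_EQUAL,
    PHASE_TITRATION,
)
from .strategies import CANONICAL_ORDER

SCHEMA_VERSION = "1.0"

SESSION_COLUMNS = [
    "participant_id", "phase", "pair_id", "presentation_index",
    "left_strategy", "right_strategy", "left_value", "right_value", "chosen",
]


class FormatError(ValueError):
    """A file violated its documented schema."""


def _fmt_eur(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# Session logs


def write_session_logs(sessions, path) -> None:
    """Write one or more session logs as CSV."""
    if isinstance(sessions, SessionLog):
        sessions = [sessions]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for session in sessions:
            for rec in session.records:
                o = rec.offer
                writer.writerow([
                    session.participant_id, o.phase, pair_id(o.pair),
                    o.presentation_index, o.left_strategy.value,
                    o.right_strategy.value, _fmt_eur(o.left_value),
                    _fmt_eur(o.right_value), rec.chosen.value,
                ])


def _rebuild_pairing(records, lineno) -> PairingResult:
    """Reconstruct the pairing outcome from its nine choice records."""
    votes = tuple(r.chosen for r in records[:N_EQUAL])
    a, b = canonical_sort(records[0].offer.pair)
    flexible = a if votes.count(a) >= 2 else b
    fixed = b if flexible is a else a
    last = records[-1]
    return PairingResult(
        flexible=flexible, fixed=fixed,
        last_display_value=last.offer.value_of(flexible),
        last_choice=last.chosen, equal_round_votes=votes,
    )


def read_session_logs(path) -> list[SessionLog]:
    """Read and validate a session-log CSV; rebuilds pairing outcomes."""
    sessions: dict[str, SessionLog] = {}
    groups: dict[tuple, list] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SESSION_COLUMNS:
            raise FormatError(f"line 1: expected header {SESSION_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            try:
                left = parse_strategy(row["left_strategy"])
                right = parse_strategy(row["right_strategy"])
                chosen = parse_strategy(row["chosen"])
                idx = int(row["presentation_index"])
                lval, rval = float(row["left_value"]), float(row["right_value"])
                phase = row["phase"]
            except (ValueError, KeyError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if phase not in (PHASE_EQUAL, PHASE_TITRATION):
                raise FormatError(f"line {lineno}: unknown phase {phase!r}")
            if phase == PHASE_EQUAL:
                if not (lval == rval == 1.0):
                    raise FormatError(f"line {lineno}: equal round must offer 1.00/1.00")
                flexible = None
            else:
                flex_vals = [v for v in (lval, rval) if v != FIXED_VALUE]
                if len(flex_vals) != 1:
                    raise FormatError(
                        f"line {lineno}: titration row needs exactly one fixed "
                        f"{FIXED_VALUE:.2f} EUR offer")
                if not 0.03 <= flex_vals[0] <= 1.97:
                    raise FormatError(
                        f"line {lineno}: flexible value {flex_vals[0]} outside [0.03, 1.97]")
                flexible = left if lval != FIXED_VALUE else right
            try:
                offer = Offer(
                    pair=frozenset((left, right)), presentation_index=idx,
                    left_strategy=left, right_strategy=right,
                    left_value=lval, right_value=rval, phase=phase,
                    flexible=flexible,
                )
                rec = ChoiceRecord(row["participant_id"], offer, chosen)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            key = (row["participant_id"], pair_id(offer.pair))
            bucket = groups.setdefault(key, [])
            if bucket and idx != bucket[-1][1].offer.presentation_index + 1:
                raise FormatError(
                    f"line {lineno}: non-monotone presentation index {idx} for {key[1]}")
            if not bucket and idx != 1:
                raise FormatError(
                    f"line {lineno}: pairing {key[1]} must start at presentation 1")
            bucket.append((lineno, rec))
            session = sessions.setdefault(
                row["participant_id"], SessionLog(participant_id=row["participant_id"]))
            session.records.append(rec)
    for (pid, pid_pair), bucket in groups.items():
        if len(bucket) != N_EQUAL + N_TITRATION:
            raise FormatError(
                f"pairing {pid_pair} of participant {pid} has {len(bucket)} "
                f"presentations, expected {N_EQUAL + N_TITRATION}")
        sessions[pid].pairing_results.append(
            _rebuild_pairing([r for _, r in bucket], bucket[0][0]))
    return list(sessions.values())


def session_logs_to_json(sessions) -> str:
    """Structured JSON export of session logs with a schema version."""
    if isinstance(sessions, SessionLog):
        sessions = [sessions]
    payload = {"schema_version": SCHEMA_VERSION, "sessions": []}
    for s in sessions:
        payload["sessions"].append({
            "participant_id": s.participant_id,
            "records": [
                {
                    "phase": r.offer.phase,
                    "pair_id": pair_id(r.offer.pair),
                    "presentation_index": r.offer.presentation_index,
                    "left_strategy": r.offer.left_strategy.value,
                    "right_strategy": r.offer.right_strategy.value,
                    "left_value": _fmt_eur(r.offer.left_value),
                    "right_value": _fmt_eur(r.offer.right_value),
                    "chosen": r.chosen.value,
                }
                for r in s.records
            ],
        })
    return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# SV profiles


def write_profiles(profiles, path) -> None:
    from .analysis import profiles_to_frame

    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "ordered_intercept", "ordered_slope",
                "predicted_choice"} | {f"sv_{s.value}" for s in CANONICAL_ORDER}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"profile table lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Study tables


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# EMG recordings


def write_emg_recording(recording, signal_path, events_path) -> None:
    """Signal as delimited text with a sampling-rate header; events as CSV."""
    channels = list(recording.samples)
    with open(signal_path, "w", newline="") as fh:
        fh.write(f"# sampling_rate={recording.sampling_rate}\n")
        writer = csv.writer(fh)
        writer.writerow(channels)
        for row in zip(*(recording.samples[c] for c in channels)):
            writer.writerow([f"{v:.6g}" for v in row])
    with open(events_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_sample", "condition"])
        for onset, condition in recording.events:
            writer.writerow([onset, condition])


def read_emg_recording(signal_path, events_path):
    from .emg import EMGRecording

    with open(signal_path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# sampling_rate="):
            raise FormatError("line 1: missing '# sampling_rate=' header")
        rate = float(header.split("=", 1)[1])
        reader = csv.reader(fh)
        channels = next(reader)
        data = {c: [] for c in channels}
        for lineno, row in enumerate(reader, start=3):
            if len(row) != len(channels):
                raise FormatError(f"line {lineno}: expected {len(channels)} values")
            for c, v in zip(channels, row):
                data[c].append(float(v))
    events = []
    with open(events_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                events.append((int(row["onset_sample"]), row["condition"]))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    return EMGRecording(
        samples={c: np.asarray(v) for c, v in data.items()},
        sampling_rate=rate, events=events,
    )


# ---------------------------------------------------------------------------
# Run configuration and result bundles


def load_run_config(path) -> dict:
    """Load a YAML run configuration (seed, generator and analysis options)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("run config must be a mapping")
    return cfg


def dump_run_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.reset_index().to_json(orient="records"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.ndarray, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(getattr(k, "value", k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Strategy):
        return obj.value
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def bundle_to_json(bundle: dict) -> str:
    """Serialize an analysis results bundle (dataclasses + DataFrames) to JSON."""
    return json.dumps(_jsonable(bundle), indent=1, default=str)
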
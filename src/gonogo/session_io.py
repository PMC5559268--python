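"""Session-log readers and writers (CSV and JSON).

Both formats embed a schema version; readers reject unknown major
versions.  Lick times are serialized in milliseconds from stimulus onset
at 0.1 ms precision, durations in configs in seconds.

CSV layout: comment header lines (``# gonogo-session ...`` carrying the
schema version, subject, task tag and the JSON-encoded task config)
followed by one row per trial with columns
``index, stimulus_class, stimulus_id, outcome, rewarded,
next_trial_delay_s, lick_times_ms`` (lick times semicolon-joined).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .task import GO, NOGO, OUTCOMES, SessionLog, TaskConfig, TrialRecord

__all__ = ["SCHEMA_VERSION", "write_session", "read_session", "load_trial_matrix"]

SCHEMA_VERSION = "1.0"
_CSV_COLUMNS = [
    "index",
    "stimulus_class",
    "stimulus_id",
    "outcome",
    "rewarded",
    "next_trial_delay_s",
    "lick_times_ms",
]


class SessionFormatError(ValueError):
    """Malformed session file."""


def _check_version(version: str, path) -> None:
    major = str(version).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise SessionFormatError(
            f"{path}: unsupported schema version {version!r} "
            f"(reader supports major {SCHEMA_VERSION.split('.')[0]})"
        )


def _format_licks(times: tuple[float, ...]) -> str:
    return ";".join(f"{t:.1f}" for t in times)


def _parse_licks(text: str, where: str) -> tuple[float, ...]:
    text = (text or "").strip()
    if not text:
        return ()
    try:
        return tuple(float(tok) for tok in text.split(";"))
    except ValueError as exc:
        raise SessionFormatError(f"{where}: bad lick_times_ms field: {exc}") from exc


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "csv"


def _trial_to_dict(t: TrialRecord) -> dict:
    return {
        "index": t.index,
        "stimulus_class": t.stimulus_class,
        "stimulus_id": t.stimulus_id,
        "lick_times_ms": [round(x, 1) for x in t.lick_times_ms],
        "outcome": t.outcome,
        "rewarded": t.rewarded,
        "next_trial_delay_s": t.next_trial_delay_s,
    }


def _trial_from_fields(
    row: int,
    index,
    stimulus_class,
    stimulus_id,
    outcome,
    rewarded,
    next_trial_delay_s,
    lick_times_ms,
) -> TrialRecord:
    where = f"row {row}"
    if stimulus_class not in (GO, NOGO):
        raise SessionFormatError(
            f"{where}: stimulus_class must be GO or NOGO, got {stimulus_class!r}"
        )
    if outcome not in OUTCOMES:
        raise SessionFormatError(f"{where}: unknown outcome {outcome!r}")
    try:
        return TrialRecord(
            index=int(index),
            stimulus_class=stimulus_class,
            stimulus_id=str(stimulus_id),
            lick_times_ms=tuple(float(x) for x in lick_times_ms),
            outcome=outcome,
            rewarded=bool(rewarded),
            next_trial_delay_s=float(next_trial_delay_s),
        )
    except ValueError as exc:
        raise SessionFormatError(f"{where}: {exc}") from exc


def write_session(log: SessionLog, path, fmt: str | None = None) -> None:
    """Write a session log as CSV or JSON (inferred from the suffix)."""
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if fmt == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "subject_id": log.subject_id,
            "task_tag": log.task_tag,
            "config": log.config.to_dict(),
            "trials": [_trial_to_dict(t) for t in log.trials],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return
    lines = [
        "# gonogo-session",
        f"# schema={SCHEMA_VERSION}",
        f"# subject_id={log.subject_id}",
        f"# task_tag={log.task_tag}",
        f"# config={json.dumps(log.config.to_dict(), sort_keys=True)}",
        ",".join(_CSV_COLUMNS),
    ]
    for t in log.trials:
        lines.append(
            f"{t.index},{t.stimulus_class},{t.stimulus_id},{t.outcome},"
            f"{int(t.rewarded)},{t.next_trial_delay_s:.6g},"
            f"{_format_licks(t.lick_times_ms)}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_session(path, fmt: str | None = None) -> SessionLog:
    """Read a session log; malformed rows raise with row number and field."""
    fmt = _infer_format(path, fmt)
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SessionFormatError(f"{path}: file is empty")
    if fmt == "json":
        payload = json.loads(text)
        _check_version(payload.get("schema_version", "?"), path)
        trials = [
            _trial_from_fields(
                row=i + 1,
                index=d.get("index"),
                stimulus_class=d.get("stimulus_class"),
                stimulus_id=d.get("stimulus_id", ""),
                outcome=d.get("outcome"),
                rewarded=d.get("rewarded"),
                next_trial_delay_s=d.get("next_trial_delay_s", 0.0),
                lick_times_ms=d.get("lick_times_ms", ()),
            )
            for i, d in enumerate(payload.get("trials", []))
        ]
        log = SessionLog(
            subject_id=payload.get("subject_id", ""),
            task_tag=payload.get("task_tag", ""),
            trials=trials,
            config=TaskConfig.from_dict(payload["config"]),
        )
        log.validate()
        return log

    meta: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
        else:
            break
    if "schema" not in meta and not any(
        line.startswith("# gonogo-session") for line in text.splitlines()[:1]
    ):
        raise SessionFormatError(f"{path}: missing session header")
    _check_version(meta.get("schema", "?"), path)

    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")
    trials = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        trials.append(
            _trial_from_fields(
                row=i,
                index=rec["index"],
                stimulus_class=rec["stimulus_class"],
                stimulus_id=rec["stimulus_id"],
                outcome=rec["outcome"],
                rewarded=int(rec["rewarded"]),
                next_trial_delay_s=rec["next_trial_delay_s"],
                lick_times_ms=_parse_licks(rec["lick_times_ms"], f"row {i}"),
            )
        )
    config = TaskConfig.from_dict(json.loads(meta["config"])) if "config" in meta \
        else TaskConfig(n_trials=max(1, len(trials)))
    log = SessionLog(
        subject_id=meta.get("subject_id", ""),
        task_tag=meta.get("task_tag", ""),
        trials=trials,
        config=config,
    )
    log.validate()
    return log


def load_trial_matrix(path, config: TaskConfig | None = None) -> SessionLog:
    """Import a legacy rectangular trial-matrix ``.mat`` file.

    Best-effort shim for deposited trial tables (one row per trial with
    class/outcome codes); mapping conventions vary between deposits, so
    this reader is provided untested and may need column adjustments.
    """
    from scipy.io import loadmat  # deferred; only needed for legacy import

    data = loadmat(path)
    arrays = {k: v for k, v in data.items() if not k.startswith("__")}
    if len(arrays) != 1:
        raise SessionFormatError(
            f"{path}: expected a single trial matrix, found {sorted(arrays)}"
        )
    (name, mat), = arrays.items()
    config = config or TaskConfig(n_trials=max(1, mat.shape[0]))
    trials = []
    for i, row in enumerate(mat, start=1):
        is_go = bool(row[0])
        licked = bool(row[1])
        if is_go:
            outcome = "hit" if licked else "miss"
        else:
            outcome = "false_alarm" if licked else "correct_rejection"
        licks = tuple(float(x) for x in row[2:] if x > 0)
        trials.append(
            TrialRecord(
                index=i,
                stimulus_class=GO if is_go else NOGO,
                stimulus_id=name,
                lick_times_ms=licks,
                outcome=outcome,
                rewarded=(outcome == "hit"),
            )
        )
    return SessionLog(subject_id=name, task_tag="imported", trials=trials, config=config)
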
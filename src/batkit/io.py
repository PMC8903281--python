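"""Readers and writers for the delimited-text interchange formats.

All files are UTF-8 CSV with a header row; times are seconds written with
full precision.  Schemas:

* tap log — ``participant_id, excerpt_id, repetition, tap_onset_s`` (one row
  per tap),
* perception responses — ``participant_id, trial_index, judgment, truth,
  confidence``,
* beat annotations — ``excerpt_id, beat_onset_s``,
* demographics — ``participant_id, group, age, music_years, dance_years``.

Schema violations raise :class:`SchemaError` with the offending column or
row named; writers and readers round-trip losslessly.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scoring import PerceptionResponse, TapTrial
from .stimuli import BeatGrid

__all__ = [
    "SchemaError",
    "read_tap_log",
    "write_tap_log",
    "read_responses",
    "write_responses",
    "read_beat_annotations",
    "write_beat_annotations",
    "read_demographics",
    "write_results",
    "read_run_config",
]


class SchemaError(ValueError):
    """A delimited input file does not match its documented schema."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")
    return frame


def read_tap_log(path) -> list[TapTrial]:
    """Read a tap log into :class:`TapTrial` records (one per trial).

    Onsets are sorted within trial; exact duplicate onsets are dropped with a
    warning; a repetition outside {1, 2} is a schema error.
    """
    frame = _read_csv(path, ["participant_id", "excerpt_id", "repetition", "tap_onset_s"])
    bad_rep = ~frame["repetition"].isin([1, 2])
    if bad_rep.any():
        raise SchemaError(
            f"{path}: repetition must be 1 or 2 "
            f"(row {int(frame.index[bad_rep][0]) + 2})"
        )
    trials = []
    keys = ["participant_id", "excerpt_id", "repetition"]
    for (pid, ex, rep), sub in frame.groupby(keys, sort=True):
        onsets = np.sort(sub["tap_onset_s"].to_numpy(dtype=float))
        deduped = np.unique(onsets)
        if deduped.size < onsets.size:
            warnings.warn(
                f"{path}: dropped {onsets.size - deduped.size} duplicate tap "
                f"onset(s) for participant {pid}, excerpt {ex}, rep {rep}",
                stacklevel=2,
            )
        trials.append(TapTrial(str(pid), str(ex), int(rep), deduped))
    return trials


def write_tap_log(trials: list[TapTrial] | pd.DataFrame, path) -> None:
    if isinstance(trials, pd.DataFrame):
        frame = trials
    else:
        rows = [
            {
                "participant_id": t.participant_id,
                "excerpt_id": t.excerpt_id,
                "repetition": t.repetition,
                "tap_onset_s": onset,
            }
            for t in trials
            for onset in t.tap_onsets
        ]
        frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.9g")


def read_responses(path) -> list[PerceptionResponse]:
    frame = _read_csv(
        path, ["participant_id", "trial_index", "judgment", "truth", "confidence"]
    )
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(
                PerceptionResponse(
                    str(row["participant_id"]),
                    int(row["trial_index"]),
                    _as_bool(row["judgment"]),
                    _as_bool(row["truth"]),
                    int(row["confidence"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from None
    return out


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "on"):
        return True
    if s in ("false", "0", "off"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def write_responses(responses, path) -> None:
    if isinstance(responses, pd.DataFrame):
        frame = responses
    else:
        frame = pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in responses],
                "trial_index": [r.trial_index for r in responses],
                "judgment": [r.judgment for r in responses],
                "truth": [r.truth for r in responses],
                "confidence": [r.confidence for r in responses],
            }
        )
    frame.to_csv(path, index=False)


def read_beat_annotations(path) -> dict[str, BeatGrid]:
    """Beat annotation CSV (``excerpt_id, beat_onset_s``) -> grids by excerpt.

    Excerpt duration is taken as the last beat plus one mean IBI unless a
    ``duration_s`` column is present.
    """
    frame = _read_csv(path, ["excerpt_id", "beat_onset_s"])
    grids = {}
    for ex, sub in frame.groupby("excerpt_id", sort=True):
        onsets = np.sort(sub["beat_onset_s"].to_numpy(dtype=float))
        if onsets.size < 2:
            raise SchemaError(f"{path}: excerpt {ex}: needs at least 2 beats")
        if "duration_s" in frame.columns:
            duration = float(sub["duration_s"].iloc[0])
        else:
            duration = float(onsets[-1] + np.mean(np.diff(onsets)))
        grids[str(ex)] = BeatGrid(str(ex), onsets, duration)
    return grids


def write_beat_annotations(grids: Mapping[str, BeatGrid], path) -> None:
    rows = [
        {"excerpt_id": ex, "beat_onset_s": onset, "duration_s": grid.duration}
        for ex, grid in grids.items()
        for onset in grid.beat_onsets
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_demographics(path) -> pd.DataFrame:
    frame = _read_csv(
        path, ["participant_id", "group", "age", "music_years", "dance_years"]
    )
    for col in ("music_years", "dance_years"):
        if (frame[col] < 0).any():
            raise SchemaError(f"{path}: {col} must be >= 0")
    return frame


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each tidy result table as ``<out_dir>/<name>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        target = out_dir / f"{name}.csv"
        frame.to_csv(target, index=False, float_format="%.9g")
        written.append(target)
    return written


def read_run_config(path) -> dict:
    """Load a YAML run configuration; must include a ``seed``."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise SchemaError(f"{path}: run config must set a seed")
    return cfg
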
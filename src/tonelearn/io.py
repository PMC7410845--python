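"""Readers and writers for the pipeline's text-based artifact formats.

Trial tables, retention/score tables and pitch tracks travel as CSV;
continuous recordings as two-column delimited text (time_s, amplitude_uV);
marker lists and configurations as JSON.  Readers validate schemas and
raise :class:`SchemaError` naming the offending column or field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import PitchTrack, Recording

TRIAL_REQUIRED = [
    "participant",
    "group",
    "phase",
    "block",
    "trial",
    "syllable",
    "talker",
    "tone",
    "response",
    "outcome",
    "stimulated",
]


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    if not table["outcome"].isin((0, 1)).all():
        raise SchemaError("column 'outcome' must be binary 0/1")
    for col in ("block", "trial", "outcome", "stimulated"):
        table[col] = table[col].astype(int)
    return table


def write_recording(recording: Recording, path: str | Path) -> None:
    times = np.arange(recording.n_samples) / recording.fs
    np.savetxt(
        path,
        np.column_stack([times, recording.data]),
        fmt="%.9g",
        delimiter="\t",
        header="time_s\tamplitude_uV",
        comments="",
    )


def read_recording(path: str | Path) -> Recording:
    raw = pd.read_csv(path, sep="\t")
    if raw.shape[1] != 2:
        raise SchemaError(
            f"recording file must have 2 columns (time_s, amplitude_uV); got {raw.shape[1]}"
        )
    times = raw.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(times)
    if times.size < 2 or np.any(dt <= 0):
        raise SchemaError("column 'time_s' must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise SchemaError("column 'time_s' must be uniformly sampled")
    return Recording(raw.iloc[:, 1].to_numpy(dtype=float), fs=1.0 / dt[0])


def write_pitch_track(track: PitchTrack, path: str | Path) -> None:
    pd.DataFrame({"time_s": track.times, "f0_hz": track.f0}).to_csv(path, index=False)


def read_pitch_track(path: str | Path) -> PitchTrack:
    raw = pd.read_csv(path)
    for col in ("time_s", "f0_hz"):
        if col not in raw.columns:
            raise SchemaError(f"pitch track missing column {col!r}")
    return PitchTrack(
        raw["time_s"].to_numpy(dtype=float), raw["f0_hz"].to_numpy(dtype=float)
    )


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps(
                {
                    "onset": markers["onset"].astype(int).tolist(),
                    "offset": markers["offset"].astype(int).tolist(),
                    "score": markers["score"].astype(float).tolist(),
                },
                indent=1,
            )
        )
    else:
        markers.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        for key in ("onset", "offset"):
            if key not in obj:
                raise SchemaError(f"marker file missing field {key!r}")
        return pd.DataFrame(
            {
                "onset": obj["onset"],
                "offset": obj["offset"],
                "score": obj.get("score", [np.nan] * len(obj["onset"])),
            }
        )
    table = pd.read_csv(path, sep="\t")
    for col in ("onset", "offset"):
        if col not in table.columns:
            raise SchemaError(f"marker file missing column {col!r}")
    return table


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
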
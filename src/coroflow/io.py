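"""Reading and writing recordings and annotation sidecars.

Recordings travel as plain CSV with header
``time_s,pressure_mmhg,velocity_cm_s``; events live in a JSON sidecar of
the form ``{"events": [{"kind", "onset_s", "duration_s"}, ...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Annotation, WaveformRecording

__all__ = ["read_recording", "write_recording", "default_events_path"]

CSV_COLUMNS = ["time_s", "pressure_mmhg", "velocity_cm_s"]


def default_events_path(csv_path: str | Path) -> Path:
    """Sidecar path convention: ``foo.csv`` -> ``foo.events.json``."""
    p = Path(csv_path)
    return p.with_suffix(".events.json")


def write_recording(
    recording: WaveformRecording,
    csv_path: str | Path,
    events_path: str | Path | None = None,
) -> None:
    """Write a recording as CSV plus a JSON annotation sidecar."""
    df = pd.DataFrame({
        "time_s": recording.time,
        "pressure_mmhg": recording.pressure,
        "velocity_cm_s": recording.velocity,
    })
    df.to_csv(csv_path, index=False)
    if events_path is None:
        events_path = default_events_path(csv_path)
    payload = {
        "sampling_rate_hz": recording.sampling_rate,
        "events": [a.to_dict() for a in recording.annotations],
    }
    Path(events_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_recording(
    csv_path: str | Path,
    events_path: str | Path | None = None,
) -> WaveformRecording:
    """Read a recording from CSV, validating grid and signal invariants.

    The annotation sidecar is optional; if absent the recording carries
    no events.  The sampling rate comes from the sidecar when present,
    otherwise it is inferred from the median time step.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"recording CSV {csv_path} is missing required column(s): {', '.join(missing)}"
        )
    time = df["time_s"].to_numpy(dtype=float)
    annotations: list[Annotation] = []
    fs = None
    if events_path is None:
        candidate = default_events_path(csv_path)
        events_path = candidate if candidate.exists() else None
    if events_path is not None:
        payload = json.loads(Path(events_path).read_text())
        if not isinstance(payload, dict) or "events" not in payload:
            raise ValueError(f"annotation sidecar {events_path} must contain an 'events' list")
        for entry in payload["events"]:
            if "kind" not in entry or "onset_s" not in entry:
                raise ValueError(
                    f"malformed event in {events_path}: each needs 'kind' and 'onset_s'"
                )
            annotations.append(Annotation.from_dict(entry))
        fs = payload.get("sampling_rate_hz")
    if fs is None:
        if time.size < 2:
            raise ValueError("cannot infer sampling rate from a single-sample recording")
        fs = 1.0 / float(np.median(np.diff(time)))
    return WaveformRecording(
        time=time,
        pressure=df["pressure_mmhg"].to_numpy(dtype=float),
        velocity=df["velocity_cm_s"].to_numpy(dtype=float),
        sampling_rate=float(fs),
        annotations=annotations,
    )
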
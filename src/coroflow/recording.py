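"""Sampled coronary waveform recordings and their event annotations.

A :class:`WaveformRecording` holds distal coronary pressure (mmHg) and
Doppler flow velocity (cm/s) on a uniform time grid, together with a list
of protocol events (vasodilator boluses, balloon-ramp interval, rest
windows).  It is the single input type of the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised protocol event kinds.
EVENT_KINDS = frozenset(
    {"bolus_adenosine", "bolus_bradykinin", "ramp_start", "ramp_end", "rest_window"}
)


@dataclass
class Annotation:
    """A protocol event anchored to the recording's time axis.

    Parameters
    ----------
    kind
        One of :data:`EVENT_KINDS`.
    onset_s
        Event onset in seconds, on the recording's time axis.
    duration_s
        Optional event duration in seconds (e.g. the length of a rest
        window or of the balloon ramp).
    """

    kind: str
    onset_s: float
    duration_s: float | None = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "onset_s": self.onset_s, "duration_s": self.duration_s}

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        return cls(kind=d["kind"], onset_s=float(d["onset_s"]),
                   duration_s=None if d.get("duration_s") is None else float(d["duration_s"]))


@dataclass
class WaveformRecording:
    """Uniformly sampled pressure and flow-velocity traces.

    Invariants enforced at construction: the time grid is strictly
    increasing with constant step ``1/sampling_rate``; pressure and
    velocity are non-negative and the same length as ``time``; every
    annotation onset lies within the recorded interval.
    """

    time: np.ndarray
    pressure: np.ndarray
    velocity: np.ndarray
    sampling_rate: float
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("recording is empty: time axis must be a non-empty 1-D array")
        if not (self.pressure.shape == self.velocity.shape == self.time.shape):
            raise ValueError("pressure and velocity must have the same length as time")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time.size > 1:
            dt = np.diff(self.time)
            step = 1.0 / self.sampling_rate
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, step, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    "non-uniform time grid: sample spacing does not match 1/sampling_rate"
                )
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be non-negative")
        if np.any(self.velocity < 0):
            raise ValueError("velocity must be non-negative")
        t0, t1 = float(self.time[0]), float(self.time[-1])
        for ann in self.annotations:
            if not (t0 - 1e-9 <= ann.onset_s <= t1 + 1e-9):
                raise ValueError(
                    f"annotation {ann.kind!r} onset {ann.onset_s} s lies outside the "
                    f"recorded interval [{t0}, {t1}] s"
                )

    @property
    def duration(self) -> float:
        """Recording span in seconds (one sample period past the last sample)."""
        return self.time.size / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.time.size

    @classmethod
    def concatenate(cls, segments: "list[WaveformRecording]") -> "WaveformRecording":
        """Join segments end-to-end on a single uniform grid.

        Annotations are shifted by each segment's start offset.  All
        segments must share one sampling rate.
        """
        if not segments:
            raise ValueError("no segments to concatenate")
        fs = segments[0].sampling_rate
        if any(s.sampling_rate != fs for s in segments):
            raise ValueError("all segments must share the same sampling rate")
        pressure = np.concatenate([s.pressure for s in segments])
        velocity = np.concatenate([s.velocity for s in segments])
        time = np.arange(pressure.size) / fs
        annotations: list[Annotation] = []
        offset_samples = 0
        for seg in segments:
            offset_s = offset_samples / fs
            for ann in seg.annotations:
                annotations.append(
                    Annotation(ann.kind, ann.onset_s + offset_s, ann.duration_s)
                )
            offset_samples += seg.n_samples
        return cls(time=time, pressure=pressure, velocity=velocity,
                   sampling_rate=fs, annotations=annotations)
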
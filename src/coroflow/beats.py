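"""Beat segmentation and per-beat reduction of waveform recordings.

All downstream indices operate on beat means, so the only preprocessing
the pipeline needs is to cut the recording into cardiac cycles and
average pressure and velocity within each.  Beats are delimited
foot-to-foot on the *pressure* trace: pressure pulsatility persists
during balloon inflation while velocity pulsatility collapses, which
makes pressure the robust gating signal across the whole protocol.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, periodogram

from .recording import Annotation, WaveformRecording

__all__ = ["Beat", "BeatSeries", "detect_beats", "beats_in_window",
           "estimate_heart_rate", "beats_to_csv"]

#: fraction of the expected cycle used as the refractory period between feet
REFRACTORY_FRACTION = 0.6


@dataclass
class Beat:
    """One foot-to-foot cardiac cycle reduced to its summary values."""

    start_time: float
    end_time: float
    mean_pressure: float
    mean_velocity: float
    peak_pressure: float | None = None

    def __post_init__(self) -> None:
        if self.peak_pressure is None:
            self.peak_pressure = self.mean_pressure
        if not self.start_time < self.end_time:
            raise ValueError("beat start_time must precede end_time")
        if self.mean_velocity < 0:
            raise ValueError("beat mean_velocity must be non-negative")
        if self.mean_pressure > self.peak_pressure + 1e-9:
            raise ValueError("beat mean_pressure cannot exceed peak_pressure")


@dataclass
class BeatSeries:
    """Ordered, non-overlapping beats with the source annotations carried through."""

    beats: list[Beat]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.beats, self.beats[1:]):
            if b.start_time < a.end_time - 1e-9 or b.start_time <= a.start_time:
                raise ValueError("beats must be strictly ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)

    @property
    def velocities(self) -> np.ndarray:
        return np.array([b.mean_velocity for b in self.beats])

    @property
    def pressures(self) -> np.ndarray:
        return np.array([b.mean_pressure for b in self.beats])


def estimate_heart_rate(recording: WaveformRecording) -> float:
    """Dominant pulsatile frequency of the pressure trace, in beats/min.

    Uses the periodogram peak within the physiological band 30-250 bpm.
    Intended for recordings whose nominal rate is unknown (e.g. files
    read from disk); falls back to 80 bpm for non-pulsatile input.
    """
    p = recording.pressure - np.mean(recording.pressure)
    if np.ptp(recording.pressure) < 1e-6:
        return 80.0
    freqs, power = periodogram(p, fs=recording.sampling_rate)
    band = (freqs >= 30.0 / 60.0) & (freqs <= 250.0 / 60.0)
    if not np.any(band):
        return 80.0
    return float(freqs[band][np.argmax(power[band])] * 60.0)


def detect_beats(recording: WaveformRecording, expected_rate: float) -> BeatSeries:
    """Segment a recording into beats at the diastolic feet of pressure.

    Feet are local pressure minima with prominence at least
    ``max(0.25 * peak-to-peak, 1 mmHg)``, separated by a refractory
    period of ``0.6 * (60 / expected_rate)`` s (suppresses dicrotic-notch
    double counts).  Each beat spans foot-to-foot; a constant
    (non-pulsatile) trace yields an empty series.
    """
    if not 30.0 <= expected_rate <= 250.0:
        raise ValueError("expected_rate must lie in [30, 250] beats/min")
    if recording.n_samples == 0:
        raise ValueError("cannot detect beats in an empty recording")
    dt = np.diff(recording.time)
    if dt.size and not np.allclose(dt, 1.0 / recording.sampling_rate, rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform sampling: beat detection requires a uniform grid")
    period = 60.0 / expected_rate
    if recording.duration < 3 * period:
        raise ValueError(
            f"recording of {recording.duration:.2f} s is shorter than 3 expected "
            f"cycles ({3 * period:.2f} s)"
        )
    p = recording.pressure
    distance = max(1, int(round(REFRACTORY_FRACTION * period * recording.sampling_rate)))
    prominence = max(0.25 * float(np.ptp(p)), 1.0)
    # pad with +inf so feet on the first/last sample are detectable
    padded = np.concatenate(([-np.inf], -p, [-np.inf]))
    feet, _ = find_peaks(padded, distance=distance, prominence=prominence)
    feet = feet - 1
    if feet.size < 2:
        return BeatSeries([], list(recording.annotations))
    counts = np.diff(feet)
    mean_p = np.add.reduceat(p, feet)[:-1] / counts
    mean_v = np.add.reduceat(recording.velocity, feet)[:-1] / counts
    peak_p = np.maximum.reduceat(p, feet)[:-1]
    t = recording.time
    beats = [
        Beat(float(t[feet[i]]), float(t[feet[i + 1]]),
             float(mean_p[i]), float(mean_v[i]), float(peak_p[i]))
        for i in range(feet.size - 1)
    ]
    return BeatSeries(beats, list(recording.annotations))


def beats_in_window(series: BeatSeries, start: float, end: float) -> BeatSeries:
    """Beats wholly contained in [start, end], order preserved.

    Boundary convention: a beat ending exactly at ``end`` is included; a
    beat starting at ``end`` is not.
    """
    if not start < end:
        raise ValueError("window start must precede end")
    selected = [b for b in series.beats
                if b.start_time >= start and b.start_time < end and b.end_time <= end]
    return BeatSeries(selected, list(series.annotations))


def beats_to_csv(series: BeatSeries, path: str | Path) -> None:
    """Export per-beat summaries as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "mean_pressure_mmhg", "mean_velocity_cm_s"])
        for b in series.beats:
            writer.writerow([b.start_time, b.end_time, b.mean_pressure, b.mean_velocity])
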
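"""Coronary pressure-flow derived indices of metabolic regulation.

Baseline flow is the mean of 5 successive resting beats; hyperemic flow
is the mean of the 3 successive beats with the highest flow after a
vasodilator bolus; coronary flow reserve (CFR) is their ratio; hyperemic
microvascular resistance (HMR) is coronary pressure divided by flow at
maximal vasodilation.  Clinically, CFR above 3.0 is considered normal
and below 2.0 pathological.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import BeatSeries
from .recording import Annotation

__all__ = [
    "HyperemiaResult",
    "baseline_flow",
    "hyperemic_flow",
    "hyperemic_pressure",
    "cfr",
    "hmr",
    "classify_cfr",
    "analyze_bolus",
]

BASELINE_N_BEATS = 5
HYPEREMIC_N_BEATS = 3

CFR_NORMAL_THRESHOLD = 3.0
CFR_PATHOLOGICAL_THRESHOLD = 2.0


@dataclass
class HyperemiaResult:
    """Indices derived from one vasodilator bolus."""

    drug: str
    baseline_flow: float      # cm/s
    hyperemic_flow: float     # cm/s
    hyperemic_pressure: float  # mmHg, over the peak-flow window
    cfr: float                # dimensionless
    hmr: float                # mmHg/(cm/s)
    classification: str       # normal | intermediate | pathological
    replicate: int | None = None
    peak_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.baseline_flow <= 0 or self.hyperemic_flow <= 0:
            raise ValueError("flows must be positive")
        if abs(self.cfr - self.hyperemic_flow / self.baseline_flow) > 1e-12 * max(1.0, self.cfr):
            raise ValueError("cfr is inconsistent with hyperemic/baseline flow")
        if abs(self.hmr - self.hyperemic_pressure / self.hyperemic_flow) > 1e-12 * max(1.0, self.hmr):
            raise ValueError("hmr is inconsistent with pressure/hyperemic flow")

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "replicate": self.replicate,
            "baseline_flow": self.baseline_flow,
            "hyperemic_flow": self.hyperemic_flow,
            "hyperemic_pressure": self.hyperemic_pressure,
            "cfr": self.cfr,
            "hmr": self.hmr,
            "classification": self.classification,
        }


def baseline_flow(rest_beats: BeatSeries) -> float:
    """Mean velocity of the final 5 successive beats of the rest window."""
    n = len(rest_beats)
    if n < BASELINE_N_BEATS:
        raise ValueError(
            f"baseline flow needs {BASELINE_N_BEATS} successive resting beats, got {n}"
        )
    return float(np.mean(rest_beats.velocities[-BASELINE_N_BEATS:]))


def hyperemic_flow(post_bolus_beats: BeatSeries) -> tuple[float, tuple[float, float]]:
    """Maximal mean over all windows of 3 successive post-bolus beats.

    Returns the window mean velocity and the window's time span.  Ties
    resolve to the earliest window.
    """
    beats = post_bolus_beats.beats
    n = len(beats)
    if n < HYPEREMIC_N_BEATS:
        raise ValueError(
            f"hyperemic flow needs {HYPEREMIC_N_BEATS} successive post-bolus beats, got {n}"
        )
    v = post_bolus_beats.velocities
    window_means = np.convolve(v, np.ones(HYPEREMIC_N_BEATS) / HYPEREMIC_N_BEATS, "valid")
    i = int(np.argmax(window_means))  # argmax returns the first maximum
    window = (beats[i].start_time, beats[i + HYPEREMIC_N_BEATS - 1].end_time)
    return float(window_means[i]), window


def hyperemic_pressure(post_bolus_beats: BeatSeries, window: tuple[float, float]) -> float:
    """Mean beat pressure over the same window used for hyperemic flow."""
    start, end = window
    sel = [b for b in post_bolus_beats.beats
           if b.start_time >= start - 1e-9 and b.end_time <= end + 1e-9]
    if not sel:
        raise ValueError(f"no beats fall within the peak-flow window [{start}, {end}] s")
    return float(np.mean([b.mean_pressure for b in sel]))


def cfr(baseline: float, hyperemic: float) -> float:
    """Coronary flow reserve: hyperemic flow divided by baseline flow."""
    if baseline <= 0:
        raise ValueError("baseline flow must be positive")
    return hyperemic / baseline


def hmr(pressure: float, hyperemic: float) -> float:
    """Hyperemic microvascular resistance: pressure / flow at maximal vasodilation."""
    if hyperemic <= 0:
        raise ValueError("hyperemic flow must be positive")
    return pressure / hyperemic


def classify_cfr(value: float) -> str:
    """Clinical CFR classification: > 3.0 normal, < 2.0 pathological.

    The thresholds are strict inequalities, so the boundary values 2.0
    and 3.0 both map to ``intermediate``.
    """
    if value <= 0:
        raise ValueError("cfr must be positive")
    if value > CFR_NORMAL_THRESHOLD:
        return "normal"
    if value < CFR_PATHOLOGICAL_THRESHOLD:
        return "pathological"
    return "intermediate"


def analyze_bolus(
    series: BeatSeries,
    bolus_event: Annotation,
    search_window_s: float = 60.0,
    window_cap_s: float | None = None,
    replicate: int | None = None,
) -> HyperemiaResult:
    """Derive all hyperemia indices for one annotated bolus.

    Baseline flow comes from the last 5 beats wholly before the bolus
    onset; the hyperemic window is searched over beats within
    ``search_window_s`` after onset, optionally capped at the onset of
    the next protocol event (``window_cap_s``) so replicate measurements
    never overlap.
    """
    if not bolus_event.kind.startswith("bolus_"):
        raise ValueError(f"annotation kind {bolus_event.kind!r} is not a bolus event")
    drug = bolus_event.kind.removeprefix("bolus_")
    onset = bolus_event.onset_s
    rest = BeatSeries([b for b in series.beats if b.end_time <= onset],
                      series.annotations)
    base = baseline_flow(rest)
    end = onset + search_window_s
    if window_cap_s is not None:
        end = min(end, window_cap_s)
    post = BeatSeries(
        [b for b in series.beats if b.start_time >= onset and b.end_time <= end],
        series.annotations,
    )
    hyp_flow, window = hyperemic_flow(post)
    hyp_pressure = hyperemic_pressure(post, window)
    ratio = cfr(base, hyp_flow)
    return HyperemiaResult(
        drug=drug,
        baseline_flow=base,
        hyperemic_flow=hyp_flow,
        hyperemic_pressure=hyp_pressure,
        cfr=ratio,
        hmr=hmr(hyp_pressure, hyp_flow),
        classification=classify_cfr(ratio),
        replicate=replicate,
        peak_window=window,
    )
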
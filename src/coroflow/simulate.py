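"""Synthetic coronary hemodynamics generator.

Produces annotated pressure/flow-velocity recordings that emulate an
intracoronary Doppler-wire experiment in an intact pig: pulsatile rest
traces, vasodilator-bolus hyperemia transients that approximately triple
flow, and a balloon-driven pressure ramp that crosses the lower
autoregulatory breakpoint so both the plateau and the ischemic limb of
the pressure-flow relation are observable.

The generator works at two scales:

* an intra-beat *template* (pressure deviation with zero cycle mean,
  velocity multiplier with unit cycle mean) carries the pulsatility;
* slow *envelopes* (rest level, gamma-variate hyperemia transient,
  linear balloon ramp through the autoregulation model) carry the
  physiology.  Downstream analysis consumes beat means only, so the
  template shape is deliberately decoupled from the envelopes.

Per-beat Gaussian noise is added to the envelope values, matching the
scale at which the analysis operates (beat means).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .recording import Annotation, WaveformRecording

__all__ = [
    "SimulationConfig",
    "autoregulation_flow_model",
    "simulate_beat_template",
    "hyperemia_transient",
    "simulate_rest_segment",
    "simulate_bolus_segment",
    "simulate_ramp_segment",
    "generate_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic coronary experiment.

    Defaults describe a healthy anesthetized pig: heart rate 85 bpm,
    mean distal coronary pressure 89 mmHg, baseline flow velocity
    19.1 cm/s, a vasodilator bolus that triples flow while distal
    pressure dips to about 61 mmHg at peak hyperemia, and a lower
    autoregulatory breakpoint at 49 mmHg.  The ischemic limb of the
    pressure-flow relation passes through a zero-flow pressure of
    10 mmHg; the autoregulatory plateau has a slightly positive slope.
    """

    heart_rate: float = 85.0                 # beats/min
    mean_pressure: float = 89.0              # mmHg, rest mean distal pressure
    pulse_pressure: float = 40.0             # mmHg, peak-to-foot excursion
    baseline_velocity: float = 19.1          # cm/s
    hyperemic_gain: float = 3.0              # peak/baseline flow multiplier
    hyperemia_time_to_peak: float = 8.0      # s after bolus onset
    hyperemia_decay_tau: float = 15.0        # s, relaxation back to baseline
    hyperemic_pressure_drop: float = 28.0    # mmHg dip of mean pressure at peak
    breakpoint_pressure: float = 49.0        # mmHg, lower autoregulation limit
    zero_flow_pressure: float = 10.0         # mmHg, ischemic-limb intercept
    plateau_slope: float = 0.02              # (cm/s)/mmHg above the breakpoint
    ramp_start_pressure: float = 89.0        # mmHg
    ramp_end_pressure: float = 25.0          # mmHg
    ramp_duration: float = 180.0             # s
    beat_noise_sd_velocity: float = 1.5      # cm/s, per-beat
    beat_noise_sd_pressure: float = 2.0      # mmHg, per-beat
    sampling_rate: float = 250.0             # Hz
    seed: int = 0
    velocity_pulsatility: float = 0.8        # depth of the systolic velocity dip

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.sampling_rate < 50:
            raise ValueError("sampling_rate must be at least 50 Hz")
        for name in ("mean_pressure", "pulse_pressure", "hyperemic_pressure_drop",
                     "breakpoint_pressure", "zero_flow_pressure",
                     "ramp_start_pressure", "ramp_end_pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.zero_flow_pressure < self.breakpoint_pressure < self.ramp_start_pressure):
            raise ValueError(
                "requires zero_flow_pressure < breakpoint_pressure < ramp_start_pressure"
            )
        if self.ramp_end_pressure >= self.breakpoint_pressure:
            raise ValueError(
                "ramp_end_pressure must fall below breakpoint_pressure so the ramp "
                "exposes both limbs of the pressure-flow relation"
            )
        if self.hyperemic_gain < 1:
            raise ValueError("hyperemic_gain must be >= 1")
        if self.baseline_velocity <= 0:
            raise ValueError("baseline_velocity must be positive")
        if self.beat_noise_sd_velocity < 0 or self.beat_noise_sd_pressure < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.hyperemia_time_to_peak <= 0 or self.hyperemia_decay_tau <= 0:
            raise ValueError("hyperemia time constants must be positive")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        if not (0 <= self.velocity_pulsatility < 1):
            raise ValueError("velocity_pulsatility must lie in [0, 1)")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Steady-state autoregulation model
# ---------------------------------------------------------------------------

def autoregulation_flow_model(mean_pressure, config: SimulationConfig):
    """Steady-state flow velocity at a given mean perfusion pressure.

    Above the breakpoint flow follows the (nearly flat) autoregulatory
    plateau ``baseline_velocity + plateau_slope * (P - ramp_start_pressure)``;
    below it flow is pressure-dependent along the straight ischemic limb
    through ``(zero_flow_pressure, 0)``.  The two limbs meet continuously
    at the breakpoint.  Accepts scalars or arrays; never returns a
    negative flow.
    """
    p = np.asarray(mean_pressure, dtype=float)
    if np.any(p < 0):
        raise ValueError("mean_pressure must be non-negative")
    c = config
    flow_at_bp = c.baseline_velocity + c.plateau_slope * (c.breakpoint_pressure - c.ramp_start_pressure)
    ischemic_slope = flow_at_bp / (c.breakpoint_pressure - c.zero_flow_pressure)
    plateau = c.baseline_velocity + c.plateau_slope * (p - c.ramp_start_pressure)
    ischemic = ischemic_slope * (p - c.zero_flow_pressure)
    f = np.where(p >= c.breakpoint_pressure, plateau, ischemic)
    f = np.maximum(f, 0.0)
    return float(f) if np.isscalar(mean_pressure) else f


# ---------------------------------------------------------------------------
# Intra-beat template
# ---------------------------------------------------------------------------

# Systole occupies the first 35% of the cycle.  The systolic pressure shape
# is a half-sinusoid of period 1.0 (in cycle-fraction units) truncated at
# end-systole, so the dicrotic notch sits at sin(0.7*pi) of the peak; the
# diastolic run-off decays exponentially from the notch towards the foot.
_SYSTOLE_FRACTION = 0.35
_SYS_HALF_PERIOD = 0.5
_NOTCH = math.sin(math.pi * _SYSTOLE_FRACTION / _SYS_HALF_PERIOD)
_DIASTOLIC_TAU = 0.18
# closed-form cycle mean of the raw shape (amplitude 1, foot at 0)
_SYS_AREA = (_SYS_HALF_PERIOD / math.pi) * (
    1.0 - math.cos(math.pi * _SYSTOLE_FRACTION / _SYS_HALF_PERIOD)
)
_DIA_AREA = _NOTCH * _DIASTOLIC_TAU * (
    1.0 - math.exp(-(1.0 - _SYSTOLE_FRACTION) / _DIASTOLIC_TAU)
)
_SHAPE_MEAN = _SYS_AREA + _DIA_AREA


def _pressure_shape(phi: np.ndarray) -> np.ndarray:
    """Raw periodic pressure shape on [0, 1): foot 0, peak 1."""
    systole = np.sin(np.pi * np.minimum(phi, _SYSTOLE_FRACTION) / _SYS_HALF_PERIOD)
    diastole = _NOTCH * np.exp(-(phi - _SYSTOLE_FRACTION) / _DIASTOLIC_TAU)
    return np.where(phi < _SYSTOLE_FRACTION, systole, diastole)


def simulate_beat_template(config: SimulationConfig, phase):
    """Intra-beat waveform template at a cardiac phase in [0, 1).

    Returns ``(pressure_deviation, velocity_multiplier)``.  The pressure
    deviation (mmHg) spans ``pulse_pressure`` from foot to peak and has
    zero mean over the cycle; the velocity multiplier dips during
    systole (coronary inflow is diastolic-dominant) and has unit mean
    over the cycle, with depth set by ``velocity_pulsatility``.
    """
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    dev = config.pulse_pressure * (_pressure_shape(phi) - _SHAPE_MEAN)
    a = config.velocity_pulsatility
    c_d = 1.0 + a * 2.0 * _SYSTOLE_FRACTION / math.pi
    mult = np.where(
        phi < _SYSTOLE_FRACTION,
        c_d - a * np.sin(np.pi * phi / _SYSTOLE_FRACTION),
        c_d,
    )
    if np.isscalar(phase):
        return float(dev), float(mult)
    return dev, mult


# ---------------------------------------------------------------------------
# Hyperemia transient
# ---------------------------------------------------------------------------

def hyperemia_transient(t_since_onset, config: SimulationConfig):
    """Normalized gamma-variate bolus response g(t), peak 1 at time-to-peak.

    ``g(t) = (t/tp)^alpha * exp(alpha * (1 - t/tp))`` with
    ``alpha = tp / decay_tau`` so the late decay rate is
    ``1/hyperemia_decay_tau``.  Zero before onset.
    """
    tp = config.hyperemia_time_to_peak
    alpha = tp / config.hyperemia_decay_tau
    s = np.asarray(t_since_onset, dtype=float) / tp
    s_safe = np.maximum(s, 1e-300)
    g = np.where(s > 0, np.exp(alpha * (np.log(s_safe) + 1.0 - s_safe)), 0.0)
    return float(g) if np.isscalar(t_since_onset) else g


# ---------------------------------------------------------------------------
# Rendering engines
# ---------------------------------------------------------------------------

def _grid(config: SimulationConfig, duration: float):
    n = int(round(duration * config.sampling_rate))
    if n < 1:
        raise ValueError("segment duration too short for the sampling rate")
    t = np.arange(n) / config.sampling_rate
    period = 60.0 / config.heart_rate
    pos = t / period  # fractional beat position from segment start
    k = np.floor(pos).astype(np.int64)
    phi = pos - k
    return t, k, phi


def _render_samplewise(
    config: SimulationConfig,
    duration: float,
    env_pressure: Callable[[np.ndarray], np.ndarray],
    env_velocity: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
):
    """Render a segment whose envelopes vary sample-by-sample (rest, bolus)."""
    t, k, phi = _grid(config, duration)
    n_beats = int(k[-1]) + 1
    vel_noise = rng.normal(0.0, config.beat_noise_sd_velocity, n_beats)
    prs_noise = rng.normal(0.0, config.beat_noise_sd_pressure, n_beats)
    dev, mult = simulate_beat_template(config, phi)
    pressure = np.maximum(env_pressure(t) + prs_noise[k] + dev, 0.0)
    velocity = np.maximum(env_velocity(t) + vel_noise[k], 0.0) * mult
    return t, pressure, velocity


def _render_beatwise(
    config: SimulationConfig,
    duration: float,
    beat_pressure: Callable[[float], float],
    rng: np.random.Generator,
):
    """Render a segment whose physiology is defined per beat (balloon ramp).

    Each beat's mean pressure is the envelope at the beat midpoint plus
    per-beat noise, and its velocity is the autoregulation model
    evaluated at that (noisy) pressure plus velocity noise — flow
    responds to the pressure the bed actually sees.
    """
    t, k, phi = _grid(config, duration)
    period = 60.0 / config.heart_rate
    n_beats = int(k[-1]) + 1
    j = np.arange(n_beats)
    lo = np.maximum(j * period, 0.0)
    hi = np.minimum((j + 1) * period, duration)
    mids = 0.5 * (lo + hi)
    prs_noise = rng.normal(0.0, config.beat_noise_sd_pressure, n_beats)
    vel_noise = rng.normal(0.0, config.beat_noise_sd_velocity, n_beats)
    p_beat = np.array([beat_pressure(m) for m in mids]) + prs_noise
    p_beat = np.maximum(p_beat, 0.0)
    v_beat = np.maximum(autoregulation_flow_model(p_beat, config) + vel_noise, 0.0)
    dev, mult = simulate_beat_template(config, phi)
    pressure = np.maximum(p_beat[k] + dev, 0.0)
    velocity = v_beat[k] * mult
    return t, pressure, velocity


def _rng_or_default(config: SimulationConfig, rng) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# Segment simulators
# ---------------------------------------------------------------------------

def simulate_rest_segment(
    config: SimulationConfig, duration: float = 30.0, rng=None
) -> WaveformRecording:
    """Resting pulsatile recording at baseline pressure and flow."""
    rng = _rng_or_default(config, rng)
    t, p, v = _render_samplewise(
        config, duration,
        env_pressure=lambda tt: np.full_like(tt, config.mean_pressure),
        env_velocity=lambda tt: np.full_like(tt, config.baseline_velocity),
        rng=rng,
    )
    ann = [Annotation("rest_window", 0.0, duration)]
    return WaveformRecording(t, p, v, config.sampling_rate, ann)


def simulate_bolus_segment(
    config: SimulationConfig,
    duration: float,
    drug: str,
    onset_s: float = 15.0,
    rng=None,
) -> WaveformRecording:
    """Rest window followed by a vasodilator bolus transient.

    The velocity envelope is ``baseline_velocity * (1 + (gain-1)*g(t))``
    with the gamma-variate ``g`` of :func:`hyperemia_transient`; mean
    pressure dips by ``hyperemic_pressure_drop * g(t)`` (distal pressure
    falls as microvascular resistance collapses).  The segment is
    annotated with a ``rest_window`` before onset and the bolus event.
    """
    if drug not in ("adenosine", "bradykinin"):
        raise ValueError(f"unknown drug {drug!r}: expected 'adenosine' or 'bradykinin'")
    needed = onset_s + config.hyperemia_time_to_peak + config.hyperemia_decay_tau
    if duration < needed:
        raise ValueError(
            f"bolus segment of {duration} s is too short to contain the hyperemic "
            f"transient (needs at least {needed:.1f} s)"
        )
    rng = _rng_or_default(config, rng)
    gain = config.hyperemic_gain

    def env_velocity(tt):
        g = hyperemia_transient(tt - onset_s, config)
        return config.baseline_velocity * (1.0 + (gain - 1.0) * g)

    def env_pressure(tt):
        g = hyperemia_transient(tt - onset_s, config)
        return config.mean_pressure - config.hyperemic_pressure_drop * g

    t, p, v = _render_samplewise(config, duration, env_pressure, env_velocity, rng)
    ann = [
        Annotation("rest_window", 0.0, onset_s),
        Annotation(f"bolus_{drug}", onset_s,
                   config.hyperemia_time_to_peak + config.hyperemia_decay_tau),
    ]
    return WaveformRecording(t, p, v, config.sampling_rate, ann)


def simulate_ramp_segment(config: SimulationConfig, rng=None) -> WaveformRecording:
    """Balloon-inflation segment: mean pressure declines linearly.

    Mean distal pressure falls from ``ramp_start_pressure`` to
    ``ramp_end_pressure`` over ``ramp_duration``; each beat's velocity
    follows :func:`autoregulation_flow_model` at the beat's mean
    pressure, plus per-beat noise.  Annotated with ``ramp_start`` (whose
    duration is the ramp length) and ``ramp_end``.
    """
    rng = _rng_or_default(config, rng)
    dur = config.ramp_duration
    p0, p1 = config.ramp_start_pressure, config.ramp_end_pressure

    def beat_pressure(t_mid: float) -> float:
        frac = min(max(t_mid / dur, 0.0), 1.0)
        return p0 + (p1 - p0) * frac

    t, p, v = _render_beatwise(config, dur, beat_pressure, rng)
    ann = [
        Annotation("ramp_start", 0.0, dur),
        Annotation("ramp_end", float(t[-1]), None),
    ]
    return WaveformRecording(t, p, v, config.sampling_rate, ann)


def simulate_step_ramp_segment(
    config: SimulationConfig,
    step_mmhg: float = 5.0,
    dwell_s: float = 20.0,
    rng=None,
) -> WaveformRecording:
    """Stepwise balloon inflation: pressure drops in discrete steps.

    A fidelity variant of :func:`simulate_ramp_segment` in which mean
    pressure descends from ``ramp_start_pressure`` to
    ``ramp_end_pressure`` in steps of ``step_mmhg`` held for ``dwell_s``
    each, mimicking manual stepwise inflations.
    """
    rng = _rng_or_default(config, rng)
    p0, p1 = config.ramp_start_pressure, config.ramp_end_pressure
    n_steps = int(math.ceil((p0 - p1) / step_mmhg)) + 1
    dur = n_steps * dwell_s

    def beat_pressure(t_mid: float) -> float:
        step = min(int(t_mid // dwell_s), n_steps - 1)
        return max(p0 - step * step_mmhg, p1)

    t, p, v = _render_beatwise(config, dur, beat_pressure, rng)
    ann = [
        Annotation("ramp_start", 0.0, dur),
        Annotation("ramp_end", float(t[-1]), None),
    ]
    return WaveformRecording(t, p, v, config.sampling_rate, ann)


def generate_experiment(
    config: SimulationConfig,
    rest_duration: float = 30.0,
    bolus_duration: float = 60.0,
    bolus_onset: float = 15.0,
) -> WaveformRecording:
    """Full protocol: rest, 3 adenosine boluses, 3 bradykinin boluses, ramp.

    Each bolus segment opens with its own rest window (the
    return-to-baseline gap between replicate measurements).  Segment
    noise streams are spawned from ``config.seed``, so the annotation
    schedule is independent of the noise realization and the whole
    recording is reproducible bit-for-bit under a fixed seed.
    """
    children = np.random.SeedSequence(config.seed).spawn(8)
    rngs = [np.random.default_rng(c) for c in children]
    segments = [simulate_rest_segment(config, rest_duration, rng=rngs[0])]
    drugs = ["adenosine"] * 3 + ["bradykinin"] * 3
    for i, drug in enumerate(drugs):
        segments.append(
            simulate_bolus_segment(config, bolus_duration, drug,
                                   onset_s=bolus_onset, rng=rngs[1 + i])
        )
    segments.append(simulate_ramp_segment(config, rng=rngs[7]))
    return WaveformRecording.concatenate(segments)
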
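"""Shared test utilities."""

from coroflow import Beat, BeatSeries


def make_beats(velocities, pressures=None, dt=0.7):
    """Build a contiguous BeatSeries from per-beat summary values."""
    if pressures is None:
        pressures = [80.0] * len(velocities)
    return BeatSeries([
        Beat(i * dt, (i + 1) * dt, p, v)
        for i, (v, p) in enumerate(zip(velocities, pressures))
    ])
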
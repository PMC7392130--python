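"""Autoregulation curve construction and breakpoint estimation.

Beat-level (pressure, flow) coordinates are pooled and averaged in
5-mmHg pressure bins.  The lower limit of autoregulation is then found
by a two-segment linear fit: every contiguous split of the ascending
bins into a low-pressure (ischemic) and a high-pressure (plateau)
segment is fitted with a pair of regressions, the best-fitted pair
(minimal pooled residual sum of squares, i.e. maximal global
two-segment R²) is selected, and the breakpoint is the intersection of
its two lines.

Selecting by pooled residuals rather than by each segment's own R² is
deliberate: the autoregulatory plateau is nearly flat, so its
per-segment variance is noise-dominated and its own R² carries almost
no information about fit quality, whereas the pooled residual compares
all candidate splits on one scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .beats import BeatSeries, beats_in_window
from .recording import Annotation

__all__ = [
    "Bin",
    "BinnedPF",
    "LineFit",
    "BreakpointFit",
    "AutoregulationWarning",
    "bin_pressure_flow",
    "fit_line",
    "intersect",
    "fit_breakpoint",
    "analyze_ramp",
]

DEFAULT_BIN_WIDTH = 5.0
DEFAULT_MIN_SEGMENT = 3


class AutoregulationWarning(UserWarning):
    """Raised (as a warning) when a breakpoint fit looks suspect."""


@dataclass
class Bin:
    """One pressure bin of pooled beat coordinates."""

    lower_edge: float     # mmHg, multiple of the bin width
    center: float         # mmHg
    mean_pressure: float  # member-mean pressure (regression abscissa)
    mean_flow: float      # member-mean velocity, cm/s
    count: int

    def to_dict(self) -> dict:
        return {"lower_edge": self.lower_edge, "center": self.center,
                "mean_pressure": self.mean_pressure, "mean_flow": self.mean_flow,
                "count": self.count}


@dataclass
class BinnedPF:
    """Ascending, non-empty pressure bins of a pressure-flow data set."""

    bins: list[Bin]

    def __post_init__(self) -> None:
        edges = [b.lower_edge for b in self.bins]
        if sorted(edges) != edges or len(set(edges)) != len(edges):
            raise ValueError("bins must be sorted ascending with unique lower edges")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def pressures(self) -> np.ndarray:
        return np.array([b.mean_pressure for b in self.bins])

    @property
    def flows(self) -> np.ndarray:
        return np.array([b.mean_flow for b in self.bins])

    @property
    def counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins])

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


@dataclass
class LineFit:
    """Ordinary least-squares line with its coefficient of determination."""

    slope: float       # (cm/s)/mmHg
    intercept: float   # cm/s
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a line fit needs at least 3 points")

    def predict(self, pressure: float) -> float:
        return self.slope * pressure + self.intercept

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r2": self.r_squared, "n": self.n_points}


@dataclass
class BreakpointFit:
    """Two-segment fit of the autoregulation curve and its intersection."""

    ischemic: LineFit      # low-pressure, pressure-dependent limb
    plateau: LineFit       # high-pressure autoregulatory limb
    split_index: int       # bins[:split] -> ischemic, bins[split:] -> plateau
    score: float           # global two-segment R2 = 1 - pooled SSE / pooled SST
    breakpoint_pressure: float  # mmHg
    breakpoint_flow: float      # cm/s
    in_range: bool
    bins: BinnedPF | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "ischemic": self.ischemic.to_dict(),
            "plateau": self.plateau.to_dict(),
            "split_index": self.split_index,
            "score": self.score,
            "breakpoint_pressure": self.breakpoint_pressure,
            "breakpoint_flow": self.breakpoint_flow,
            "in_range": self.in_range,
        }
        if self.bins is not None:
            d["bins"] = [b.to_dict() for b in self.bins.bins]
        return d


# ---------------------------------------------------------------------------

def bin_pressure_flow(beats: BeatSeries, bin_width: float = DEFAULT_BIN_WIDTH) -> BinnedPF:
    """Pool beat (pressure, flow) coordinates into fixed-width pressure bins.

    Bin edges are anchored at multiples of ``bin_width`` with half-open
    intervals ``[k*w, (k+1)*w)``.  Each retained bin reports its members'
    mean pressure, mean flow, and count; empty bins are omitted.
    """
    if len(beats) == 0:
        raise ValueError("cannot bin an empty beat series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    p = beats.pressures
    v = beats.velocities
    keys = np.floor(p / bin_width).astype(np.int64)
    bins = []
    for k in np.unique(keys):
        mask = keys == k
        bins.append(Bin(
            lower_edge=float(k * bin_width),
            center=float((k + 0.5) * bin_width),
            mean_pressure=float(p[mask].mean()),
            mean_flow=float(v[mask].mean()),
            count=int(mask.sum()),
        ))
    return BinnedPF(bins)


def _ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Closed-form (weighted) least squares of y on x.

    Returns ``(slope, intercept, r_squared, sse)``.  If the ordinate has
    zero variance and zero residual the fit is declared perfect
    (R² = 1): a flat plateau is an exactly explained line.
    """
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    xbar = (w * x).sum() / total
    ybar = (w * y).sum() / total
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 1e-12 * max(1.0, xbar * xbar):
        raise ValueError("degenerate abscissa: all pressures identical")
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    sse = float((w * resid ** 2).sum())
    sst = float((w * (y - ybar) ** 2).sum())
    scale = max(1.0, float((w * y * y).sum()))
    if sst <= 1e-12 * scale:
        r2 = 1.0 if sse <= 1e-9 * scale else 0.0
    else:
        r2 = 1.0 - sse / sst
    r2 = min(max(r2, 0.0), 1.0)
    return float(slope), float(intercept), r2, sse


def _fit_bins(bins: list[Bin], weighted: bool):
    x = np.array([b.mean_pressure for b in bins])
    y = np.array([b.mean_flow for b in bins])
    if len(bins) < 3:
        raise ValueError(f"a regression segment needs at least 3 bins, got {len(bins)}")
    w = np.array([b.count for b in bins], dtype=float) if weighted else None
    slope, intercept, r2, sse = _ols(x, y, w)
    return LineFit(slope, intercept, r2, len(bins)), sse


def fit_line(bins, weighted: bool = False) -> LineFit:
    """OLS of bin mean flow on bin mean pressure.

    Unweighted by default (each averaged bin point counts once, as the
    pooled-and-averaged curve suggests); pass ``weighted=True`` to weight
    by per-bin beat counts.
    """
    bins = list(bins.bins) if isinstance(bins, BinnedPF) else list(bins)
    fit, _ = _fit_bins(bins, weighted)
    return fit


def intersect(ischemic: LineFit, plateau: LineFit) -> tuple[float, float]:
    """Intersection point of the two regression lines.

    Raises if the lines are parallel to numerical precision (the
    breakpoint is then undefined).
    """
    dslope = ischemic.slope - plateau.slope
    if abs(dslope) <= 1e-9:
        raise ValueError("regression lines are parallel: breakpoint undefined")
    pressure = (plateau.intercept - ischemic.intercept) / dslope
    flow = ischemic.predict(pressure)
    return float(pressure), float(flow)


def _pooled_sst(bins: list[Bin], weighted: bool) -> float:
    y = np.array([b.mean_flow for b in bins])
    w = np.array([b.count for b in bins], dtype=float) if weighted else np.ones_like(y)
    ybar = (w * y).sum() / w.sum()
    return float((w * (y - ybar) ** 2).sum())


def _iter_splits(bins: list[Bin], min_segment: int, weighted: bool):
    """Yield (split, low_fit, high_fit, total_sse) for every valid split."""
    n = len(bins)
    for split in range(min_segment, n - min_segment + 1):
        low, low_sse = _fit_bins(bins[:split], weighted)
        high, high_sse = _fit_bins(bins[split:], weighted)
        yield split, low, high, low_sse + high_sse


def fit_breakpoint(
    binned: BinnedPF,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    weighted: bool = False,
) -> BreakpointFit:
    """Two-segment regression of the binned pressure-flow curve.

    Enumerates every contiguous partition of the ascending bins into a
    low (ischemic) and a high (plateau) segment of at least
    ``min_segment`` bins each, fits both lines, and keeps the
    best-fitted pair: the split with the minimal pooled residual sum of
    squares (ties resolve to the lower split index).  ``score`` reports
    the global two-segment R², ``1 - pooled SSE / pooled SST``, which
    the selected split maximizes.  The breakpoint is the intersection of
    the two selected lines; ``in_range`` records whether it falls inside
    the observed bin-pressure range.
    """
    bins = sorted(binned.bins, key=lambda b: b.lower_edge)
    n = len(bins)
    if min_segment < 3:
        raise ValueError("min_segment must be at least 3 (2-point lines fit vacuously)")
    if n < 2 * min_segment:
        raise ValueError(
            f"breakpoint fit needs at least {2 * min_segment} bins "
            f"({min_segment} per limb), got {n}"
        )
    best = None
    for split, low, high, sse in _iter_splits(bins, min_segment, weighted):
        if best is None or sse < best[3]:
            best = (split, low, high, sse)
    split, low, high, sse = best
    sst = _pooled_sst(bins, weighted)
    scale = max(1.0, sum(b.mean_flow ** 2 for b in bins))
    if sst <= 1e-12 * scale:
        score = 1.0 if sse <= 1e-9 * scale else 0.0
    else:
        score = min(max(1.0 - sse / sst, 0.0), 1.0)
    try:
        bp_pressure, bp_flow = intersect(low, high)
    except ValueError as err:
        raise ValueError(
            f"{err} (selected split {split}: ischemic slope {low.slope:.6g}, "
            f"plateau slope {high.slope:.6g})"
        ) from err
    pressures = [b.mean_pressure for b in bins]
    in_range = min(pressures) <= bp_pressure <= max(pressures)
    return BreakpointFit(
        ischemic=low, plateau=high, split_index=split, score=score,
        breakpoint_pressure=bp_pressure, breakpoint_flow=bp_flow,
        in_range=in_range, bins=BinnedPF(bins),
    )


def analyze_ramp(
    series: BeatSeries,
    ramp_annotation: Annotation,
    end_s: float | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    weighted: bool = False,
) -> BreakpointFit:
    """Breakpoint analysis of the beats inside the balloon-ramp window.

    The window runs from the annotation onset to ``end_s``, the
    annotation's own duration, or the last beat — whichever is given
    first.  A warning is emitted when the fitted breakpoint falls
    outside the observed pressure range.
    """
    start = ramp_annotation.onset_s
    if end_s is None:
        if ramp_annotation.duration_s is not None:
            end_s = start + ramp_annotation.duration_s
        elif series.beats:
            end_s = series.beats[-1].end_time
        else:
            raise ValueError("ramp window end is undefined and the series is empty")
    window = beats_in_window(series, start, end_s)
    if len(window) == 0:
        raise ValueError("no beats fall inside the ramp window")
    binned = bin_pressure_flow(window, bin_width)
    fit = fit_breakpoint(binned, min_segment=min_segment, weighted=weighted)
    if not fit.in_range:
        warnings.warn(
            f"fitted breakpoint {fit.breakpoint_pressure:.1f} mmHg lies outside the "
            "observed pressure range",
            AutoregulationWarning,
            stacklevel=2,
        )
    return fit
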
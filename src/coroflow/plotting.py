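"""Static plot of the binned pressure-flow curve with its fitted limbs."""

from __future__ import annotations

from pathlib import Path

from .autoregulation import BreakpointFit

__all__ = ["plot_breakpoint"]


def plot_breakpoint(fit: BreakpointFit, path: str | Path) -> None:
    """Save a pressure-flow scatter with both regression lines and the breakpoint."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if fit.bins is None:
        raise ValueError("fit carries no bins to plot")
    p = fit.bins.pressures
    f = fit.bins.flows
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(p, f, c="k", zorder=3, label="5-mmHg bin means")
    lo = np.linspace(p.min(), fit.breakpoint_pressure, 20)
    hi = np.linspace(fit.breakpoint_pressure, p.max(), 20)
    ax.plot(lo, fit.ischemic.slope * lo + fit.ischemic.intercept, "k-",
            label=f"ischemic (R²={fit.ischemic.r_squared:.3f})")
    ax.plot(hi, fit.plateau.slope * hi + fit.plateau.intercept, "k--",
            label=f"plateau (R²={fit.plateau.r_squared:.3f})")
    ax.axvline(fit.breakpoint_pressure, color="tab:red", lw=0.8)
    ax.annotate(f"breakpoint {fit.breakpoint_pressure:.1f} mmHg",
                (fit.breakpoint_pressure, fit.breakpoint_flow),
                textcoords="offset points", xytext=(8, -12))
    ax.set_xlabel("coronary pressure (mmHg)")
    ax.set_ylabel("flow velocity (cm/s)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
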
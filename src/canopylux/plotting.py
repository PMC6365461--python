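"""Optional figures (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .stats import SegmentedFit


def plot_segmented(x, y, fit: SegmentedFit, path=None, xlabel="dose (MJ m$^{-2}$)",
                   ylabel="response"):
    """Scatter plus the fitted two-segment line, breakpoint dashed.

    Returns the matplotlib Axes; saves a PNG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, "o", ms=4, alpha=0.7, color="0.3")
    xs = np.linspace(x.min(), x.max(), 200)
    ys = fit.intercept + fit.slope_left * xs + (fit.slope_right - fit.slope_left) * np.maximum(xs - fit.psi, 0.0)
    ax.plot(xs, ys, color="firebrick")
    ax.axvline(fit.psi, ls="--", color="0.5",
               label=f"$\\psi$ = {fit.psi:.1f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
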
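"""Matplotlib figure helpers (calibration line, 2D histogram, density plot).

Plotting is a pure view over already-computed results; nothing here changes
stored data or statistics.
"""
from __future__ import annotations

import numpy as np

from .calibrate import CalibrationModel, GravimetricComparison
from .ratios import DensityPlot
from .segment import Histogram2D, SeedLocus


def plot_calibration(calib: CalibrationModel, comparison: GravimetricComparison | None = None,
                     ax=None):
    """Calibration points + fitted MD-vs-HU line, optionally the ash line and
    the residual curve on a twin axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if calib.residuals is not None:
        ax.plot(calib.residuals["mean_hu"], calib.residuals["nominal_md"], "o",
                label="phantoms")
        grid = np.linspace(calib.residuals["mean_hu"].min(),
                           calib.residuals["mean_hu"].max(), 50)
    else:
        grid = np.linspace(0, 30000, 50)
    ax.plot(grid, calib.slope * grid + calib.intercept, "-",
            label=f"MD = {calib.slope:.3g}*HU {calib.intercept:+.3g}")
    if comparison is not None:
        ax.plot(comparison.hu_grid,
                comparison.ash_slope * comparison.hu_grid + comparison.ash_intercept,
                "g-", label="ash line")
        ax2 = ax.twinx()
        ax2.plot(comparison.hu_grid, comparison.residual_curve, "r--",
                 label="CT - ash")
        ax2.set_ylabel("residual (mg/cc)")
    ax.set_xlabel("HU")
    ax.set_ylabel("mineral density (mg/cc)")
    ax.legend()
    return ax


def plot_histogram2d(hist: Histogram2D, loci: list[SeedLocus] | None = None, ax=None):
    """Log-count intensity/gradient histogram with optional seed-locus boxes."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots()
    with np.errstate(divide="ignore"):
        img = np.log10(hist.counts.T + 1)
    ax.pcolormesh(hist.intensity_edges, hist.gradient_edges, img, shading="auto")
    if loci:
        for l in loci:
            ax.add_patch(Rectangle(
                (l.intensity_lo, l.gradient_lo),
                l.intensity_hi - l.intensity_lo, l.gradient_hi - l.gradient_lo,
                fill=False, edgecolor="white"))
    ax.set_xlabel("intensity (HU)")
    ax.set_ylabel("gradient magnitude (HU/voxel)")
    return ax


def plot_density(dp: DensityPlot, ax=None):
    """Joint element-element density plot with detected peaks marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    with np.errstate(divide="ignore"):
        ax.pcolormesh(dp.x_edges, dp.y_edges, np.log10(dp.counts.T + 1),
                      shading="auto")
    for i, j in dp.peaks:
        ax.plot(0.5 * (dp.x_edges[i] + dp.x_edges[i + 1]),
                0.5 * (dp.y_edges[j] + dp.y_edges[j + 1]), "r+")
    ax.set_title(dp.character)
    return ax
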
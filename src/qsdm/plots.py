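"""Diagnostic plots: calibration scatter and log-scale biomass maps."""

from __future__ import annotations

import numpy as np


def calibration_plot(result, ax=None):
    """Observed vs predicted class quantiles with the 1:1 reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.class_table
    ax.scatter(t["mean_predicted"], t["observed_quantile"], color="k", zorder=3)
    lims = [
        min(t["mean_predicted"].min(), t["observed_quantile"].min()),
        max(t["mean_predicted"].max(), t["observed_quantile"].max()),
    ]
    ax.plot(lims, lims, "k--", lw=1, label="1:1")
    ax.plot(
        lims,
        [result.intercept + result.slope * x for x in lims],
        color="tab:red",
        lw=1,
        label=f"fit (slope={result.slope:.2f}, r={result.r:.3f})",
    )
    ax.set_xlabel("predicted quantile (g AFDW m$^{-2}$)")
    ax.set_ylabel("observed quantile (g AFDW m$^{-2}$)")
    ax.set_title(f"calibration, $\\tau$ = {result.tau}")
    ax.legend()
    return ax


def biomass_map_plot(biomass, ax=None, log: bool = True):
    """Render a biomass raster, optionally on a log scale (zeros masked)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots()
    data = np.asarray(biomass, dtype=float)
    norm = None
    if log:
        positive = data[np.isfinite(data) & (data > 0)]
        data = np.where(data <= 0, np.nan, data)
        if positive.size:
            norm = LogNorm(vmin=positive.min(), vmax=positive.max())
    im = ax.imshow(data, norm=norm, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="biomass (g AFDW m$^{-2}$)")
    return ax
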
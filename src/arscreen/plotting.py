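"""Basic diagnostic plots for concentration series and fitted curves."""

from __future__ import annotations

import numpy as np

from .hill_fitting import HillFit, hill_response
from .normalization import ConcentrationSeries


def plot_series(
    series: ConcentrationSeries,
    fit: HillFit | None = None,
    threshold: float | None = None,
    ax=None,
):
    """Scatter the well-level responses on a log10 axis; overlay the fit.

    Returns the matplotlib axes.  A horizontal dotted line marks the
    activity threshold when given.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    concs, resps = series.well_level()
    ax.scatter(np.log10(concs), resps, s=12, alpha=0.6, label="wells")
    ax.plot(np.log10(series.concs), series.medians, "k.", ms=8, label="median")
    if fit is not None:
        grid = np.logspace(
            np.log10(series.concs.min()), np.log10(series.concs.max()), 200
        )
        ax.plot(np.log10(grid),
                hill_response(grid, fit.top, fit.log10_ac50, fit.slope),
                "r-", lw=1.5, label="Hill fit")
        ax.axvline(fit.log10_ac50, color="r", ls="--", lw=0.8)
    if threshold is not None:
        ax.axhline(threshold, color="crimson", ls=":", lw=1)
    ax.set_xlabel("log10 concentration (µM)")
    ax.set_ylabel(
        "resp (log2 fold)" if series.mode == "agonist" else "resp (%)"
    )
    ax.set_title(f"{series.chemical_id} [{series.mode}/{series.biogroup}]",
                 fontsize=9)
    return ax
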
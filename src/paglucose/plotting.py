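"""Optional figures: calibration line and Clarke error grid.

Both functions draw onto a supplied or fresh matplotlib Axes and return it;
callers decide about saving/showing.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .calibration import GlucoseCalibrationResults
from .ega import clarke_zone

__all__ = ["plot_calibration", "plot_clarke_grid"]


def plot_calibration(
    features,
    results: GlucoseCalibrationResults,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Scatter per-class mean window integrals vs concentration per day,
    with each day's least-squares line and r in the legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for day, df in features.groupby("day"):
        per_class = df.groupby("glucose_mgdl")["integral"].mean().sort_index()
        conc = per_class.index.to_numpy(dtype=float)
        cal = results.days[int(day)]
        ax.plot(conc, per_class.to_numpy(), "o", label=f"day {day} (r = {cal.r:.3f})")
        ax.plot(conc, cal.slope * conc + cal.intercept, "-", alpha=0.6)
    ax.set_xlabel("glucose (mg/dL)")
    ax.set_ylabel("window integral (µV·kHz)")
    ax.legend()
    return ax


def plot_clarke_grid(
    reference_mgdl,
    predicted_mgdl,
    ax: "plt.Axes | None" = None,
    max_mgdl: float = 400.0,
) -> "plt.Axes":
    """Clarke grid with shaded zone regions and the prediction points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    vals = np.arange(1.0, max_mgdl + 1.0, 2.0)
    zone_codes = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}
    img = np.empty((vals.size, vals.size))
    for i, r in enumerate(vals):
        for j, p in enumerate(vals):
            img[j, i] = zone_codes[clarke_zone(r, p)]
    ax.imshow(
        img,
        origin="lower",
        extent=(vals[0], vals[-1], vals[0], vals[-1]),
        cmap="Pastel1",
        vmin=0,
        vmax=8,
        aspect="equal",
    )
    for label, (x, y) in {
        "A": (200, 200), "B": (300, 150), "C": (150, 330),
        "D": (320, 120), "E": (60, 300),
    }.items():
        if x <= max_mgdl and y <= max_mgdl:
            ax.text(x, y, label, fontsize=12, ha="center")
    ax.plot(reference_mgdl, predicted_mgdl, "k.", ms=6)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    return ax
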
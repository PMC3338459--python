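"""Presentation plots: supply time series against alongshore wind stress."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ocean import WindSeries
from .recruitment import SupplySeries


def plot_supply_panels(wind: WindSeries, observed: SupplySeries | None,
                       predicted: dict[str, SupplySeries], path) -> None:
    """Stacked panels: wind stress (+ observed supply) on top, one panel per
    predicted series below."""
    n = 1 + len(predicted)
    fig, axes = plt.subplots(n, 1, figsize=(9, 2.2 * n), sharex=False)
    if n == 1:
        axes = [axes]
    ax = axes[0]
    ax.plot(wind.t / 24.0, wind.tau_y, "k--", lw=0.8, label="wind stress")
    ax.set_ylabel(r"$\tau_y$ (N m$^{-2}$)")
    ax.axhline(0, color="0.7", lw=0.5)
    if observed is not None:
        ax2 = ax.twinx()
        ax2.plot(range(observed.dates.size), observed.counts, "C0-", lw=1.0)
        ax2.set_ylabel("observed supply (d$^{-1}$)")
    ax.legend(loc="upper right", fontsize=8)
    for axp, (label, series) in zip(axes[1:], predicted.items()):
        axp.plot(range(series.dates.size), series.counts, lw=1.0)
        axp.set_ylabel("supply (d$^{-1}$)")
        axp.set_title(label, fontsize=9)
    axes[-1].set_xlabel("day of run")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
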
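"""Diagnostic plots: NSD time series and 14-day elevation profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .altitude import ElevationSeries  # noqa: E402
from .displacement import DisplacementSeries, MigrationEvent  # noqa: E402


def plot_nsd(
    series: DisplacementSeries,
    event: MigrationEvent | None,
    path,
) -> None:
    """Net-squared-displacement plot with detected migration dates."""
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(series.fix_t, series.fix_nsd, ".", ms=1.5, color="0.7")
    ax.plot(series.smoothed.index, series.smoothed, color="C0", lw=1.5)
    if event is not None:
        for d, c in (
            (event.spring_start, "C2"),
            (event.spring_end, "C2"),
            (event.fall_start, "C3"),
            (event.fall_end, "C3"),
        ):
            if d is not None:
                ax.axvline(d, color=c, ls="--", lw=0.8)
    ax.set_ylabel("NSD (km$^2$)")
    ax.set_title(f"{series.animal_id}")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_elevation(series: ElevationSeries, path) -> None:
    """Daily and 14-day moving-mean elevation profile."""
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(series.daily_mean.index, series.daily_mean, ".", ms=2,
            color="0.7", label="daily mean")
    ax.plot(series.moving_mean.index, series.moving_mean, color="C0",
            lw=1.5, label="14-day moving mean")
    ax.axhline(series.winter_median_m, color="C3", ls=":",
               label="winter median")
    ax.axhline(series.summer_median_m, color="C2", ls=":",
               label="summer median")
    ax.set_ylabel("elevation (m)")
    ax.set_title(f"{series.animal_id}")
    ax.legend(fontsize=7, ncol=2)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
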
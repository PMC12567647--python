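"""Static figures: concordance histogram, per-cycle temperature plots,
and a luteal-profile gallery.

Styling is deliberately minimal; the figures are diagnostic aids, not a
publication surface.  Per-cycle plots mark the LH surge day with a
vertical line and the temperature-derived ovulation day with a dot.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cycle_model import Cycle

__all__ = ["plot_diff_histogram", "plot_cycle", "plot_luteal_gallery", "render_report"]


def plot_diff_histogram(histogram: Mapping[int, int], path: str | Path) -> Path:
    """Bar chart of the per-cycle (a_edo − surge_day) differences."""
    path = Path(path)
    diffs = sorted(histogram)
    counts = [histogram[d] for d in diffs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(diffs, counts, color="tab:blue")
    ax.set_xlabel("A-EDO − LH surge day (days)")
    ax.set_ylabel("Cycles")
    ax.set_xticks(diffs)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def plot_cycle(
    cycle: Cycle,
    surge_day: int | None,
    a_edo: int | None,
    path: str | Path,
) -> Path:
    """Daily temperatures with the surge day (line) and A-EDO (dot)."""
    path = Path(path)
    temps = cycle.temperatures
    days = np.arange(1, cycle.length + 1)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(days, temps, "o-", ms=3, color="0.3", lw=0.8)
    if surge_day is not None:
        ax.axvline(surge_day, color="tab:blue", lw=1.5, label="LH surge")
    if a_edo is not None:
        rec = cycle.records[a_edo - 1]
        y = rec.temperature
        if y is None:
            finite = temps[~np.isnan(temps)]
            y = float(finite.mean()) if finite.size else 36.5
        ax.plot([a_edo], [y], "o", ms=9, color="tab:green", label="A-EDO")
    ax.set_xlabel("Cycle day")
    ax.set_ylabel("Temperature (°C)")
    ax.set_title(cycle.cycle_id)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def plot_luteal_gallery(
    cycles: Iterable[Cycle],
    profiles: pd.DataFrame,
    anchors: Mapping[str, int],
    path: str | Path,
    group_by: str = "amplitude_class",
    per_group: int = 3,
) -> Path:
    """Grid of temperature curves grouped by a luteal profile class."""
    path = Path(path)
    by_id = {c.cycle_id: c for c in cycles}
    groups = []
    for cls, grp in profiles.groupby(group_by, sort=True):
        ids = [cid for cid in grp["cycle_id"] if cid in by_id][:per_group]
        if ids:
            groups.append((str(cls), ids))
    nrows = max(1, len(groups))
    ncols = per_group
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows), squeeze=False)
    for i, (cls, ids) in enumerate(groups):
        for j in range(ncols):
            ax = axes[i][j]
            if j >= len(ids):
                ax.axis("off")
                continue
            c = by_id[ids[j]]
            days = np.arange(1, c.length + 1)
            ax.plot(days, c.temperatures, "-", lw=0.9, color="0.3")
            anchor = anchors.get(c.cycle_id)
            if anchor is not None:
                ax.axvline(anchor, color="tab:blue", lw=1.2)
            ax.set_title(f"{cls}: {c.cycle_id}", fontsize=8)
            ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def render_report(
    validation_dir: str | Path,
    cycles: list[Cycle],
    outdir: str | Path,
    max_cycle_plots: int | None = None,
) -> list[Path]:
    """Produce all figures from a validation output directory.

    Requires ``concordance.csv``, ``histogram.csv`` and
    ``luteal_profiles.csv`` under ``validation_dir``; raises
    FileNotFoundError naming the first missing file.
    """
    vdir = Path(validation_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for fname in ("concordance.csv", "histogram.csv", "luteal_profiles.csv"):
        if not (vdir / fname).exists():
            raise FileNotFoundError(f"missing validation output: {vdir / fname}")

    hist_df = pd.read_csv(vdir / "histogram.csv")
    histogram = dict(zip(hist_df["diff"].astype(int), hist_df["count"].astype(int)))
    if histogram:
        written.append(plot_diff_histogram(histogram, outdir / "diff_histogram.png"))

    conc = pd.read_csv(vdir / "concordance.csv")
    by_id = {c.cycle_id: c for c in cycles}
    rows = conc.itertuples()
    if max_cycle_plots is not None:
        rows = list(conc.itertuples())[:max_cycle_plots]
    for row in rows:
        c = by_id.get(str(row.cycle_id))
        if c is None:
            continue
        written.append(
            plot_cycle(c, int(row.surge_day), int(row.a_edo), outdir / f"cycle_{c.cycle_id}.png")
        )

    profiles = pd.read_csv(vdir / "luteal_profiles.csv")
    if len(profiles):
        anchors = dict(zip(profiles["cycle_id"].astype(str), profiles["anchor_day"].astype(int)))
        for group in ("amplitude_class", "rise_class", "fluctuation_class"):
            written.append(
                plot_luteal_gallery(
                    cycles, profiles, anchors, outdir / f"luteal_{group}.png", group_by=group
                )
            )
    return written
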
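"""Figure rendering on top of the analysis numbers.

Every figure is cosmetics over numbers that are computed (and tested)
elsewhere; these functions only arrange matplotlib artists. They always
write the backing numbers as CSV next to the image.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .analysis import SeriesSummary, fit_curves  # noqa: E402

__all__ = ["plot_box", "plot_dynamic", "plot_fits"]


def _save(fig, path: Path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_box(summary: SeriesSummary, path) -> None:
    """Per-date box plot of one trait."""
    path = Path(path)
    frame = summary.per_date
    fig, ax = plt.subplots(figsize=(max(4, len(frame) * 0.9), 4))
    stats = [
        {"med": row["median"], "q1": row["q1"], "q3": row["q3"],
         "whislo": row["min"], "whishi": row["max"],
         "fliers": summary.outliers.get(date, []), "label": str(date)}
        for date, row in frame.iterrows()
    ]
    ax.bxp(stats, showfliers=True)
    ax.set_ylabel(summary.trait)
    ax.tick_params(axis="x", rotation=45)
    frame.to_csv(path.with_suffix(".csv"))
    _save(fig, path)


def plot_dynamic(summary: SeriesSummary, path) -> None:
    """Mean/max trend of one trait over dates."""
    path = Path(path)
    frame = summary.per_date
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame.index, frame["mean"], marker="o", label="mean")
    ax.plot(frame.index, frame["max"], marker="s", label="max")
    ax.set_ylabel(summary.trait)
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    frame.to_csv(path.with_suffix(".csv"))
    _save(fig, path)


def plot_fits(x, y, path) -> None:
    """Scatter plus all fitted families; best R² in the title, RMSE in the
    legend."""
    import numpy as np
    import pandas as pd

    path = Path(path)
    results, best = fit_curves(x, y)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=12, color="k", zorder=3)
    grid = np.linspace(np.min(x), np.max(x), 200)
    rows = []
    for result in results:
        if result.note is not None:
            continue
        ax.plot(grid, result.predict(grid),
                label=f"{result.equation()} (RMSE {result.rmse:.4f})")
        rows.append({"family": result.family, "rmse": result.rmse,
                     "r_squared": result.r_squared,
                     "best": result in best})
    ax.set_title(f"best R² = {max(r.r_squared for r in best):.2f}")
    ax.legend(fontsize=7)
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    _save(fig, path)
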
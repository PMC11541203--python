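"""Growth and circularity curves: mean +/- SD per cell line per day.

Each image is one observation.  SDs are sample standard deviations
(n-1 denominator), reported as 0 for singleton groups; no interpolation
is done across missing days -- curves carry observed timepoints only.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .image_io import ImageRecord
from .morphometry import MorphometryResult

SUMMARY_COLUMNS = [
    "cell_line",
    "day",
    "n_images",
    "mean_area",
    "sd_area",
    "mean_circularity",
    "sd_circularity",
]


def summarize(results: Iterable[tuple[ImageRecord, MorphometryResult]]) -> pd.DataFrame:
    """Group per-image morphometry by (cell_line, day).

    Returns one row per observed (cell_line, day) pair, sorted by cell
    line then day, with mean and sample SD of area and circularity.
    All results must share units (px vs mm).
    """
    rows = [
        {
            "cell_line": rec.cell_line,
            "day": rec.day,
            "area": res.area,
            "circularity": res.circularity,
            "units": res.units,
        }
        for rec, res in results
    ]
    if not rows:
        raise ValidationError("no results to summarize")
    df = pd.DataFrame(rows)
    return summarize_frame(df)


def summarize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """As :func:`summarize`, for a DataFrame with columns
    cell_line, day, area, circularity and optionally units."""
    required = {"cell_line", "day", "area", "circularity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("no results to summarize")
    if "units" in df.columns and df["units"].nunique() > 1:
        raise ValidationError(
            f"mixed units in results: {sorted(df['units'].unique())}; "
            "measure all images with the same calibration"
        )
    grouped = (
        df.groupby(["cell_line", "day"], sort=True)
        .agg(
            n_images=("area", "size"),
            mean_area=("area", "mean"),
            sd_area=("area", lambda s: s.std(ddof=1)),
            mean_circularity=("circularity", "mean"),
            sd_circularity=("circularity", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    grouped[["sd_area", "sd_circularity"]] = grouped[["sd_area", "sd_circularity"]].fillna(0.0)
    return grouped[SUMMARY_COLUMNS]


def growth_rate_profile(
    summary: pd.DataFrame, cell_line: str
) -> list[tuple[tuple[int, int], float]]:
    """Mean-area change per day between consecutive observed timepoints.

    Returns ``[((day_i, day_{i+1}), rate), ...]`` for the given line.
    """
    sub = summary[summary["cell_line"] == cell_line].sort_values("day")
    if sub.empty:
        raise KeyError(f"unknown cell line: {cell_line!r}")
    if len(sub) < 2:
        raise ValidationError(f"need >= 2 timepoints for {cell_line!r}, got {len(sub)}")
    days = sub["day"].to_numpy()
    areas = sub["mean_area"].to_numpy()
    return [
        ((int(d0), int(d1)), float((a1 - a0) / (d1 - d0)))
        for d0, d1, a0, a1 in zip(days[:-1], days[1:], areas[:-1], areas[1:])
    ]


def plot_growth_curves(summary: pd.DataFrame, out_dir) -> list[str]:
    """Write area-vs-day and circularity-vs-day plots with +/-SD bands.

    Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    specs = [
        ("mean_area", "sd_area", "area", "Organoid area"),
        ("mean_circularity", "sd_circularity", "circularity", "Circularity C = 4πA/P²"),
    ]
    for mean_col, sd_col, stem, title in specs:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for line, sub in summary.groupby("cell_line"):
            sub = sub.sort_values("day")
            ax.errorbar(
                sub["day"], sub[mean_col], yerr=sub[sd_col],
                marker="o", markersize=3, capsize=2, label=str(line),
            )
        ax.set_xlabel("day")
        ax.set_ylabel(mean_col.replace("mean_", ""))
        ax.set_title(f"{title} (mean ± SD)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{stem}_vs_day.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
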
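"""Aggregation of per-series fits into result tables and figures.

Tables are the tested surface: a tidy height table (one row per fitted
series joined to its study metadata) and grouped summaries (count, mean
height, share positive per treatment class or other grouping).  Figures —
per-treatment-class panels of fitted curves with dose-levels centralised
at zero, and dot plots of curve heights with a zero reference line — are
artifacts rendered from those tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .database import Database
from .emax import CurveHeight
from .series import AnalysisSeries

__all__ = [
    "height_table",
    "grouped_height_summary",
    "centralised_levels",
    "plot_curve_panels",
    "plot_height_dots",
]

HEIGHT_COLUMNS = [
    "study_id", "series_id", "outcome", "method", "height_mean",
    "interval_lo", "interval_hi", "treatment_class", "disease", "design_class",
]


def height_table(
    fits: Sequence[tuple[AnalysisSeries, CurveHeight, str]],
    db: Database,
) -> pd.DataFrame:
    """One row per fitted series — height summaries joined to study
    metadata.  ``fits`` holds (series, height, method) triples; a series
    whose study is missing from the database is an error listing the
    offenders."""
    known = {s.study_id: s for s in db.studies}
    missing = sorted({s.study_id for s, _, _ in fits} - set(known))
    if missing:
        raise ValueError(f"series reference studies absent from database: {missing}")
    rows = []
    for series, height, method in fits:
        if method not in ("mle", "bayes"):
            raise ValueError(f"unknown method {method!r}")
        meta = known[series.study_id]
        if not (-1.0 <= height.mean <= 1.0):
            raise ValueError(f"height outside [-1, 1] for {series.series_id}")
        rows.append({
            "study_id": series.study_id,
            "series_id": series.series_id,
            "outcome": series.outcome,
            "method": method,
            "height_mean": height.mean,
            "interval_lo": height.interval_lo,
            "interval_hi": height.interval_hi,
            "treatment_class": meta.treatment_class,
            "disease": meta.disease,
            "design_class": meta.design_class,
        })
    return pd.DataFrame(rows, columns=HEIGHT_COLUMNS)


def grouped_height_summary(records: pd.DataFrame, group_by: str = "treatment_class") -> pd.DataFrame:
    """Per-group count, mean height and share of positive heights,
    split by outcome.  Counts conserve the input row count."""
    if len(records) == 0:
        raise ValueError("no height records to summarise")
    if group_by not in records.columns:
        raise KeyError(f"unknown grouping field {group_by!r}")
    keys = [group_by] if group_by == "outcome" else [group_by, "outcome"]
    out = (
        records.groupby(keys, sort=True)
        .agg(
            n_series=("height_mean", "size"),
            mean_height=("height_mean", "mean"),
            share_positive=("height_mean", lambda h: float(np.mean(h > 0))),
        )
        .reset_index()
    )
    return out


def centralised_levels(levels: Sequence[int], max_shown: int = 9) -> np.ndarray:
    """Presentation transform for curve panels: subtract the mean level,
    and when more than ``max_shown`` levels are present keep the middle
    ``max_shown`` (for K levels, levels ceil((K-m)/2)+1 .. +m)."""
    arr = np.asarray(levels, dtype=float)
    K = arr.size
    centred = arr - arr.mean()
    if K <= max_shown:
        return centred
    start = int(np.ceil((K - max_shown) / 2))
    return centred[start:start + max_shown]


def _treatment_panels(frame: pd.DataFrame) -> list[str]:
    return sorted(frame["treatment_class"].unique())


def plot_curve_panels(
    curves: pd.DataFrame,
    out_path: str | Path,
    outcome: str = "DLT",
    max_shown: int = 9,
) -> Path:
    """One panel per treatment class; each fitted curve drawn over its
    centralised dose-levels.

    ``curves`` is tidy with columns series_id, treatment_class, level,
    prob (one row per series-level, e.g. from
    :func:`dosemono.inference.fitted_curve` results).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = _treatment_panels(curves)
    if not classes:
        raise ValueError("no curves to plot")
    ncol = min(3, len(classes))
    nrow = int(np.ceil(len(classes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharey=True)
    for ax in axes.ravel():
        ax.set_visible(False)
    for ax, cls in zip(axes.ravel(), classes):
        ax.set_visible(True)
        sub = curves[curves["treatment_class"] == cls]
        for _, grp in sub.groupby("series_id"):
            grp = grp.sort_values("level")
            x = centralised_levels(grp["level"].to_numpy(), max_shown)
            start = (len(grp) - len(x)) // 2 if len(grp) > len(x) else 0
            y = grp["prob"].to_numpy()[start:start + len(x)]
            ax.plot(x, y, lw=0.8, alpha=0.6, color="tab:blue")
        ax.set_title(cls, fontsize=9)
        ax.set_ylim(0, 1)
        ax.set_xlabel("dose-level (centred)")
        ax.set_ylabel(f"Pr({outcome})")
    fig.suptitle(f"Fitted dose-{outcome} curves")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_height_dots(records: pd.DataFrame, out_path: str | Path) -> Path:
    """Dot plot of curve heights by treatment class, DLT and OR
    side-by-side, dashed zero reference line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(records) == 0:
        raise ValueError("no height records to plot")
    bad = records[(records["height_mean"] < -1) | (records["height_mean"] > 1)]
    if len(bad):
        raise ValueError(f"heights outside [-1, 1]: {bad['series_id'].tolist()}")

    classes = _treatment_panels(records)
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(classes) + 2))
    offset = {"DLT": -0.15, "OR": 0.15}
    color = {"DLT": "tab:red", "OR": "tab:blue"}
    rng = np.random.default_rng(0)  # presentation jitter only
    for yi, cls in enumerate(classes):
        for outcome in ("DLT", "OR"):
            sub = records[(records["treatment_class"] == cls)
                          & (records["outcome"] == outcome)]
            if len(sub) == 0:
                continue
            jitter = rng.uniform(-0.06, 0.06, len(sub))
            ax.scatter(sub["height_mean"], yi + offset[outcome] + jitter,
                       s=12, alpha=0.7, color=color[outcome],
                       label=outcome if yi == 0 else None)
    ax.axvline(0.0, color="red", ls="--", lw=1)
    ax.set_yticks(range(len(classes)), classes, fontsize=8)
    ax.set_xlabel("curve height (Pr at highest dose − Pr at lowest)")
    ax.set_xlim(-1, 1)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
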
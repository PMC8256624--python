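"""End-to-end glue: database -> analysis series -> fits -> height table."""

from __future__ import annotations

import pandas as pd

from .database import Database
from .inference import fit_bayes, fit_mle, fitted_curve, height_of_fit
from .reporting import height_table
from .series import AnalysisSeries, make_analysis_series

__all__ = ["build_all_series", "fit_all_series", "series_to_frame"]


def build_all_series(db: Database, outcome: str) -> list[AnalysisSeries]:
    """Analysis series for one outcome across every study in the database."""
    out: list[AnalysisSeries] = []
    for study in db.studies:
        out.extend(make_analysis_series(study.study_id, db.records_for(study.study_id), outcome))
    return out


def series_to_frame(series_list: list[AnalysisSeries]) -> pd.DataFrame:
    """Flatten series to a tidy table (one row per series-level)."""
    rows = []
    for s in series_list:
        for p in s.points:
            rows.append({
                "study_id": s.study_id, "series_id": s.series_id,
                "outcome": s.outcome, "level": p.level,
                "dose_label": p.dose.label, "n": p.n, "events": p.events,
                "fittable": s.fittable,
            })
    return pd.DataFrame(rows, columns=[
        "study_id", "series_id", "outcome", "level", "dose_label",
        "n", "events", "fittable",
    ])


def fit_all_series(
    db: Database,
    series_list: list[AnalysisSeries],
    method: str = "bayes",
    seed: int = 0,
):
    """Fit every fittable series; returns (height table, fits, curve table).

    Bayesian fits get per-series seeds derived deterministically from
    ``seed``.  MLE failures are recorded (row omitted from the height
    table) rather than raised.
    """
    fits = []
    triples = []
    curve_rows = []
    meta = {s.study_id: s for s in db.studies}
    for i, series in enumerate(series_list):
        if not series.fittable:
            continue
        if method == "bayes":
            fit = fit_bayes(series, seed=int((seed * 9973 + i) % (2**31 - 1)))
        elif method == "mle":
            fit = fit_mle(series)
            if not fit.converged:
                fits.append(fit)
                continue
        else:
            raise ValueError(f"unknown method {method!r}")
        fits.append(fit)
        height = height_of_fit(fit, series.levels)
        triples.append((series, height, method))
        curve = fitted_curve(fit, series.levels)
        for lvl, prob in zip(curve["levels"], curve["mean"]):
            curve_rows.append({
                "series_id": series.series_id, "outcome": series.outcome,
                "treatment_class": meta[series.study_id].treatment_class,
                "level": float(lvl), "prob": float(prob),
            })
    heights = height_table(triples, db)
    curves = pd.DataFrame(curve_rows, columns=[
        "series_id", "outcome", "treatment_class", "level", "prob",
    ])
    return heights, fits, curves
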
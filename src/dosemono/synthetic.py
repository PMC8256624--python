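"""Simulated dose-finding trial databases with known ground-truth curves.

Each simulated study gets a dose set (an escalating single-agent ladder
or, for a configurable share of studies, a partially ordered two-agent
grid), true Emax curves for toxicity and response on the ordinal
dose-level scale, per-dose cohort sizes, and binomially drawn event
counts.  Defaults emulate the landscape of published dose-escalation
trials: around four dose-levels per series (quartiles 2 and 5), cohorts
of three to six patients, monotone-increasing true toxicity curves, and
true response curves that are flat for most studies.  Everything is a
pure function of (spec, seed).

For partially ordered dose sets the latent dose strength driving the
binomial draws is the dose's depth in the partial order (the length of
the longest chain ending at it), so outcomes remain consistent across
the series that share a dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np
import pandas as pd

from .database import Database, DoseOutcomeRecord, StudyMeta
from .emax import EmaxParams, curve_height, emax_prob
from .inference import fit_bayes, fit_mle, height_of_fit
from .series import make_analysis_series

__all__ = [
    "ScenarioSpec",
    "TruthRecord",
    "sample_database",
    "literature_scenario",
    "recovery_experiment",
    "summarize_recovery",
]

# manuscript-level label frequencies emulating the published landscape
TREATMENT_CLASSES = (
    ("Inhibitor", 0.37),
    ("Chemotherapy", 0.33),
    ("Chemotherapy + inhibitor", 0.11),
    ("Monoclonal antibody", 0.05),
    ("Immunomodulatory", 0.03),
    ("Radiotherapy", 0.03),
    ("Immunomodulatory + chemotherapy", 0.02),
    ("Oncolytic virus", 0.02),
    ("Radiopharmaceutical + inhibitor", 0.02),
    ("Antibody-drug conjugate", 0.01),
    ("Cytokine", 0.01),
)
DISEASES = (
    ("Solid tumours", 0.31), ("Breast cancer", 0.09),
    ("Gastrointestinal cancer", 0.08), ("AML", 0.07),
    ("Lung cancer", 0.07), ("Lymphoma", 0.07),
    ("Multiple myeloma", 0.06), ("Glioma", 0.06),
    ("Melanoma", 0.05), ("Mixed haematological cancers", 0.05),
    ("Head and neck cancer", 0.05), ("Sarcoma", 0.04),
)
YEARS = ((2008, 0.11), (2009, 0.08), (2010, 0.08), (2011, 0.17),
         (2012, 0.23), (2013, 0.14), (2014, 0.19))
# modified-Fibonacci style escalation factors
ESCALATION = np.array([1.0, 2.0, 3.3, 5.0, 7.0, 9.0, 12.0, 16.0, 21.0, 27.0, 35.0])


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a simulated landscape of dose-finding trials.

    ``dose_count_probs`` is the distribution of dose-levels per study,
    chosen so the series-size summary reproduces a median of 4 with
    quartiles (2, 5).  Toxicity truths are monotone increasing with
    curve heights uniform on ``dlt_height_range``; response truths are
    flat except for a ``or_frac_positive`` minority with heights on
    ``or_height_range``.  ``frac_combination`` of studies get a
    partially ordered two-agent dose set (a crossed pair under a joint
    escalation, or a diamond).
    """

    n_studies: int = 100
    dose_count_probs: dict[int, float] = field(default_factory=lambda: {
        2: 0.30, 3: 0.15, 4: 0.22, 5: 0.18, 6: 0.08, 7: 0.04, 8: 0.03,
    })
    cohort_sizes: tuple[int, ...] = (3, 4, 5, 6)
    frac_combination: float = 0.15
    or_reported_prob: float = 0.60
    dlt_p_lo_range: tuple[float, float] = (0.02, 0.15)
    dlt_height_range: tuple[float, float] = (0.10, 0.50)
    or_flat_range: tuple[float, float] = (0.05, 0.35)
    or_frac_positive: float = 0.15
    or_height_range: tuple[float, float] = (0.10, 0.40)
    hill_range: tuple[float, float] = (0.8, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if abs(sum(self.dose_count_probs.values()) - 1.0) > 1e-9:
            raise ValueError("dose_count_probs must sum to 1")
        if any(k < 2 for k in self.dose_count_probs):
            raise ValueError("dose counts must be >= 2")
        if not (0.0 <= self.frac_combination <= 1.0):
            raise ValueError("frac_combination must be in [0, 1]")
        if not all(c >= 1 for c in self.cohort_sizes):
            raise ValueError("cohort sizes must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one study and outcome: the generating curve and
    its height over the study's ordinal levels."""

    study_id: str
    outcome: str
    params: EmaxParams
    true_height: float
    n_levels: int


def literature_scenario(seed: int = 20080) -> ScenarioSpec:
    """The packaged default landscape: ~100 studies, monotone toxicity
    truths (median height around 0.3), flat response truths with a small
    positive minority, metadata drawn with realistic frequencies."""
    return ScenarioSpec(seed=seed)


# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, table) -> object:
    labels = [t[0] for t in table]
    probs = np.array([t[1] for t in table], dtype=float)
    probs /= probs.sum()
    return labels[rng.choice(len(labels), p=probs)]


def _truth_with_height(
    rng: np.random.Generator, K: int, p_lo: float, height: float,
    hill_range: tuple[float, float],
) -> EmaxParams:
    """A monotone truth whose height over levels 1..K equals ``height``
    (clipped so the ceiling stays below 0.95)."""
    ed50 = rng.uniform(1.0, K)
    hill = rng.uniform(*hill_range)
    if height == 0.0:
        return EmaxParams(p_lo, p_lo, ed50, hill)
    shape = EmaxParams(0.0, 1.0, ed50, hill)
    span = emax_prob(shape, float(K)) - emax_prob(shape, 1.0)
    p_hi = min(p_lo + height / span, 0.95)
    return EmaxParams(p_lo, p_hi, ed50, hill)


def _sample_dlt_truth(rng: np.random.Generator, K: int, spec: ScenarioSpec) -> EmaxParams:
    p_lo = rng.uniform(*spec.dlt_p_lo_range)
    height = rng.uniform(*spec.dlt_height_range)
    return _truth_with_height(rng, K, p_lo, height, spec.hill_range)


def _sample_or_truth(rng: np.random.Generator, K: int, spec: ScenarioSpec) -> EmaxParams:
    if rng.uniform() < spec.or_frac_positive:
        p_lo = rng.uniform(0.05, 0.25)
        height = rng.uniform(*spec.or_height_range)
        return _truth_with_height(rng, K, p_lo, height, spec.hill_range)
    p = rng.uniform(*spec.or_flat_range)
    return EmaxParams(p, p, rng.uniform(1.0, K), rng.uniform(*spec.hill_range))


def _single_agent_doses(rng: np.random.Generator, K: int) -> list[tuple[str, dict, int]]:
    """(label, components, depth) triples for an escalating ladder."""
    base = float(rng.choice([10, 25, 50, 100]))
    return [
        (f"d{k + 1}", {"drugA": base * ESCALATION[k]}, k + 1)
        for k in range(K)
    ]


def _combination_doses(rng: np.random.Generator, K: int) -> list[tuple[str, dict, int]]:
    """A two-agent dose set containing at least one incomparable pair.

    Either the crossed-pair topology — (a1,b2) and (a2,b1) both below
    (a2,b2) — or a diamond (a1,b1) < {(a2,b1), (a1,b2)} < (a2,b2), each
    optionally extended by further joint escalations.  Depth is the
    length of the longest chain ending at the dose.
    """
    a = 10.0 * ESCALATION
    b = 50.0 * ESCALATION
    doses: list[tuple[str, dict, int]] = []
    if rng.uniform() < 0.5:  # crossed pair
        doses.append(("d1", {"drugA": a[0], "drugB": b[1]}, 1))
        doses.append(("d2", {"drugA": a[1], "drugB": b[0]}, 1))
        doses.append(("d3", {"drugA": a[1], "drugB": b[1]}, 2))
        top_depth, ai, bi = 2, 1, 1
    else:  # diamond
        doses.append(("d1", {"drugA": a[0], "drugB": b[0]}, 1))
        doses.append(("d2", {"drugA": a[1], "drugB": b[0]}, 2))
        doses.append(("d3", {"drugA": a[0], "drugB": b[1]}, 2))
        doses.append(("d4", {"drugA": a[1], "drugB": b[1]}, 3))
        top_depth, ai, bi = 3, 1, 1
    # extend with joint escalations up to roughly K doses
    k = len(doses)
    while k < K:
        ai, bi = ai + 1, bi + 1
        top_depth += 1
        k += 1
        doses.append((f"d{k}", {"drugA": a[ai], "drugB": b[bi]}, top_depth))
    return doses


def sample_database(spec: ScenarioSpec) -> tuple[Database, list[TruthRecord]]:
    """Simulate a database of dose-finding trials with known truths.

    Per study: a dose set with depths, true toxicity and response curves,
    cohort sizes, and events drawn Binomial(n, p(depth)).  Deterministic
    in ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    counts = sorted(spec.dose_count_probs)
    probs = np.array([spec.dose_count_probs[k] for k in counts])

    studies: list[StudyMeta] = []
    records: list[DoseOutcomeRecord] = []
    truths: list[TruthRecord] = []

    for i in range(spec.n_studies):
        sid = f"S{i + 1:03d}"
        treatment = _pick(rng, TREATMENT_CLASSES)
        meta = StudyMeta(
            study_id=sid,
            year=int(_pick(rng, YEARS)),
            design_class="model_based" if rng.uniform() < 0.74 else "rule_based",
            disease_class=str(_pick(rng, (
                ("non_haematological", 0.71), ("haematological", 0.26),
                ("both", 0.02), ("undisclosed", 0.01),
            ))),
            disease=str(_pick(rng, DISEASES)),
            treatment_class=str(treatment),
            contains_chemotherapy=("hemo" in str(treatment)) or rng.uniform() < 0.25,
        )
        studies.append(meta)

        K = int(counts[rng.choice(len(counts), p=probs)])
        is_combo = rng.uniform() < spec.frac_combination and K >= 3
        doses = _combination_doses(rng, K) if is_combo else _single_agent_doses(rng, K)
        max_depth = max(d for _, _, d in doses)

        dlt_truth = _sample_dlt_truth(rng, max_depth, spec)
        or_truth = _sample_or_truth(rng, max_depth, spec)
        or_reported = rng.uniform() < spec.or_reported_prob
        levels = list(range(1, max_depth + 1)) if max_depth >= 2 else [1, 2]
        truths.append(TruthRecord(sid, "DLT", dlt_truth,
                                  curve_height(dlt_truth, levels), max_depth))
        if or_reported:
            truths.append(TruthRecord(sid, "OR", or_truth,
                                      curve_height(or_truth, levels), max_depth))

        for label, components, depth in doses:
            n_dlt = int(rng.choice(spec.cohort_sizes))
            p_tox = emax_prob(dlt_truth, float(depth))
            events_dlt = int(rng.binomial(n_dlt, p_tox))
            if or_reported:
                p_resp = emax_prob(or_truth, float(depth))
                n_or = n_dlt
                events_or = int(rng.binomial(n_or, p_resp))
            else:
                n_or = events_or = None
            records.append(DoseOutcomeRecord(
                study_id=sid, dose_label=label, dose_components=dict(components),
                n_evaluable_dlt=n_dlt, n_dlt=events_dlt,
                n_evaluable_or=n_or, n_or=events_or,
            ))

    return Database(studies=studies, records=records), truths


# ---------------------------------------------------------------------------
# parameter-recovery harness


def recovery_experiment(
    spec: ScenarioSpec,
    method: str = "bayes",
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample → build series → fit → height, repeated, against the truth.

    Each replicate simulates one single-agent study from ``spec``, builds
    its toxicity series, fits by the requested method and records the
    estimated height, interval and truth.  Fit failures are counted
    (``fit_ok``), never fatal.  One row per replicate; aggregate with
    :func:`summarize_recovery`.
    """
    if method not in ("mle", "bayes"):
        raise ValueError("method must be 'mle' or 'bayes'")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = replace(spec, n_studies=1, frac_combination=0.0)
    rows = []
    for rep in range(n_reps):
        child_seed = int((seed * 1_000_003 + rep) % (2**31 - 1))
        db, truths = sample_database(replace(base, seed=child_seed))
        truth = next(t for t in truths if t.outcome == "DLT")
        series_list = make_analysis_series(
            db.studies[0].study_id, db.records, "DLT")
        series = series_list[0]
        row = {
            "rep": rep, "series_id": series.series_id,
            "n_levels": series.n_levels, "true_height": truth.true_height,
            "est_height": np.nan, "interval_lo": np.nan, "interval_hi": np.nan,
            "covered": np.nan, "fit_ok": False,
        }
        try:
            if method == "bayes":
                fit = fit_bayes(series, seed=child_seed)
                height = height_of_fit(fit, series.levels)
                row.update(est_height=height.mean, interval_lo=height.interval_lo,
                           interval_hi=height.interval_hi,
                           covered=bool(height.interval_lo <= truth.true_height
                                        <= height.interval_hi),
                           fit_ok=True)
            else:
                fit = fit_mle(series)
                if fit.converged:
                    height = height_of_fit(fit, series.levels)
                    row.update(est_height=height.mean, fit_ok=True)
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> dict[str, float]:
    """Bias, RMSE and interval coverage of the height estimates."""
    ok = table[table["fit_ok"]]
    err = ok["est_height"] - ok["true_height"]
    cov = ok["covered"].dropna()
    return {
        "n_reps": int(len(table)),
        "n_ok": int(len(ok)),
        "bias": float(err.mean()) if len(ok) else float("nan"),
        "rmse": float(np.sqrt(np.mean(err**2))) if len(ok) else float("nan"),
        "coverage": float(cov.mean()) if len(cov) else float("nan"),
        "mean_est_height": float(ok["est_height"].mean()) if len(ok) else float("nan"),
        "mean_true_height": float(ok["true_height"].mean()) if len(ok) else float("nan"),
    }
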
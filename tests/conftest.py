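import numpy as np
import pytest

from dosemono import (
    AnalysisSeries,
    Database,
    DoseCombination,
    DoseOutcomeRecord,
    SeriesPoint,
    StudyMeta,
)


@pytest.fixture
def worked_example_doses():
    """The canonical three-dose two-drug set with one incomparable pair:
    d1 and d2 cross each other, both sit below d3."""
    return [
        DoseCombination({"A": 10.0, "B": 20.0}, label="d1"),
        DoseCombination({"A": 20.0, "B": 10.0}, label="d2"),
        DoseCombination({"A": 20.0, "B": 20.0}, label="d3"),
    ]


def make_series(counts, outcome="DLT", study_id="S1"):
    """Series over levels 1..K from a list of (n, events) pairs."""
    points = tuple(
        SeriesPoint(
            dose=DoseCombination({"drug": 10.0 * (k + 1)}, label=f"d{k + 1}"),
            level=k + 1,
            n=n,
            events=events,
        )
        for k, (n, events) in enumerate(counts)
    )
    return AnalysisSeries(study_id=study_id, outcome=outcome, points=points)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def tiny_db():
    """One rule-based and one model-based study, three doses each."""
    studies = [
        StudyMeta("S1", 2010, "rule_based", "non_haematological",
                  "Solid tumours", "Chemotherapy", True),
        StudyMeta("S2", 2012, "model_based", "haematological",
                  "AML", "Inhibitor", False),
    ]
    records = []
    for sid in ("S1", "S2"):
        for k, (n, d, r) in enumerate([(3, 0, 1), (3, 1, 1), (6, 2, 2)]):
            records.append(DoseOutcomeRecord(
                study_id=sid, dose_label=f"d{k + 1}",
                dose_components={"drugA": 10.0 * (k + 1)},
                n_evaluable_dlt=n, n_dlt=d,
                n_evaluable_or=n if sid == "S1" else None,
                n_or=r if sid == "S1" else None,
            ))
    return Database(studies=studies, records=records)
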
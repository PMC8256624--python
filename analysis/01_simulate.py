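"""Generate the synthetic dose-finding trial landscape.

Produces a database of ~100 simulated dose-escalation studies with known
ground-truth toxicity and response curves: monotone-increasing DLT
truths, mostly flat OR truths, trial-realistic cohort sizes (3-6
patients per dose) and a share of partially ordered combination dose
sets.  Writes the database and truth table under results/.
"""

from pathlib import Path

import pandas as pd

from dosemono import literature_scenario, sample_database, write_database

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = literature_scenario()
    db, truths = sample_database(spec)
    write_database(db, OUT / "synth_db.csv")
    pd.DataFrame([
        {"study_id": t.study_id, "outcome": t.outcome,
         "p_lo": t.params.p_lo, "p_hi": t.params.p_hi,
         "ed50": t.params.ed50, "hill": t.params.hill,
         "true_height": t.true_height, "n_levels": t.n_levels}
        for t in truths
    ]).to_csv(OUT / "truth.csv", index=False)
    n_combo = sum(
        1 for s in db.studies
        if any(len(r.dose_components) > 1 for r in db.records_for(s.study_id)))
    print(f"{len(db.studies)} studies ({n_combo} with combination doses), "
          f"{len(db.records)} dose rows -> {OUT / 'synth_db.csv'}")
    print(f"{len(truths)} truth records -> {OUT / 'truth.csv'}")


if __name__ == "__main__":
    main()
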
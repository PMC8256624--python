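"""Decompose each study's dose set into fully orderable analysis series.

Reads results/synth_db.csv, applies the partial-order chain
decomposition separately for the DLT and OR outcomes, writes the series
tables and the characteristics summary (the trial-landscape table:
counts by year, design, disease and treatment class, and the
median/IQR of dose-levels per series).
"""

from pathlib import Path

from dosemono import (
    build_all_series,
    characteristics_table,
    read_database,
    render_characteristics,
    series_to_frame,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    db = read_database(OUT / "synth_db.csv")
    dlt = build_all_series(db, "DLT")
    orr = build_all_series(db, "OR")
    series_to_frame(dlt).to_csv(OUT / "series_dlt.csv", index=False)
    series_to_frame(orr).to_csv(OUT / "series_or.csv", index=False)

    table = characteristics_table(db, dlt, orr)
    table.to_csv(OUT / "characteristics.csv", index=False)
    text = render_characteristics(table)
    (OUT / "characteristics.txt").write_text(text + "\n")

    size_cell = table[table.block == "dose_levels"].iloc[0]
    print(f"{len(dlt)} DLT series, {len(orr)} OR series "
          f"({sum(s.fittable for s in dlt)} / {sum(s.fittable for s in orr)} fittable)")
    print(f"dose-levels per series, median (IQR): DLT {size_cell['dlt_series']}, "
          f"OR {size_cell['or_series']}")


if __name__ == "__main__":
    main()
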
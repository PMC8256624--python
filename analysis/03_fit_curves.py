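"""Fit Emax curves to every fittable series, Bayesian and maximum
likelihood.

The Bayesian route (ensemble MCMC under uniform asymptote priors)
produces a usable curve for every series; the ML route is run alongside
to tabulate how often it fails on trial-sized cohorts (non-convergence,
boundary estimates, exploding standard errors).  Writes per-series
height summaries joined to study metadata.
"""

from pathlib import Path

import pandas as pd

from dosemono import build_all_series, fit_all_series, fit_mle, read_database

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    db = read_database(OUT / "synth_db.csv")
    dlt = build_all_series(db, "DLT")
    orr = build_all_series(db, "OR")

    heights_d, _, curves_d = fit_all_series(db, dlt, method="bayes", seed=77)
    heights_o, _, curves_o = fit_all_series(db, orr, method="bayes", seed=78)
    heights = pd.concat([heights_d, heights_o], ignore_index=True)
    heights.to_csv(OUT / "heights_bayes.csv", index=False)
    curves_d.to_csv(OUT / "curves_dlt.csv", index=False)
    curves_o.to_csv(OUT / "curves_or.csv", index=False)

    # ML failure census on the same series
    mle_rows = []
    for series in [*dlt, *orr]:
        if not series.fittable:
            continue
        fit = fit_mle(series)
        mle_rows.append({"series_id": series.series_id,
                         "outcome": series.outcome,
                         "converged": fit.converged,
                         "failure_reason": fit.failure_reason})
    mle = pd.DataFrame(mle_rows)
    mle.to_csv(OUT / "mle_failures.csv", index=False)

    n_fit = len(heights)
    print(f"Bayesian fits succeeded for all {n_fit} fittable series")
    census = mle["failure_reason"].value_counts()
    print("ML fit outcomes:", dict(census))
    print(f"ML failed on {100 * (1 - mle['converged'].mean()):.0f}% of series "
          "(small cohorts push estimates to the boundary or blow up the "
          "standard errors); the Bayesian route is used for inference")


if __name__ == "__main__":
    main()
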
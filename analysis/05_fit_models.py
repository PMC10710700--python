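"""Fit the binomial GLMM families on the synthetic decision datasets.

Two model families, mirroring the structure of the field workflow:

* departure model — hourly resting-vs-departure records, predictors wind
  support, |side wind|, cloud, precipitation; AICc ranking, per-bird random
  intercept;
* soaring model — soaring-vs-flapping records with wind support, |side
  wind|, delta-T and the wind-support x delta-T interaction; AIC ranking,
  per-bird random intercept.

Both go through the full pipeline: standardization, collinearity screen
(|r| >= 0.6), all-subsets ranking, averaging of models within 2 criterion
units, 10-fold predictive accuracy, variance-partition R2.  Results land in
results/model_*.json and are printed as coefficient tables.
"""

import json
from pathlib import Path

import pandas as pd

from soarflight.stats import ModelSpec, collinearity_screen, dredge_average, standardize
from soarflight.synthetic import SimConfig, simulate_soaring_dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def fit_family(name, spec, table, covars):
    table, _ = standardize(table, covars)
    retained, report = collinearity_screen(table, covars)
    if not report.empty:
        print(f"[{name}] collinearity screen dropped: {report['dropped'].tolist()}")
        spec = ModelSpec(spec.response,
                         [t for t in spec.terms
                          if all(v in retained for v in t.replace('poly(', '').rstrip(')').split(':')
                                 if not v.isdigit())],
                         group=spec.group, criterion=spec.criterion)
    result = dredge_average(spec, table, kfold=10, kfold_seed=42)
    with open(OUT / f"model_{name}.json", "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2)
    print(f"\n[{name}] averaged over {result.n_models_averaged} model(s); "
          f"best terms: {list(result.best_terms)}")
    print(result.table.round(3).to_string())
    print(f"P.A. {100 * result.predictive_accuracy:.0f}%  "
          f"R2c {result.r2_conditional:.2f}  R2m {result.r2_marginal:.2f}")
    return result


def main():
    departures = pd.read_csv(OUT / "departure_records.csv")
    fit_family(
        "departure",
        ModelSpec("departed", ["tailwind", "sidewind", "cloud", "precip"], criterion="AICc"),
        departures,
        ["tailwind", "sidewind", "cloud", "precip"],
    )

    soaring = simulate_soaring_dataset(SimConfig(seed=42), n_points=2000)
    fit_family(
        "soaring_sea",
        ModelSpec("soaring", ["tailwind", "sidewind", "delta_T", "tailwind:delta_T"]),
        soaring,
        ["tailwind", "sidewind", "delta_T"],
    )


if __name__ == "__main__":
    main()
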
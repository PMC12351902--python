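#!/usr/bin/env python
"""Generate the synthetic study panel and country cross-section.

Emulates the conditions of the global macro analysis: a 33-year annual
panel of five variables (GINI, GDP_PPP, FPI, FI, HE) with known lagged
causal links and mixed integration orders, plus a 99-country two-cluster
cross-section for the income stratification stage.  Ground truth is
written alongside each dataset so later stages can be scored against it.

Writes: results/synthetic_panel.csv (+ .truth.json),
        results/country_cross_section.csv (+ .truth.json)
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tycausal.panel import write_panel, write_results
from tycausal.synthetic import SyntheticTruth, gen_country_cross_section, gen_var_panel

SEED = 20260930
OUT = Path(__file__).resolve().parent.parent / "results"

# the planted causal structure: inequality and real income drive food
# prices, inequality and prices drive food insecurity, prices (2-year lag)
# and insecurity drive health expenditure; GDP_PPP and HE are I(1)
TRUTH = SyntheticTruth(
    variables=("GINI", "GDP_PPP", "FPI", "FI", "HE"),
    edges=(
        ("GINI", "FPI", 1, 0.6),
        ("GDP_PPP", "FPI", 1, 0.4),
        ("GINI", "FI", 1, 0.5),
        ("FPI", "FI", 2, 0.4),
        ("FPI", "HE", 2, 0.5),
        ("FI", "HE", 1, 0.4),
    ),
    ar={v: 0.4 for v in ("GINI", "GDP_PPP", "FPI", "FI", "HE")},
    integration={"GDP_PPP": 1, "HE": 1},
    n=33,
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = gen_var_panel(TRUTH, start_year=1990)
    write_panel(panel, OUT / "synthetic_panel.csv")
    write_results(TRUTH, OUT / "synthetic_panel.truth.json")
    print(f"panel: {panel.n_years} years ({panel.years[0]}-{panel.years[-1]}), "
          f"{len(panel.variables)} variables, {len(TRUTH.edges)} planted causal links")

    cross, labels = gen_country_cross_section(
        n_countries=99, n_clusters=2, separation=6.0, seed=SEED,
        cluster_sizes=[67, 32],  # the higher-center cloud is the smaller, 32-country group
    )
    df = pd.DataFrame(cross.features, columns=cross.feature_names)
    df.insert(0, "country", cross.country_ids)
    df["true_group"] = labels
    df.to_csv(OUT / "country_cross_section.csv", index=False)
    json.dump(
        {"n_countries": 99, "n_clusters": 2, "separation": 6.0,
         "cluster_sizes": [32, 67], "seed": SEED},
        open(OUT / "country_cross_section.truth.json", "w"), indent=2,
    )
    hi = int(np.sum(labels == 1))
    print(f"cross-section: 99 countries, {hi} high-income / {99 - hi} low-income by truth")


if __name__ == "__main__":
    main()
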
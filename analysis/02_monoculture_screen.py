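"""Monoculture growth screen over the scenario fixtures.

Each scenario member is simulated alone with parsimonious FBA under its
scenario's diet; biomass fluxes, viability flags (growth > 0.001 1/h) and
secreted/consumed exchange fluxes go to results/monocultures/. This is the
baseline against which the pairwise stage measures biomass effects,
transfers and overproduction.
"""

import os
import sys

import pandas as pd

from coculture import pipeline, synthetic
from coculture.pipeline import RunConfig

OUTDIR = sys.argv[1] if len(sys.argv) > 1 else "results/monocultures"


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    config = RunConfig()
    tables = []
    for scenario in synthetic.all_scenarios():
        table, _ = pipeline.run_monocultures(
            [scenario.model_a, scenario.model_b], scenario.diet, config,
            outdir=os.path.join(OUTDIR, scenario.name))
        table.insert(0, "scenario", scenario.name)
        tables.append(table)
    combined = pd.concat(tables, ignore_index=True)
    combined.to_csv(os.path.join(OUTDIR, "all_monocultures.tsv"),
                    sep="\t", index=False, float_format="%.10g")
    print(combined.to_string(index=False))
    n_viable = int(combined["viable"].sum())
    print(f"\n{n_viable}/{len(combined)} monocultures viable "
          f"(> {config.viability_cutoff} 1/h); the one non-viable member is the "
          "designed inert partner.")


if __name__ == "__main__":
    main()
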
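"""Regenerate the designed co-culture scenario fixtures.

Writes each scenario's two member models as SBML (Level 3 + FBC) and its
diet as a three-column TSV under results/fixtures/, so every later stage —
and any external FBA tool — can consume them from disk. Running this script
twice produces identical files.
"""

import os
import sys

from coculture import synthetic, write_sbml
from coculture.model_core import write_diet_table

OUTDIR = sys.argv[1] if len(sys.argv) > 1 else "results/fixtures"


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    for scenario in synthetic.all_scenarios():
        for model in (scenario.model_a, scenario.model_b):
            write_sbml(model, os.path.join(OUTDIR, f"{model.id}.xml"))
        write_diet_table(scenario.diet,
                         os.path.join(OUTDIR, f"{scenario.name}.diet.tsv"))
        expected = scenario.expected
        print(f"{scenario.name:30s} members=({scenario.model_a.id}, "
              f"{scenario.model_b.id}) expected_type={expected.interaction}")
    print(f"\nwrote {len(synthetic.SCENARIO_NAMES)} scenario fixtures to {OUTDIR}/")


if __name__ == "__main__":
    main()
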
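#!/usr/bin/env python
"""Verify that the injected condition effects are statistically recovered.

The generator injects two known effects: alpha-band power multiplied by 4
during eye closure (the Berger effect) and dry-system delta-band noise
power doubled relative to gel. This driver simulates seeded cohorts
(15 subjects each), runs the EOEC band-power path, and checks per cohort
whether the paired tests detect both effects at the Bonferroni-adjusted
alpha = 0.01. Detection should be (near-)universal at these effect sizes.
"""

from pathlib import Path

import pandas as pd

from eegcompare.calibration import effect_recovery

N_COHORTS = 20
OUT = "results/effect_recovery.tsv"


def main() -> None:
    Path("results").mkdir(exist_ok=True)
    rows = []
    for seed in range(1, N_COHORTS + 1):
        flags = effect_recovery(seed, n_subjects=15)
        rows.append({"seed": seed, **flags})
    df = pd.DataFrame(rows)
    df.to_csv(OUT, sep="\t", index=False)
    print(f"over {N_COHORTS} cohorts: "
          f"alpha EC>EO detected in {df['alpha_ec_gt_eo'].mean():.0%}, "
          f"dry delta excess detected in {df['delta_dry_gt_gel'].mean():.0%} "
          f"(table in {OUT})")


if __name__ == "__main__":
    main()
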
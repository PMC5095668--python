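"""Exit-corrected survival from synthetic time-lapse fate tables.

Generates a synthetic imaging experiment (death from the population model,
independent delayed mitotic exit, censoring at 72 h), estimates
cause-specific hazards, and shows that the exit-corrected survival curve
recovers the true death-only curve while the raw fraction-alive curve is
biased upward by the competing exits.  Also demonstrates that the exit
curve is invariant to changes in the death process.
"""

import pathlib
from dataclasses import replace

import numpy as np
import pandas as pd

from mitoswitch import empirical, population, synthetic

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    pop = synthetic.default_population()
    gt = synthetic.GroundTruth(pop=pop, seed=3)
    tab = synthetic.generate_fates(gt, 4000)
    counts = tab["fate"].value_counts().to_dict()
    print(f"4000 synthetic cells: {counts}")

    est = empirical.estimate_hazards(tab, bins=0.5)
    corrected = empirical.corrected_survival(est, label="control")
    exits = empirical.exit_curve(est, label="control")
    truth = population.survival_curve_quadrature(pop, corrected.times)
    raw = empirical.raw_survival(tab, corrected.times)

    ok = np.isfinite(corrected.fraction)
    gap = float(np.abs(corrected.fraction[ok] - truth.fraction[ok]).max())
    raw_bias = float((truth.fraction[ok] - raw.fraction[ok]).max())
    print(f"corrected vs true death-only survival: max gap {gap:.3f}")
    print(f"raw fraction-still-arrested undershoots the death-only curve by "
          f"up to {raw_bias:.3f} because exits also deplete it")

    # independence: doubling the death propensity must not move the exit curve
    fast = synthetic.GroundTruth(pop=replace(pop, mu_m=pop.mu_m - np.log(4)), seed=3)
    est_fast = empirical.estimate_hazards(synthetic.generate_fates(fast, 4000), bins=0.5)
    exits_fast = empirical.exit_curve(est_fast, label="fast-death")
    both = np.isfinite(exits.fraction) & np.isfinite(exits_fast.fraction)
    drift = float(np.abs(exits.fraction[both] - exits_fast.fraction[both]).max())
    print(f"exit curve shift when death is accelerated 4x: max {drift:.3f} "
          "(independent competing risks)")

    out = pd.concat([
        corrected.to_frame(), exits.to_frame(), truth.to_frame(),
        raw.to_frame(), exits_fast.to_frame(),
    ])
    out.to_csv(RESULTS / "competing_risks_curves.tsv", sep="\t", index=False)
    print(f"Wrote {RESULTS}/competing_risks_curves.tsv")


if __name__ == "__main__":
    main()
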
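"""Parameter recovery: constrained fit on a fully synthetic experiment.

Runs one full replicate of the recovery harness -- synthetic fate tables
for control + two knockdowns, exit correction, blot and half-life
constraints, then the two-stage constrained least-squares fit -- and
reports how well the Mcl-1/Bak and Bcl-xL/Bak medians are recovered.
Takes a few minutes on one CPU.
"""

import pathlib

import numpy as np
import pandas as pd

from mitoswitch import recovery

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    outcome = recovery.run_replicate(master_seed=4)
    truth, result = outcome.truth, outcome.result

    rows = []
    for name, true_value in (
        ("median_mcl1_bak", np.exp(truth.mu_m)),
        ("median_bclxl_bak", np.exp(truth.mu_x)),
        ("tau_M_h", truth.tau_M),
        ("tau_X_h", truth.tau_X),
        ("knockdown_m", recovery.KNOCKDOWN),
        ("knockdown_x", recovery.KNOCKDOWN),
    ):
        key = {"median_mcl1_bak": "mu_m", "median_bclxl_bak": "mu_x",
               "tau_M_h": "tau_M", "tau_X_h": "tau_X",
               "knockdown_m": "knockdown_m", "knockdown_x": "knockdown_x"}[name]
        est = result.parameters[key]
        if key in ("mu_m", "mu_x"):
            est = float(np.exp(est))
        rows.append({"quantity": name, "true": true_value, "fitted": est,
                     "rel_error": est / true_value - 1.0})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "fit_recovery.tsv", sep="\t", index=False)
    result.restarts.to_csv(RESULTS / "fit_restarts.tsv", sep="\t", index=False)

    print(table.to_string(index=False))
    print(f"\nbest SSE {result.sse:.4g}; median-ratio errors: "
          f"Mcl-1/Bak {outcome.rel_err_mcl1:.1%}, "
          f"Bcl-xL/Bak {outcome.rel_err_bclxl:.1%}; "
          f"ratio ordering preserved: {outcome.ordering_preserved}")
    print("The blot boxes and the triplicate half-life constraint are what "
          "pin the absolute scale; without them the Mcl-1 median and decay "
          "constant trade off along a near-degenerate ray.")


if __name__ == "__main__":
    main()
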
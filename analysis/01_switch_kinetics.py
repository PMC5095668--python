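"""Simulate both pore models with the bundled reference parameters.

Integrates the tetramer-pore (Model I) and 256-mer-pore (Model II) networks
from the bundled reference parameter set, writes downsampled trajectories
and a switch-metrics table to results/, and prints the MOMP delay and
0.1 -> 0.5 switch duration of each model.
"""

import pathlib
import warnings

import numpy as np
import pandas as pd

from mitoswitch import analytics, kinetics

HOUR = 3600.0
RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    warnings.filterwarnings("ignore", category=RuntimeWarning)
    rows = []
    for variant, horizon_h in (("I", 30.0), ("II", 50.0)):
        params = kinetics.reference_parameters(variant)
        model = kinetics.build_model(params)
        init = kinetics.reference_initial_state(params.pore_size)
        traj = kinetics.simulate(model, init, horizon=horizon_h * HOUR, grid=10.0)

        frame = traj.to_frame()
        frame = frame[frame["time_s"] % 1800 == 0]  # 30-min output resolution
        frame.to_csv(RESULTS / f"trajectory_model_{variant}.tsv",
                     sep="\t", index=False)

        t50 = kinetics.momp_time(traj)
        dt = kinetics.switch_duration(traj)
        bound = analytics.switch_bound(params.pore_size, params.delta_M)
        qs = analytics.quasistatic_from_kinetics(params, M_0=init.M_free,
                                                 B_T=init.total_bak(model.sizes))
        rows.append({
            "model": variant,
            "pore_size": params.pore_size,
            "gamma_m_per_nM_s": params.gamma_m,
            "momp_time_h": t50 / HOUR,
            "switch_duration_h": dt / HOUR,
            "sharpness_bound_h": bound / HOUR,
            "quasistatic_delay_h": analytics.momp_delay(qs) / HOUR,
            "calibrated_K_C_nM": qs.K_C,
        })
        print(f"Model {variant} (A={params.pore_size}): MOMP delay "
              f"{t50 / HOUR:.2f} h, switch duration {dt / HOUR:.2f} h "
              f"(pore-size bound {bound / HOUR:.3f} h)")

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "switch_metrics.tsv", sep="\t", index=False)
    print(f"\nWith the bundled translocation constants the tetramer model "
          f"switches in {table.switch_duration_h[0]:.2f} h after a "
          f"{table.momp_time_h[0]:.2f} h delay, while the 256-mer model is "
          f"slower on both counts ({table.switch_duration_h[1]:.2f} h after "
          f"{table.momp_time_h[1]:.2f} h): at these constants the large pore "
          f"needs a far higher monomer threshold, deep in the regime where "
          f"Mcl-1:Bak buffering and Bak redistribution stretch the switch.")
    print(f"Wrote {RESULTS}/switch_metrics.tsv and two trajectory files.")


if __name__ == "__main__":
    main()
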
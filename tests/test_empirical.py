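"""Cause-specific hazard estimation and exit-corrected survival curves."""

import io

import numpy as np
import pandas as pd
import pytest

from mitoswitch.empirical import (
    corrected_survival,
    estimate_hazards,
    exit_curve,
    raw_survival,
    read_fate_table,
    write_fate_table,
)
from mitoswitch.errors import ValidationError


def table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "entry_h", "fate", "fate_h"])


def competing_table(n, death_rate, exit_rate, censor, seed):
    rng = np.random.default_rng(seed)
    # same underlying uniforms regardless of rates, so reparameterizations
    # of one cause leave the other cause's times untouched
    u_death, u_exit = rng.uniform(size=(2, n))
    t_death = -np.log(u_death) / death_rate if death_rate > 0 else np.full(n, np.inf)
    t_exit = -np.log(u_exit) / exit_rate if exit_rate > 0 else np.full(n, np.inf)
    fate_h = np.minimum.reduce([t_death, t_exit, np.full(n, censor)])
    fate = np.where((t_death <= t_exit) & (t_death < censor), "death",
                    np.where(t_exit < censor, "exit", "censored"))
    return table({"cell_id": np.arange(n), "entry_h": 0.0, "fate": fate,
                  "fate_h": fate_h})


class TestHazardEstimation:
    def test_hand_counted_death_hazard(self):
        """10 cells; one dies at 1.5 h and one exits at 0.5 h, so 8 remain
        at risk entering [2, 3); two deaths there give 2/(8*1 h) = 0.25/h."""
        rows = {
            "cell_id": range(10),
            "entry_h": [0.0] * 10,
            "fate": ["death", "exit", "death", "death"] + ["censored"] * 6,
            "fate_h": [1.5, 0.5, 2.2, 2.8] + [10.0] * 6,
        }
        est = estimate_hazards(table(rows), bins=np.arange(0.0, 11.0, 1.0))
        assert est.at_risk[2] == 8
        assert est.death_hazard[2] == pytest.approx(0.25)
        assert est.exit_hazard[0] == pytest.approx(0.1)

    def test_no_deaths_gives_zero_death_hazard(self):
        rows = {
            "cell_id": range(4), "entry_h": [0.0] * 4,
            "fate": ["exit"] * 2 + ["censored"] * 2,
            "fate_h": [1.0, 2.0, 5.0, 5.0],
        }
        est = estimate_hazards(table(rows), bins=1.0)
        assert np.nansum(est.death_hazard) == 0.0
        surv = corrected_survival(est)
        ok = np.isfinite(surv.fraction)
        assert np.all(surv.fraction[ok] == 1.0)

    def test_all_censored_at_zero_is_degenerate(self):
        rows = {"cell_id": [0, 1], "entry_h": [0.0, 0.0],
                "fate": ["censored", "censored"], "fate_h": [0.0, 0.0]}
        with pytest.raises(ValidationError):
            estimate_hazards(table(rows), bins=1.0)

    def test_vocabulary_and_sign_validation(self):
        bad_fate = {"cell_id": [0], "entry_h": [0.0], "fate": ["vanished"],
                    "fate_h": [1.0]}
        with pytest.raises(ValidationError):
            estimate_hazards(table(bad_fate), bins=1.0)
        negative = {"cell_id": [0], "entry_h": [0.0], "fate": ["death"],
                    "fate_h": [-1.0]}
        with pytest.raises(ValidationError):
            estimate_hazards(table(negative), bins=1.0)

    def test_empty_interior_bin_propagates_gap(self):
        rows = {"cell_id": [0, 1], "entry_h": [0.0, 0.0],
                "fate": ["death", "death"], "fate_h": [0.5, 5.5]}
        est = estimate_hazards(table(rows), bins=1.0)
        # after the first death the risk set persists (second cell), but a
        # bin past the last fate would be empty; here at_risk stays >= 1
        assert np.isfinite(est.death_hazard[:6]).all()
        # force a genuine gap: single cell dying early, grid extending past it
        one = {"cell_id": [0], "entry_h": [0.0], "fate": ["death"],
               "fate_h": [0.5]}
        est1 = estimate_hazards(table(one), bins=np.arange(0.0, 4.0, 1.0))
        surv = corrected_survival(est1)
        assert surv.gaps is not None and surv.gaps.any()
        assert np.isnan(surv.fraction[-1])


class TestCorrectedSurvival:
    def test_without_exits_matches_raw_survival(self):
        tab = competing_table(400, death_rate=0.15, exit_rate=0.0,
                              censor=30.0, seed=2)
        est = estimate_hazards(tab, bins=0.25)
        surv = corrected_survival(est)
        raw = raw_survival(tab, surv.times)
        ok = np.isfinite(surv.fraction)
        assert np.abs(surv.fraction[ok] - raw.fraction[ok]).max() < 0.02

    def test_recovers_true_death_survival_under_competing_exit(self):
        tab = competing_table(2000, death_rate=0.1, exit_rate=0.2,
                              censor=24.0, seed=4)
        est = estimate_hazards(tab, bins=0.25)
        surv = corrected_survival(est)
        s10 = np.interp(10.0, surv.times, surv.fraction)
        deaths = np.histogram(tab.loc[tab.fate == "death", "fate_h"],
                              bins=est.edges)[0]
        var = np.cumsum(deaths / np.maximum(est.at_risk, 1) ** 2)
        se = np.exp(-1.0) * np.sqrt(var[np.searchsorted(est.edges, 10.0) - 1])
        assert abs(s10 - np.exp(-1.0)) < 3 * se

    def test_correction_raises_survival_when_exits_compete(self):
        tab = competing_table(3000, death_rate=0.12, exit_rate=0.25,
                              censor=24.0, seed=6)
        est = estimate_hazards(tab, bins=0.5)
        surv = corrected_survival(est)
        raw = raw_survival(tab, surv.times)
        ok = np.isfinite(surv.fraction)
        assert np.all(surv.fraction[ok] >= raw.fraction[ok] - 1e-9)

    def test_halving_bin_width_is_stable(self):
        tab = competing_table(20_000, death_rate=0.05, exit_rate=0.05,
                              censor=24.0, seed=8)
        values = []
        for bw in (0.25, 0.125):
            est = estimate_hazards(tab, bins=bw)
            surv = corrected_survival(est)
            values.append(np.interp(10.0, surv.times, surv.fraction))
        assert abs(values[0] - values[1]) / values[1] < 0.01

    def test_agrees_with_nelson_aalen(self):
        """Independent oracle: lifelines' Nelson-Aalen estimator of the
        death-cause cumulative hazard, with exits/censoring as censoring."""
        lifelines = pytest.importorskip("lifelines")
        tab = competing_table(2000, death_rate=0.08, exit_rate=0.1,
                              censor=30.0, seed=10)
        naf = lifelines.NelsonAalenFitter()
        naf.fit(tab["fate_h"], event_observed=(tab["fate"] == "death"))
        est = estimate_hazards(tab, bins=0.25)
        surv = corrected_survival(est)
        at = np.array([5.0, 10.0, 15.0])
        ours = np.interp(at, surv.times, surv.fraction)
        theirs = np.exp(-np.interp(at, naf.cumulative_hazard_.index.to_numpy(),
                                   naf.cumulative_hazard_.iloc[:, 0].to_numpy()))
        assert np.abs(ours - theirs).max() < 0.02


class TestExitCurve:
    def test_zero_exit_hazard_gives_zero_curve(self):
        tab = competing_table(300, death_rate=0.2, exit_rate=0.0,
                              censor=20.0, seed=12)
        est = estimate_hazards(tab, bins=0.5)
        exits = exit_curve(est)
        ok = np.isfinite(exits.fraction)
        assert np.all(exits.fraction[ok] == 0.0)

    def test_constant_exit_hazard_level(self):
        tab = competing_table(20_000, death_rate=0.0, exit_rate=0.2,
                              censor=30.0, seed=14)
        est = estimate_hazards(tab, bins=0.25)
        exits = exit_curve(est)
        e5 = np.interp(5.0, exits.times, exits.fraction)
        assert e5 == pytest.approx(1.0 - np.exp(-1.0), abs=0.02)

    def test_invariant_to_death_hazard_doubling(self):
        curves = []
        for death_rate in (0.1, 0.2):
            tab = competing_table(2000, death_rate=death_rate, exit_rate=0.2,
                                  censor=24.0, seed=16)
            est = estimate_hazards(tab, bins=np.arange(0.0, 24.5, 0.5))
            curves.append(exit_curve(est))
        a, b = curves
        ok = np.isfinite(a.fraction) & np.isfinite(b.fraction)
        idx = a.times[ok] <= 10.0
        gap = np.abs(a.fraction[ok][idx] - b.fraction[ok][idx]).max()
        # 3 SE of the cumulative exit probability near E(10) ~ 0.86
        assert gap < 3 * 0.02


class TestIO:
    def test_round_trip(self, tmp_path):
        tab = competing_table(50, death_rate=0.1, exit_rate=0.1,
                              censor=20.0, seed=18)
        path = tmp_path / "fates.tsv"
        write_fate_table(tab, path)
        back = read_fate_table(path)
        assert np.allclose(back["fate_h"], tab["fate_h"])
        assert (back["fate"] == tab["fate"]).all()

    def test_reader_validates(self):
        bad = io.StringIO("cell_id\tentry_h\tfate\tfate_h\n0\t0\tghost\t1\n")
        with pytest.raises(ValidationError):
            read_fate_table(bad)
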
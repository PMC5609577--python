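"""Crossover design construction, mixed-model estimation and the
LSMeans percent-difference arithmetic."""

import numpy as np
import pandas as pd
import pytest

from lipopls.crossover import simulate_crossover_study
from lipopls.treatment_effect import (
    EffectEstimate,
    adjust_posthoc,
    build_design,
    fit_mixed_model,
    percent_difference,
)


def one_outcome(ds, cls="LDL_tot", lipid="CH"):
    r = ds.records
    return r[(r["class"] == cls) & (r["lipid"] == lipid)]


class TestDesign:
    def test_row_count_full_design(self):
        ds = simulate_crossover_study("low_hdl_cm", 40, None, seed=1)
        rows = build_design(one_outcome(ds))
        assert len(rows) == 40 * 2 * 2  # subjects x periods x visits

    def test_crossover_balance(self):
        ds = simulate_crossover_study("low_hdl_cm", 40, None, seed=1)
        rec = one_outcome(ds)
        per_subject = rec[rec["visit"].notna()].groupby("subject")["treatment"].unique()
        assert all(set(t) == {"TB", "placebo"} for t in per_subject)
        assert (ds.subjects["sequence"] == "TB-placebo").sum() == 20

    def test_trial_replica_bookkeeping(self):
        """44 enrolled subjects, one missing post-treatment sample and
        three whole-subject exclusions leave 163 analysis rows."""
        ds = simulate_crossover_study("low_hdl_cm", 44, None, seed=4,
                                      drop_records=[("S08", "D81")])
        rows = build_design(one_outcome(ds), excluded_subjects={"S04", "S39", "S41"})
        assert len(rows) == 41 * 4 - 1 == 163

    def test_missing_baseline_drops_period(self):
        ds = simulate_crossover_study("low_hdl_cm", 10, None, seed=2,
                                      drop_records=[("S03", "D57")])
        with pytest.warns(UserWarning, match="S03"):
            rows = build_design(one_outcome(ds))
        assert len(rows) == 10 * 4 - 2  # S03 loses its two period-2 visits

    def test_odd_subject_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            simulate_crossover_study("low_hdl_cm", 5, None, seed=0)


class TestMixedModel:
    def test_balanced_null_equals_raw_mean_difference(self, rng):
        """With balanced data and constant covariates the LSMean
        contrast reduces to the difference of raw treatment means."""
        n = 16
        subj = np.repeat([f"S{i}" for i in range(n)], 4)
        tb = np.tile([0.0, 0, 1, 1], n)
        y = rng.normal(5.0, 0.3, 4 * n) + np.repeat(rng.normal(0, 0.2, n), 4)
        rows = pd.DataFrame({
            "subject": subj, "value": y, "tb": tb,
            "baseline": 5.0, "male": 1.0, "age": 60.0, "bmi": 29.0,
            "visit2": np.tile([0.0, 1, 0, 1], n),
        })
        est = fit_mixed_model(rows)
        raw_diff = y[tb == 1].mean() - y[tb == 0].mean()
        assert est.lsmean_tb - est.lsmean_placebo == pytest.approx(raw_diff, abs=1e-8)

    def test_recovers_injected_five_percent_reduction(self):
        """A 0.95 multiplier on LDL_tot-CH is recovered within one
        percentage point (averaged over seeds, low-noise setting)."""
        diffs = []
        for seed in range(5):
            ds = simulate_crossover_study(
                "low_hdl_cm", 40, {("LDL_tot", "CH"): 0.95},
                sigma_subject=0.10, sigma_visit=0.02, seed=100 + seed,
            )
            est = fit_mixed_model(build_design(one_outcome(ds)))
            diffs.append(est.pct_diff)
        assert abs(np.mean(diffs) - (-5.0)) < 1.0

    def test_recovers_injected_ten_percent_increase(self):
        diffs = []
        for seed in range(5):
            ds = simulate_crossover_study(
                "low_hdl_cm", 40, {("HDL_tot", "CH"): 1.10},
                sigma_subject=0.10, sigma_visit=0.02, seed=200 + seed,
            )
            est = fit_mixed_model(build_design(one_outcome(ds, "HDL_tot", "CH")))
            diffs.append(est.pct_diff)
        assert abs(np.mean(diffs) - 10.0) < 1.0

    def test_null_type_one_rate(self):
        """No-effect simulator: rejection rate at alpha=0.05 inside the
        binomial 95% band over 200 replicates."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            ds = simulate_crossover_study("low_hdl_cm", 24, None,
                                          sigma_subject=0.12, sigma_visit=0.05,
                                          seed=5000 + seed)
            est = fit_mixed_model(build_design(one_outcome(ds)))
            hits += est.p_value < 0.05
        lo = n_rep * 0.05 - 1.96 * np.sqrt(n_rep * 0.05 * 0.95)
        hi = n_rep * 0.05 + 1.96 * np.sqrt(n_rep * 0.05 * 0.95)
        assert lo <= hits <= hi, f"{hits} rejections outside [{lo:.1f}, {hi:.1f}]"

    def test_lsmeans_invariant_to_covariate_recentering(self):
        ds = simulate_crossover_study("low_hdl_cm", 20, None, seed=9)
        rows = build_design(one_outcome(ds))
        est1 = fit_mixed_model(rows)
        shifted = rows.copy()
        shifted["age"] += 10.0
        shifted["bmi"] -= 3.0
        est2 = fit_mixed_model(shifted)
        assert est1.lsmean_placebo == pytest.approx(est2.lsmean_placebo, abs=1e-6)
        assert est1.lsmean_tb == pytest.approx(est2.lsmean_tb, abs=1e-6)


class TestPercentDifference:
    @pytest.mark.parametrize("placebo,tb,expected", [
        (3.017, 2.859, -5.24),   # total-LDL cholesterol LSMeans
        (1.424, 1.346, -5.48),   # LDL09 cholesterol LSMeans
        (2.0, 2.0, 0.0),
    ])
    def test_published_lsmean_arithmetic(self, placebo, tb, expected):
        assert percent_difference(placebo, tb) == expected

    def test_nonpositive_placebo_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


class TestPosthoc:
    def make_est(self, p):
        return EffectEstimate("LDL_tot", "CH", 3.0, 2.9, 0.1, 0.1, -3.33, p)

    def test_two_arm_identity(self):
        out = adjust_posthoc([self.make_est(0.04)])
        assert out[0].p_value == 0.04 and out[0].adjusted

    def test_multi_arm_bound(self):
        for p in (0.01, 0.2, 0.7):
            out = adjust_posthoc([self.make_est(p)], n_arms=4)
            assert out[0].p_value >= p

    def test_empty_passthrough(self):
        assert adjust_posthoc([]) == []
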
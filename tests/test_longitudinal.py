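"""Latent progression, dropout, joint likelihood and model fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from cogirt import (
    HazardSpec,
    ItemBank,
    ItemSpec,
    LongitudinalIRT,
    ProgressionParams,
    SubjectEffects,
    TrialDesign,
    VisitSchedule,
    dropout_interval_loglik,
    fit_longitudinal,
    joint_subject_loglik,
    select_hazard,
    simulate_trial,
    survival,
    trajectory,
)
from cogirt.items import logpmf_table
from cogirt.longitudinal import CTS_SCHEDULE

P_LEADE = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54)


class TestTrajectory:
    def test_baseline_value(self):
        eff = SubjectEffects(0.2, -0.1)
        assert trajectory(0.0, eff, P_LEADE) == pytest.approx(0.95 + 0.2)

    def test_two_year_typical_progression(self):
        eff = SubjectEffects(0.0, 0.0)
        assert trajectory(24.0, eff, P_LEADE) == pytest.approx(1.65)

    def test_drug_effect_scales_slope(self):
        p = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54, beta_drug=0.2)
        treated = SubjectEffects(0.0, 0.0, x_grp=1)
        # slope contribution over 12 months: 0.8 * 0.35 = 0.28
        assert trajectory(12.0, treated, p) - 0.95 == pytest.approx(0.28)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            VisitSchedule((3, 6, 9))
        with pytest.raises(ValueError):
            VisitSchedule((0, 6, 6))


class TestSurvival:
    def test_constant_hazard_closed_form(self):
        hz = HazardSpec("constant", np.log(0.5))
        eff = SubjectEffects(0.0, 0.0)
        assert survival(12.0, eff, P_LEADE, hz) == pytest.approx(
            np.exp(-0.5), abs=1e-9
        )

    def test_time_zero_is_one(self):
        hz = HazardSpec("progression_rate", -1.0, 0.65)
        assert survival(0.0, SubjectEffects(0.3, 0.1), P_LEADE, hz) == 1.0

    @pytest.mark.parametrize("t_months", [6.0, 12.0, 20.0])
    def test_disability_hazard_matches_riemann_sum(self, t_months):
        hz = HazardSpec("disability", -2.0, 0.8)
        eff = SubjectEffects(0.4, 0.25)
        d0, a = eff.d0(P_LEADE), eff.slope(P_LEADE)
        u = np.linspace(0, t_months / 12.0, 2_000_001)
        h = np.exp(hz.theta3 + hz.theta4 * (d0 + a * u))
        oracle = np.exp(-np.trapezoid(h, u))
        assert survival(t_months, eff, P_LEADE, hz) == pytest.approx(
            oracle, abs=1e-6
        )


class TestDropoutInterval:
    def test_closed_form_interval_probability(self):
        hz = HazardSpec("constant", np.log(0.5))
        eff = SubjectEffects(0.0, 0.0)
        ll = dropout_interval_loglik(12.0, 15.0, eff, P_LEADE, hz)
        # log(S(1 yr) - S(1.25 yr)) = log(e^-0.5 - e^-0.625) = log(0.071270)
        assert ll == pytest.approx(np.log(np.exp(-0.5) - np.exp(-0.625)), abs=1e-12)
        assert np.exp(ll) == pytest.approx(0.071270, abs=2e-6)

    def test_completer_with_negligible_hazard(self):
        hz = HazardSpec("constant", -30.0)
        ll = dropout_interval_loglik(
            20.0, None, SubjectEffects(0, 0), P_LEADE, hz,
            end_of_study_months=20.0,
        )
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_interval_probabilities_partition_to_one(self):
        hz = HazardSpec("progression_rate", 0.3, 0.65)
        eff = SubjectEffects(0.1, 0.05)
        times = list(CTS_SCHEDULE.times)
        probs = [
            np.exp(dropout_interval_loglik(a, b, eff, P_LEADE, hz))
            for a, b in zip(times[:-1], times[1:])
        ]
        completer = np.exp(
            dropout_interval_loglik(times[-1], None, eff, P_LEADE, hz,
                                    end_of_study_months=times[-1])
        )
        assert sum(probs) + completer == pytest.approx(1.0, abs=1e-12)

    def test_order_validated(self):
        hz = HazardSpec("constant", 0.0)
        with pytest.raises(ValueError):
            dropout_interval_loglik(12.0, 9.0, SubjectEffects(0, 0), P_LEADE, hz)


def _toy_bank():
    return ItemBank(
        [
            ItemSpec("b1", "commands", "binary3pl", a=1.3, b=0.8, c=0.05),
            ItemSpec("w1", "word_recall", "binomial_words",
                     a=1.0, b=0.2, c=0.05, n_words=10),
        ]
    )


def _toy_records(values):
    """(time, item, value) triples for one subject."""
    return pd.DataFrame(
        {
            "subject_id": "s",
            "study_id": "T",
            "arm": 0,
            "time_months": [v[0] for v in values],
            "item_id": [v[1] for v in values],
            "value": [v[2] for v in values],
        }
    )


def _grid_oracle(records, bank, params, n=401, lim=8.0):
    """Dense 2-D trapezoid integration over the random-effect plane."""
    e1 = np.linspace(-lim, lim, n)
    e2 = np.linspace(-lim, lim, n)
    E1, E2 = np.meshgrid(e1, e2, indexing="ij")
    total = np.zeros_like(E1)
    for _, r in records.iterrows():
        D = (params.theta1 + E1) + (params.theta2 + E2) * r["time_months"] / 12.0
        total += logpmf_table(bank[r["item_id"]], D)[int(r["value"])]
    prior = multivariate_normal(mean=[0, 0], cov=params.cov).logpdf(
        np.dstack([E1, E2])
    )
    integrand = np.exp(total + prior)
    inner = np.trapezoid(integrand, e2, axis=1)
    return float(np.log(np.trapezoid(inner, e1)))


class TestJointSubjectLoglik:
    RECORDS = [(0.0, "b1", 1), (0.0, "w1", 3), (18.0, "b1", 0), (18.0, "w1", 6)]

    def test_agh_matches_dense_grid_oracle(self):
        bank = _toy_bank()
        rec = _toy_records(self.RECORDS)
        oracle = _grid_oracle(rec, bank, P_LEADE)
        agh = joint_subject_loglik(rec, bank, P_LEADE, method="agh", n_nodes=21)
        assert agh == pytest.approx(oracle, abs=1e-6)

    def test_laplace_reasonable_on_toy(self):
        bank = _toy_bank()
        rec = _toy_records(self.RECORDS)
        oracle = _grid_oracle(rec, bank, P_LEADE)
        lap = joint_subject_loglik(rec, bank, P_LEADE, method="laplace")
        assert abs(lap - oracle) < 0.05 * abs(oracle)

    def test_zero_variance_collapses_to_typical_trajectory(self):
        bank = _toy_bank()
        rec = _toy_records(self.RECORDS)
        p0 = ProgressionParams(0.95, 0.35, 0.0, 0.0, 0.0)
        ll = joint_subject_loglik(rec, bank, p0)
        expect = 0.0
        for t, iid, v in self.RECORDS:
            D = np.asarray(0.95 + 0.35 * t / 12.0)
            expect += float(logpmf_table(bank[iid], D)[v])
        assert ll == pytest.approx(expect, abs=1e-12)

    def test_constant_hazard_factorizes(self):
        bank = _toy_bank()
        rec = _toy_records(self.RECORDS)
        hz = HazardSpec("constant", np.log(0.4))
        with_drop = joint_subject_loglik(
            rec, bank, P_LEADE, hazard=hz, dropout=(18.0, 20.0), method="agh",
            n_nodes=15,
        )
        without = joint_subject_loglik(rec, bank, P_LEADE, method="agh", n_nodes=15)
        eff = SubjectEffects(0.0, 0.0)
        drop_term = dropout_interval_loglik(18.0, 20.0, eff, P_LEADE, hz)
        assert with_drop - without == pytest.approx(drop_term, abs=1e-7)

    def test_nonfinite_diagnostic_names_item(self):
        bank = ItemBank(
            [ItemSpec("b1", "commands", "binary3pl", a=1.0, b=0.0, c=0.0)]
        )
        # a non-finite trajectory parameter poisons the integrand; the
        # diagnostic must name the offending item
        p0 = ProgressionParams(np.nan, 0.0, 0.0, 0.0, 0.0)
        rec = _toy_records([(0.0, "b1", 0)])
        with pytest.raises(FloatingPointError, match="b1"):
            joint_subject_loglik(rec, bank, p0)


class TestEngineAgainstReference:
    def test_dataset_loglik_matches_per_subject_reference(self, rbank):
        p = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54)
        design = TrialDesign(
            n_total=15, params=p, bank=rbank, schedule=CTS_SCHEDULE,
            allocation=0.0, seed=77,
        )
        trial = simulate_trial(design)
        model = LongitudinalIRT(trial.responses, rbank, drug_effect=False)
        fast = model.loglik(
            dict(theta1=0.9, theta2=0.3, omega1=0.6, omega2=0.35, rho=0.4)
        )
        pp = ProgressionParams(0.9, 0.3, 0.6, 0.35, 0.4)
        slow = sum(
            joint_subject_loglik(g, rbank, pp, method="laplace")
            for _, g in trial.responses.groupby("subject_id")
        )
        assert fast == pytest.approx(slow, rel=2e-5)

    def test_arm_exchangeability_without_drug_effect(self, rbank):
        p = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54)
        design = TrialDesign(
            n_total=30, params=p, bank=rbank, schedule=CTS_SCHEDULE,
            allocation=0.5, seed=13,
        )
        trial = simulate_trial(design)
        nat = dict(theta1=0.95, theta2=0.35, omega1=0.68, omega2=0.39, rho=0.54,
                   beta_drug=0.0)
        m1 = LongitudinalIRT(trial.responses, rbank, drug_effect=True)
        flipped = trial.responses.copy()
        flipped["arm"] = 1 - flipped["arm"]
        m2 = LongitudinalIRT(flipped, rbank, drug_effect=True)
        assert m1.loglik(nat) == pytest.approx(m2.loglik(nat), abs=1e-8)


class TestFitLongitudinal:
    def test_time_shift_reparameterizes_baseline(self, placebo_trial, rbank):
        res = fit_longitudinal(placebo_trial.responses, rbank,
                               drug_effect=False, se=False)
        shifted = placebo_trial.responses.copy()
        shifted["time_months"] = shifted["time_months"] + 6.0
        res2 = fit_longitudinal(shifted, rbank, drug_effect=False, se=False)
        # theta1 is the intercept at t = 0: observations moved 6 months later
        # lower the extrapolated baseline by theta2 * 0.5 years
        expect_shift = -res.estimates["theta2"] * 0.5
        assert res2.estimates["theta1"] - res.estimates["theta1"] == (
            pytest.approx(expect_shift, abs=0.02)
        )
        assert res2.estimates["theta2"] == pytest.approx(
            res.estimates["theta2"], abs=0.01
        )

    def test_null_drug_ci_covers_zero(self, rbank):
        p = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54)
        covered = 0
        n_rep = 25
        for s in range(n_rep):
            design = TrialDesign(
                n_total=150, params=p, bank=rbank, schedule=CTS_SCHEDULE,
                allocation=0.5, seed=5000 + s,
            )
            trial = simulate_trial(design)
            res = LongitudinalIRT(trial.responses, rbank, drug_effect=True).fit()
            w = res.wald_test_drug()
            covered += int(w["ci_low"] <= 0.0 <= w["ci_high"])
        assert covered >= int(0.8 * n_rep)  # nominal 95%, small-sample slack

    def test_summary_mentions_key_facts(self, placebo_trial, rbank):
        res = fit_longitudinal(placebo_trial.responses, rbank, drug_effect=False)
        text = res.summary()
        assert "theta1" in text and "log-likelihood" in text


class TestHazardSelection:
    @staticmethod
    def _trial(kind, theta4, seed, n=150):
        hz = (
            HazardSpec("constant", 0.1)
            if kind == "constant"
            else HazardSpec(kind, -0.3, theta4)
        )
        p = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54)
        design = TrialDesign(
            n_total=n, params=p, bank=_toy_bank_wide(), schedule=CTS_SCHEDULE,
            allocation=0.0, hazard=hz, seed=seed,
        )
        return simulate_trial(design)

    def test_constant_data_keeps_constant_hazard(self):
        trial = self._trial("constant", None, seed=31)
        hz, report = select_hazard(trial.responses, _toy_bank_wide(),
                                   dropout=trial.dropout)
        assert hz.kind == "constant"
        assert (report["delta_m2ll"] > -0.5).all()  # nested LR is nonnegative

    def test_strong_slope_dependence_detected(self):
        trial = self._trial("progression_rate", 2.5, seed=32, n=250)
        hz, report = select_hazard(trial.responses, _toy_bank_wide(),
                                   dropout=trial.dropout)
        assert hz.kind == "progression_rate"
        row = report.set_index("kind").loc["progression_rate"]
        assert row["significant"] and row["delta_m2ll"] > 3.84


def _toy_bank_wide():
    """Six informative items, enough to track individual trajectories."""
    items = [
        ItemSpec(f"b{j}", "commands", "binary3pl",
                 a=1.4, b=0.4 * j - 0.4, c=0.02)
        for j in range(4)
    ] + [
        ItemSpec("w1", "word_recall", "binomial_words",
                 a=1.1, b=0.3, c=0.05, n_words=10),
        ItemSpec("w2", "delayed_word_recall", "binomial_words",
                 a=1.5, b=-0.5, c=0.05, n_words=10),
    ]
    return ItemBank(items)
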
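"""Synthetic task schedule, cohort and BOLD-run generators."""

import collections

import numpy as np
import pandas as pd
import pytest

from antdrift import cohort
from antdrift.betaseries import build_trial_design
from antdrift.ddm import CONDITIONS


class TestSchedule:
    def test_each_delay_occurs_three_times_per_run(self):
        sched = cohort.generate_trial_schedule(cohort.ScheduleConfig(), seed=4)
        for run, sub in sched.groupby("run"):
            for col, values in (
                ("cue_target_delay", cohort.CUE_TARGET_DELAYS),
                ("target_cue_delay", cohort.TARGET_CUE_DELAYS),
            ):
                counts = collections.Counter(np.round(sub[col], 3))
                assert counts == {v: 3 for v in values}

    def test_six_runs_give_216_trials(self):
        sched = cohort.generate_trial_schedule(cohort.ScheduleConfig(n_runs=6), seed=0)
        assert len(sched) == 216
        assert len(cohort.generate_trial_schedule(
            cohort.ScheduleConfig(n_runs=5), seed=0)) == 180

    def test_onset_accounting(self):
        """target onset = cue onset + 200 ms cue + cue-target delay."""
        sched = cohort.generate_trial_schedule(cohort.ScheduleConfig(), seed=1)
        np.testing.assert_allclose(
            sched["target_onset"],
            sched["cue_onset"] + 0.2 + sched["cue_target_delay"],
        )
        # fixed delay multisets: every run fits inside a 156-volume window
        assert sched["target_onset"].max() < 156 * 1.92

    def test_condition_split_respected(self):
        sched = cohort.generate_trial_schedule(cohort.ScheduleConfig(), seed=2)
        for _, sub in sched.groupby("run"):
            assert sub["condition"].value_counts().tolist() == [12, 12, 12]

    def test_identical_seed_identical_schedule(self):
        a = cohort.generate_trial_schedule(cohort.ScheduleConfig(), seed=9)
        b = cohort.generate_trial_schedule(cohort.ScheduleConfig(), seed=9)
        assert a.equals(b)

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError):
            cohort.ScheduleConfig(condition_split=(12, 12, 13))


class TestCohort:
    def test_zero_between_subject_sd_gives_identical_parameters(self):
        g = cohort.GroupSpec("G", (2.0, 1.8, 1.6), (1.5, 1.5, 1.5), 0.4,
                             drift_sd=0.0, boundary_sd=0.0, t0_sd=0.0)
        _, truth = cohort.generate_cohort(
            (g,), 4, cohort.ScheduleConfig(n_runs=1), seed=1)
        subs = truth["subjects"]
        for col in ("v_congruent", "a_congruent", "t0"):
            assert subs[col].nunique() == 1

    def test_group_rt_ordering(self, small_cohort):
        """Mean RT orders healthy controls fastest, Lewy body slowest."""
        table, _ = small_cohort
        means = table.groupby("group", sort=False)["rt"].mean()
        assert means["Control"] < means["AD"] < means["LBD"]

    def test_rt_distributions_right_skewed(self, small_cohort):
        table, _ = small_cohort
        rts = table["rt"].dropna()
        assert rts.skew() > 0.5
        # diffusion trials respect the non-decision floor; only uniform
        # contaminants may fall below it
        clean = table[~table["contaminant"]]["rt"].dropna()
        assert clean.min() > 0.2

    def test_censored_trials_emitted(self, small_cohort):
        table, _ = small_cohort
        censored = table[table["response"] == -1]
        assert len(censored) > 0
        assert censored["rt"].isna().all()

    def test_condition_invariant_parameters_equalize_accuracy(self):
        g = cohort.GroupSpec("G", (1.5, 1.5, 1.5), (1.5, 1.5, 1.5), 0.3,
                             drift_sd=0.0, boundary_sd=0.0, t0_sd=0.0)
        table, _ = cohort.generate_cohort((g,), 6, cohort.ScheduleConfig(n_runs=6),
                                          seed=2, p_outlier=0.0)
        ok = table[table["response"].isin([0, 1])]
        accs = ok.groupby("condition")["response"].mean()
        n = len(ok) / 3
        se = np.sqrt(accs.mean() * (1 - accs.mean()) / n)
        assert accs.max() - accs.min() < 6 * se

    def test_ground_truth_round_trips_from_seed(self):
        kw = dict(schedule=cohort.ScheduleConfig(n_runs=2), seed=33,
                  networks=("dorsal",))
        t1, tr1 = cohort.generate_cohort(cohort.default_groups(), 3, **kw)
        t2, tr2 = cohort.generate_cohort(cohort.default_groups(), 3, **kw)
        assert t1.equals(t2)
        assert tr1["subjects"].equals(tr2["subjects"])


class TestCoupledTrials:
    def _params(self):
        rng = np.random.default_rng(8)
        n = 10_000
        conds = np.array(CONDITIONS)[rng.integers(0, 3, n)]
        betas = rng.standard_normal(n)
        return conds, betas

    def test_zero_coupling_identical_to_uncoupled(self):
        conds, betas = self._params()
        kw = dict(v_cond=(2.0, 1.6, 1.4), a_cond=(1.5, 1.5, 1.5), t0=0.4,
                  conditions=conds[:500], seed=5)
        a = cohort.generate_coupled_trials(betas=betas[:500], coupling=0.0, **kw)
        b = cohort.generate_coupled_trials(betas=np.zeros(500), coupling=0.7, **kw)
        assert a.equals(b)

    @pytest.mark.parametrize("b,expect_higher_top", [(0.5, True), (-0.5, False)])
    def test_coupling_orders_accuracy_by_beta_quartile(self, b, expect_higher_top):
        conds, betas = self._params()
        trials = cohort.generate_coupled_trials(
            (2.0, 1.6, 1.4), (1.5, 1.5, 1.5), 0.4, conds, betas, b, seed=6)
        trials["beta"] = betas
        ok = trials[trials["response"].isin([0, 1])]
        q1, q3 = np.quantile(ok["beta"], [0.25, 0.75])
        top = ok.loc[ok["beta"] >= q3, "response"].mean()
        bottom = ok.loc[ok["beta"] <= q1, "response"].mean()
        assert (top > bottom) == expect_higher_top

    def test_nonfinite_betas_rejected(self):
        with pytest.raises(ValueError):
            cohort.generate_coupled_trials(
                (2, 2, 2), (1.5, 1.5, 1.5), 0.4, ["congruent"], [np.nan], 0.3, seed=1)


class TestBOLDRun:
    def _schedule(self):
        return cohort.generate_trial_schedule(
            cohort.ScheduleConfig(n_runs=1), seed=12)

    def test_run_has_156_volumes_at_tr(self):
        sched = self._schedule()
        run, _ = cohort.generate_bold_run(sched, np.ones(36), seed=1)
        assert run.samples.shape == (156,)
        assert run.tr == pytest.approx(1.92)

    def test_noiseless_run_is_pure_design_combination(self):
        sched = self._schedule()
        cfg = cohort.BOLDRunConfig(noise_sd=0.0, drift_amplitude=0.0,
                                   motion_leak=0.0, motion_step_mm=0.0,
                                   motion_step_deg=0.0)
        amps = np.linspace(0.5, 2.0, 36)
        run, truth = cohort.generate_bold_run(sched, amps, cfg, seed=2)
        design = build_trial_design(run)
        trial_cols = design.filter(like="trial_").to_numpy()
        expected = cfg.baseline * (1 + trial_cols @ amps / 100.0)
        np.testing.assert_allclose(run.samples, expected, rtol=1e-10)

    def test_doubling_amplitudes_doubles_noiseless_signal(self):
        sched = self._schedule()
        cfg = cohort.BOLDRunConfig(noise_sd=0.0, drift_amplitude=0.0,
                                   motion_leak=0.0)
        amps = np.full(36, 0.8)
        r1, _ = cohort.generate_bold_run(sched, amps, cfg, seed=3)
        r2, _ = cohort.generate_bold_run(sched, 2 * amps, cfg, seed=3)
        mod1 = r1.samples / cfg.baseline - 1
        mod2 = r2.samples / cfg.baseline - 1
        np.testing.assert_allclose(mod2, 2 * mod1, atol=1e-12)

    def test_amplitude_count_must_match_trials(self):
        with pytest.raises(ValueError):
            cohort.generate_bold_run(self._schedule(), np.ones(35), seed=1)
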
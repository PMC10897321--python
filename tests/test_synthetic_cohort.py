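import dataclasses

import numpy as np
import pytest
from scipy import stats

from thermosleep import preprocess as prep
from thermosleep import synthetic_cohort as sc

from conftest import second_part_stage_minutes


class TestCohortSpec:
    def test_defaults_valid(self):
        spec = sc.CohortSpec()
        assert spec.n_subjects == 72
        assert spec.n_epochs == 900

    @pytest.mark.parametrize(
        "kwargs,needle",
        [
            (dict(study_sizes=(0, 3, 3)), "study_sizes"),
            (dict(study_sizes=(1, 2)), "study_sizes"),
            (dict(tau_mat=200.0), "tau"),
            (dict(tau_pbt=300.0), "tau"),
            (dict(persistence=1.5), "persistence"),
            (dict(cycle_period_min=-1.0), "cycle_period_min"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, needle):
        with pytest.raises(ValueError, match=needle):
            sc.CohortSpec(**kwargs)

    def test_roundtrip_dict(self):
        spec = sc.CohortSpec(seed=9)
        assert sc.CohortSpec.from_dict(spec.to_dict()) == spec

    def test_from_dict_rejects_unknown(self):
        with pytest.raises(ValueError, match="unknown"):
            sc.CohortSpec.from_dict({"bogus_field": 1})


class TestDeterminism:
    def test_same_seed_identical(self, tiny_spec):
        a = sc.generate_cohort(tiny_spec)
        b = sc.generate_cohort(tiny_spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.hm.hypnogram, sb.hm.hypnogram)
            assert np.array_equal(sa.lm.hypnogram, sb.lm.hypnogram)
            for var in sa.hm.physio:
                assert np.array_equal(sa.hm.physio[var].values, sb.hm.physio[var].values)
            assert sa.profile == sb.profile

    def test_different_seed_differs(self, tiny_spec):
        a = sc.generate_cohort(tiny_spec)
        b = sc.generate_cohort(dataclasses.replace(tiny_spec, seed=tiny_spec.seed + 1))
        assert any(
            not np.array_equal(sa.hm.hypnogram, sb.hm.hypnogram) for sa, sb in zip(a, b)
        )

    def test_subject_count_and_shared_profile(self, tiny_spec):
        cohort = sc.generate_cohort(tiny_spec)
        assert len(cohort) == sum(tiny_spec.study_sizes)
        for profile, hm, lm in cohort:
            assert hm.subject_id == lm.subject_id == profile.subject_id
            assert hm.condition == "HM" and lm.condition == "LM"


class TestNightRecordingInvariants:
    def test_shapes_and_ranges(self, default_cohort):
        rec = default_cohort[0].hm
        assert len(rec.hypnogram) == 900
        assert set(rec.hypnogram) <= set(sc.STAGES)
        for var, (step, n_sensors) in sc.PHYSIO_SAMPLING.items():
            series = rec.physio[var]
            assert series.values.shape == (n_sensors, 27000 // step)
            assert series.times_s.min() >= 0 and series.times_s.max() < 27000
        for var in ("CBT", "PBT", "MAT"):
            vals = rec.physio[var].values
            assert vals.min() >= 25.0 and vals.max() <= 40.0
        hr = rec.physio["HR"].values
        assert hr.min() >= 30.0 and hr.max() <= 120.0


class TestNullEffect:
    def test_null_symmetry_of_n3(self):
        # all HM effect parameters zero: mean per-subject HM-LM nightly N3 ~ 0
        spec = dataclasses.replace(
            sc.CohortSpec(seed=42).null_effect(), study_sizes=(40, 40, 40)
        )
        cohort = sc.generate_cohort(spec)
        diffs = [
            ((c.hm.hypnogram == "N3").sum() - (c.lm.hypnogram == "N3").sum()) * 0.5
            for c in cohort
        ]
        diffs = np.asarray(diffs, dtype=float)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3.5 * sem + 1e-9

    def test_null_physio_identical_when_noise_free(self):
        spec = sc.CohortSpec(
            seed=0,
            noise_sd={"CBT": 0.0, "PBT": 0.0, "MAT": 0.0, "HR": 0.0},
        ).null_effect()
        profile = sc.draw_profile(spec, 0, 1)
        profile = dataclasses.replace(profile, g_i=0.0)
        hm = sc.generate_physiology(profile, "HM", spec, np.random.default_rng(0))
        lm = sc.generate_physiology(profile, "LM", spec, np.random.default_rng(1))
        for var in hm:
            np.testing.assert_array_equal(hm[var].values, lm[var].values)


class TestHypnogramModel:
    def test_stationary_when_no_cycle_or_trend(self):
        # cycle amplitudes and trends zero: stage proportions are the same in
        # the first and second half of the night (t test across independent
        # runs per stage; epochs within a run are bout-autocorrelated, so the
        # comparison is made at the run level)
        spec = sc.CohortSpec(
            seed=0,
            n3_cycle_amplitude=0.0,
            rem_cycle_amplitude=0.0,
            n3_night_decline=0.0,
            rem_night_rise=0.0,
        ).null_effect()
        profile = sc.draw_profile(spec, 0, 3)
        profile = dataclasses.replace(
            profile, stage_offset={s: 0.0 for s in sc.STAGES}
        )
        n_runs = 60
        diffs = {s: [] for s in sc.STAGES}
        for i in range(n_runs):
            hyp = sc.generate_hypnogram(profile, "LM", spec, np.random.default_rng(i))
            first, second = hyp[:450], hyp[450:]
            for s in sc.STAGES:
                diffs[s].append((first == s).mean() - (second == s).mean())
        for s in sc.STAGES:
            _, p = stats.ttest_1samp(diffs[s], 0.0)
            assert p > 0.01, f"stage {s} proportions drift between night halves"

    def test_max_persistence_single_stage(self):
        spec = dataclasses.replace(sc.CohortSpec(seed=0), persistence=1.0)
        profile = sc.draw_profile(spec, 0, 1)
        hyp = sc.generate_hypnogram(profile, "LM", spec, np.random.default_rng(3))
        assert len(set(hyp)) == 1

    def test_minimum_bout_length(self, default_cohort):
        for c in default_cohort[:10]:
            hyp = c.lm.hypnogram
            changes = np.flatnonzero(hyp[1:] != hyp[:-1]) + 1
            bounds = np.concatenate(([0], changes, [len(hyp)]))
            lengths = np.diff(bounds)
            assert lengths.min() >= 2  # >= 1 min

    def test_folded_peak_locations_majority_of_seeds(self):
        # group-mean folded LM timecourse: N3 peaks in cycle bins 0-2 and REM
        # in bins 8-10 for the majority of seeds
        from thermosleep import cycle_spectral as cs

        n3_ok = rem_ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = dataclasses.replace(sc.CohortSpec(seed=seed), study_sizes=(4, 4, 4))
            folded_n3 = []
            folded_rem = []
            for idx in range(spec.n_subjects):
                profile = sc.draw_profile(spec, idx, 1 + idx % 3)
                hyp = sc.generate_hypnogram(
                    profile, "LM", spec, np.random.default_rng((seed, idx))
                )
                binned = prep.bin_hypnogram(hyp)
                folded_n3.append(cs.fold_cycles(binned["N3"].to_numpy()).cycle_mean)
                folded_rem.append(cs.fold_cycles(binned["REM"].to_numpy()).cycle_mean)
            n3_ok += int(np.mean(folded_n3, axis=0).argmax()) in (0, 1, 2)
            rem_ok += int(np.mean(folded_rem, axis=0).argmax()) in (8, 9, 10)
        assert n3_ok > n_seeds // 2
        assert rem_ok > n_seeds // 2


class TestPhysiologyModel:
    @pytest.fixture()
    def noise_free_spec(self):
        return sc.CohortSpec(
            seed=0,
            noise_sd={"CBT": 0.0, "PBT": 0.0, "MAT": 0.0, "HR": 0.0},
            sensor_offset_sd={"PBT": 0.0, "MAT": 0.0},
            resp_jitter_sd={"CBT": 0.0, "PBT": 0.0, "MAT": 0.0},
        )

    def _profile(self, spec, g):
        profile = sc.draw_profile(spec, 0, 1)
        return dataclasses.replace(
            profile,
            g_i=g,
            resp_mult={"CBT": 1.0, "PBT": 1.0, "MAT": 1.0},
            sensor_offset={"PBT": (0.0,) * 3, "MAT": (0.0,) * 5},
        )

    def test_cooling_minima_rank_order(self, noise_free_spec):
        profile = self._profile(noise_free_spec, 0.4)
        rng = np.random.default_rng(0)
        hm = sc.generate_physiology(profile, "HM", noise_free_spec, rng)
        lm = sc.generate_physiology(profile, "LM", noise_free_spec, rng)
        argmin_t = {}
        for var in ("MAT", "PBT", "CBT"):
            delta = hm[var].values[0] - lm[var].values[0]
            argmin_t[var] = hm[var].times_s[np.argmin(delta)]
        assert argmin_t["MAT"] <= argmin_t["PBT"] <= argmin_t["CBT"]
        # minima at the closed-form peak times of the cooling kinetics
        for var, tau in (("MAT", noise_free_spec.tau_mat), ("CBT", noise_free_spec.tau_cbt)):
            expected = sc.cooling_peak_time_min(tau, noise_free_spec.tau_recovery)
            assert argmin_t[var] / 60.0 == pytest.approx(expected, abs=1.5)

    def test_hr_coupled_exactly_to_cbt(self, noise_free_spec):
        profile = self._profile(noise_free_spec, 0.5)
        hm = sc.generate_physiology(profile, "HM", noise_free_spec, np.random.default_rng(0))
        lm = sc.generate_physiology(profile, "LM", noise_free_spec, np.random.default_rng(1))
        d_hr = hm["HR"].values[0] - lm["HR"].values[0]
        t_min = hm["HR"].times_s / 60.0
        d_cbt_curve = sc.cooling_delta(profile, noise_free_spec, "CBT", t_min)
        np.testing.assert_allclose(d_hr, noise_free_spec.hr_cbt_slope * d_cbt_curve, atol=1e-9)

    def test_nightly_mean_gradient_equals_g(self, noise_free_spec):
        # calibration: nightly-mean HM-LM change of CBT-PBT equals g_i
        profile = self._profile(noise_free_spec, 0.37)
        t_min = (np.arange(45) + 0.5) * 10.0
        d_grad = sc.cooling_delta(profile, noise_free_spec, "CBT", t_min) - sc.cooling_delta(
            profile, noise_free_spec, "PBT", t_min
        )
        assert d_grad.mean() == pytest.approx(0.37, rel=5e-3)


class TestGenerativeCorrelation:
    def test_gradient_n3_correlation_matches_variance_decomposition(self):
        """Empirical corr(delta gradient, second-part delta N3) vs the
        law-of-total-variance oracle assembled from fixed-g brute-force runs."""
        sd_g = sc.CohortSpec().hm_gradient_sd
        mu_g = sc.CohortSpec().hm_gradient_mean

        def fixed_g_run(g0, seed):
            spec = dataclasses.replace(
                sc.CohortSpec(seed=seed),
                study_sizes=(40, 40, 40),
                hm_gradient_mean=g0,
                hm_gradient_sd=0.0,
            )
            cohort = sc.generate_cohort(spec)
            n3 = np.array(
                [
                    second_part_stage_minutes(c.hm, "N3")
                    - second_part_stage_minutes(c.lm, "N3")
                    for c in cohort
                ]
            )
            grad = np.array(
                [
                    prep.paired_delta(
                        prep.bin_night(c.hm), prep.bin_night(c.lm)
                    ).nightly_mean["CBT-PBT"]
                    for c in cohort
                ]
            )
            return n3, grad

        n3_lo, gr_lo = fixed_g_run(mu_g - 0.5 * sd_g, seed=101)
        n3_hi, gr_hi = fixed_g_run(mu_g + 0.5 * sd_g, seed=102)
        k_n3 = (n3_hi.mean() - n3_lo.mean()) / sd_g
        k_g = (gr_hi.mean() - gr_lo.mean()) / sd_g
        v_n3 = 0.5 * (n3_lo.var(ddof=1) + n3_hi.var(ddof=1))
        v_g = 0.5 * (gr_lo.var(ddof=1) + gr_hi.var(ddof=1))
        r_oracle = (k_n3 * k_g * sd_g**2) / np.sqrt(
            (k_n3**2 * sd_g**2 + v_n3) * (k_g**2 * sd_g**2 + v_g)
        )

        spec = dataclasses.replace(sc.CohortSpec(seed=5), study_sizes=(70, 70, 60))
        cohort = sc.generate_cohort(spec)
        n3 = np.array(
            [
                second_part_stage_minutes(c.hm, "N3")
                - second_part_stage_minutes(c.lm, "N3")
                for c in cohort
            ]
        )
        grad = np.array(
            [
                prep.paired_delta(prep.bin_night(c.hm), prep.bin_night(c.lm)).nightly_mean[
                    "CBT-PBT"
                ]
                for c in cohort
            ]
        )
        r_emp = np.corrcoef(grad, n3)[0, 1]
        assert r_emp > 0
        assert r_oracle > 0
        # Fisher-z 99% Monte-Carlo band around the oracle (n = 200), plus
        # slack for the oracle's own simulation error
        z_tol = 2.58 / np.sqrt(len(grad) - 3) + 0.08
        assert abs(np.arctanh(r_emp) - np.arctanh(r_oracle)) < z_tol
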
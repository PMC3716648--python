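import dataclasses

import numpy as np
import pandas as pd
import pytest

from icuglyc.errors import ConfigError, ProtocolError
from icuglyc.synthetic import (DEFAULT_PROTOCOL, PatientProfile, SimConfig,
                               SlidingScaleProtocol, build_schedules,
                               generate_cohort, integrate, simulate_patient,
                               sliding_scale_insulin)

PROFILE = PatientProfile("p01", "trauma", 50.0, 30.0, False, 5.0)


def quiet_config(**kw):
    base = dict(seed=0, duration_hours=6.0, basal_glucose_mgdl=120.0,
                circadian_amplitude_mgdl=0.0, insulin_sensitivity=0.0,
                dextrose_gain=0.0, stress_pulse_rate_per_day=0.0,
                ar_noise_sd_mgdl=0.0, sensor_noise_sd_mgdl=0.0,
                target_composition=(0.0, 1.0, 0.0))
    base.update(kw)
    return SimConfig(**base)


class TestDynamics:
    def test_all_dynamics_off_gives_constant_cgm(self):
        truth, cgm, _ = simulate_patient(PROFILE, quiet_config())
        assert np.all(truth.serum == 120.0)
        assert np.all(cgm.values == 120.0)

    def test_zero_lag_no_noise_cgm_equals_serum(self):
        cfg = quiet_config(interstitial_lag_minutes=0.0,
                           circadian_amplitude_mgdl=10.0,
                           stress_pulse_rate_per_day=4.0)
        truth, cgm, _ = simulate_patient(PROFILE, cfg)
        np.testing.assert_array_equal(cgm.values, truth.serum)

    def test_interstitial_lag_maximizes_cross_correlation_at_lag(self):
        # noise channels off, but enough signal variation for a sharp peak
        cfg = quiet_config(duration_hours=24.0, circadian_amplitude_mgdl=15.0,
                           stress_pulse_rate_per_day=8.0,
                           target_composition=(0.045, 0.838, 0.117))
        truth, cgm, _ = simulate_patient(PROFILE, cfg)
        s = truth.serum - truth.serum.mean()
        c = cgm.values - cgm.values.mean()
        corrs = [np.corrcoef(s[:-k], c[k:])[0, 1] if k else np.corrcoef(s, c)[0, 1]
                 for k in range(7)]
        # true lag is 12.5 min = 2.5 grid steps
        assert int(np.argmax(corrs)) in (2, 3)

    def test_component_log_conserves_serum_differences(self):
        truth, _, _ = simulate_patient(
            PROFILE, SimConfig(seed=11, duration_hours=24.0))
        comp = truth.component_log.to_numpy()
        for t in range(len(comp)):
            assert truth.serum[t + 1] == truth.serum[t] + comp[t].sum()

    def test_serum_stays_above_floor_and_positive(self):
        truth, _, _ = simulate_patient(
            PROFILE, SimConfig(seed=5, duration_hours=24.0,
                               target_composition=(0.3, 0.4, 0.3)))
        assert np.all(truth.serum > 0)
        assert truth.serum.min() >= 40.0 - 1e-9

    def test_default_composition_matches_target_within_5_points(self):
        for seed in (1, 2, 3):
            truth, _, _ = simulate_patient(
                PROFILE, SimConfig(seed=seed, duration_hours=24.0))
            for state, target in zip(("hypo", "normo", "hyper"),
                                     (4.5, 83.8, 11.7)):
                assert abs(truth.composition[state] - target) <= 5.0
            assert not truth.composition_warning


class TestCouplingDirections:
    """Open-loop monotonicity: more dextrose never lowers later serum,
    more insulin never raises it."""

    @staticmethod
    def _schedules(cfg):
        rng = np.random.default_rng(cfg.seed)
        sched = build_schedules(cfg, rng)
        sched.noise[:] = 0.0
        sched.insulin_override = np.zeros(cfg.n_steps)
        return sched

    def test_dextrose_is_monotone_increasing(self):
        cfg = SimConfig(seed=2, duration_hours=6.0, ar_noise_sd_mgdl=0.0)
        sched = self._schedules(cfg)
        base, *_ = integrate(sched, cfg)
        sched.dextrose_rate = sched.dextrose_rate.copy()
        sched.dextrose_rate[20] += 100.0
        bumped, *_ = integrate(sched, cfg)
        assert np.all(bumped >= base - 1e-12)

    def test_insulin_is_monotone_decreasing(self):
        cfg = SimConfig(seed=2, duration_hours=6.0, ar_noise_sd_mgdl=0.0)
        sched = self._schedules(cfg)
        base, *_ = integrate(sched, cfg)
        sched.insulin_override = sched.insulin_override.copy()
        sched.insulin_override[20] += 15.0
        dosed, *_ = integrate(sched, cfg)
        assert np.all(dosed <= base + 1e-12)


class TestSlidingScale:
    BANDS = SlidingScaleProtocol(bands=((0.0, 150.0, 0.0), (150.0, 200.0, 2.0),
                                        (200.0, float("inf"), 4.0)))

    @pytest.mark.parametrize("poc,expected", [(100.0, 0.0), (150.0, 2.0),
                                              (199.9, 2.0), (250.0, 4.0)])
    def test_band_lookup_closed_on_left(self, poc, expected):
        units, route = sliding_scale_insulin(poc, self.BANDS)
        assert units == expected
        assert route in ("infusion", "subcutaneous")

    def test_dose_is_monotone_in_glucose(self):
        grid = np.linspace(45, 500, 200)
        doses = [sliding_scale_insulin(g, DEFAULT_PROTOCOL)[0] for g in grid]
        assert all(b >= a for a, b in zip(doses, doses[1:]))

    def test_gapped_bands_rejected(self):
        with pytest.raises(ProtocolError):
            SlidingScaleProtocol(bands=((0.0, 150.0, 0.0),
                                        (160.0, float("inf"), 2.0)))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ProtocolError):
            SlidingScaleProtocol(bands=((0.0, 150.0, 0.0),
                                        (140.0, float("inf"), 2.0)))


class TestEventStreams:
    def test_poc_intervals_within_configured_bounds(self):
        _, _, records = simulate_patient(
            PROFILE, SimConfig(seed=9, duration_hours=24.0))
        poc = records.subset("poc_glucose", "glucose")
        gaps = np.diff(poc["timestamp"].to_numpy()) / np.timedelta64(1, "m")
        assert np.all(gaps >= 59.0) and np.all(gaps <= 121.0)

    def test_determinism_same_config_bit_identical(self):
        cfg = SimConfig(seed=17, duration_hours=12.0)
        t1, c1, r1 = simulate_patient(PROFILE, cfg)
        t2, c2, r2 = simulate_patient(PROFILE, cfg)
        np.testing.assert_array_equal(t1.serum, t2.serum)
        np.testing.assert_array_equal(c1.values, c2.values)
        pd.testing.assert_frame_equal(r1.events, r2.events)

    def test_heart_rate_positively_coupled_to_glucose(self):
        truth, _, records = simulate_patient(
            PROFILE, SimConfig(seed=21, duration_hours=24.0))
        hr = records.subset("vital_signs", "heart_rate")
        idx = ((hr["timestamp"] - truth.times[0]).dt.total_seconds() / 300).astype(int)
        r = np.corrcoef(truth.serum[idx], hr["value"].astype(float))[0, 1]
        assert r > 0.5


class TestValidation:
    def test_short_duration_rejected(self):
        with pytest.raises(ConfigError):
            simulate_patient(PROFILE, SimConfig(duration_hours=1.0))

    def test_uneven_sampling_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(duration_hours=5.0, sample_minutes=7.0)

    def test_bad_composition_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(target_composition=(0.5, 0.4, 0.2))

    def test_underage_profile_rejected(self):
        with pytest.raises(ConfigError):
            PatientProfile("kid", "trauma", 16.0, 25.0, False, 2.0)


class TestCohort:
    def test_single_patient_manifest(self, tmp_path):
        out = tmp_path / "cohort"
        cohort = generate_cohort(1, SimConfig(duration_hours=4.0), seed=5,
                                 out_dir=out)
        assert len(cohort.manifest) == 1
        assert (out / "manifest.csv").exists()
        assert (out / "patient_01.cgm.csv").exists()

    def test_default_split_mirrors_14_of_19(self):
        cohort = generate_cohort(19, SimConfig(duration_hours=2.0), seed=1)
        splits = cohort.manifest["split"].tolist()
        assert splits.count("train") == 14 and splits.count("test") == 5
        assert splits[:14] == ["train"] * 14

    def test_same_master_seed_gives_identical_manifest_bytes(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_cohort(3, SimConfig(duration_hours=4.0), seed=42, out_dir=a)
        generate_cohort(3, SimConfig(duration_hours=4.0), seed=42, out_dir=b)
        assert (a / "manifest.csv").read_bytes() == (b / "manifest.csv").read_bytes()

    def test_existing_output_dir_refused_without_overwrite(self, tmp_path):
        out = tmp_path / "cohort"
        generate_cohort(1, SimConfig(duration_hours=4.0), seed=5, out_dir=out)
        with pytest.raises(ConfigError):
            generate_cohort(1, SimConfig(duration_hours=4.0), seed=5, out_dir=out)
        generate_cohort(1, SimConfig(duration_hours=4.0), seed=5, out_dir=out,
                        overwrite=True)
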
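"""Generator contracts: band confinement, amplitude-power law, schedules, determinism."""

import numpy as np
import pytest

import eegfatigue.calibration as cal
from eegfatigue.bands import BANDS
from eegfatigue.recording import SCENTS
from eegfatigue.simulate import (
    ScenarioConfig,
    SubjectTraits,
    default_fatigue_envelopes,
    identification_scenario,
    intervention_multiplier,
    intervention_scenario,
    simulate_cohort,
    simulate_eeg,
    simulate_kss,
)
from eegfatigue.preprocess import epoch_split, aggregate_temporal
from eegfatigue.spectral import band_powers, periodogram

from conftest import make_epoch


def band_variance(x, fs, low, high):
    spec = periodogram(make_epoch(x, fs=fs))
    mask = (spec.freqs >= low) & (spec.freqs < high)
    return spec.psd[mask].sum() * spec.resolution


class TestSimulateEEG:
    def test_null_generator_is_silent(self):
        config = identification_scenario(
            band_envelopes={b.name: [(0.0, 0.0)] for b in BANDS},
            noise_sd=0.0, minute_amp_sd=0.0, duration_min=1.0,
        )
        rec = simulate_eeg(config)
        assert np.all(rec.samples == 0.0)

    def test_alpha_only_variance_is_confined(self, stationary_alpha_config):
        rec = simulate_eeg(stationary_alpha_config)
        x = rec.samples[0]
        in_band = band_variance(x, rec.sampling_rate, 8.0, 12.0)
        total = band_variance(x, rec.sampling_rate, 0.0, rec.sampling_rate / 2)
        assert in_band == pytest.approx(1.0, rel=0.05)
        assert total - in_band == pytest.approx(0.0, abs=1e-9)

    def test_band_confinement_all_bands(self):
        config = identification_scenario(
            noise_sd=0.0, minute_amp_sd=0.0, duration_min=1.0
        )
        for band in BANDS:
            cfg = ScenarioConfig(
                **{**vars(config), "band_envelopes": {band.name: [(0.0, 1.0)]}}
            )
            rec = simulate_eeg(cfg)
            x = rec.samples[0]
            inside = band_variance(x, rec.sampling_rate, band.low, band.high)
            total = band_variance(x, rec.sampling_rate, 0.0, rec.sampling_rate / 2)
            assert inside / total >= 0.95

    def test_amplitude_to_power_law(self):
        """Doubling a band's amplitude quadruples its average PSD (within 10%)."""
        powers = []
        for amp in (1.0, 2.0):
            config = identification_scenario(
                band_envelopes={"beta": [(0.0, amp)]},
                noise_sd=0.0, minute_amp_sd=0.0, duration_min=1.0,
            )
            rec = simulate_eeg(config)
            powers.append(band_powers(epoch_split(aggregate_temporal(rec))[0]).G_beta)
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.10)

    def test_stationary_minute_variance_matches_envelope(self):
        """Over a stationary 60-s stretch each band contributes (a_b * m_b)^2."""
        config = identification_scenario(
            band_envelopes={"theta": [(0.0, 0.7)]},
            noise_sd=0.0, minute_amp_sd=0.0, duration_min=2.0,
        )
        rec = simulate_eeg(config)
        for ep in epoch_split(aggregate_temporal(rec)):
            assert ep.samples.var() == pytest.approx(0.49, rel=0.10)

    def test_beta_halving_quadruples_alpha_beta_ratio(self, short_fatigue_config):
        """R(alpha/beta) scales as 1/a_beta^2: halving beta ~quadruples it."""
        from eegfatigue.studies import subject_pipeline

        rec = simulate_eeg(short_fatigue_config)
        series, _ = subject_pipeline(rec)
        assert series.R_ab[29] / series.R_ab[0] == pytest.approx(4.0, rel=0.12)

    def test_rejects_sub_nyquist_sampling_rate(self):
        with pytest.raises(ValueError, match="Nyquist"):
            identification_scenario(sampling_rate=80.0)

    def test_recording_shape_and_events(self):
        config = intervention_scenario("peppermint", duration_min=45.0)
        rec = simulate_eeg(config)
        assert rec.n_samples == 45 * 60 * 128
        assert rec.n_channels == 2
        assert rec.events["intervention"] == 30.0


class TestEnvelopes:
    def test_minute_zero_equals_baseline(self):
        env = default_fatigue_envelopes()
        for name, traj in env.items():
            assert traj[0] == (0.0, cal.BAND_BASELINE[name])

    def test_beta_declines_most_alpha_least(self):
        env = default_fatigue_envelopes()

        def rel_change(name, minute=30.0):
            xs, ys = zip(*env[name])
            return abs(np.interp(minute, xs, ys) / ys[0] - 1.0)

        assert rel_change("beta") > rel_change("alpha")
        assert rel_change("beta") == max(rel_change(n) for n in ("theta", "alpha", "beta", "gamma"))

    def test_theta_nondecreasing_first_half(self):
        xs, ys = zip(*default_fatigue_envelopes()["theta"])
        grid = np.linspace(0, 30, 61)
        vals = np.interp(grid, xs, ys)
        assert np.all(np.diff(vals) >= 0)


def induced_ratio_curve(scent, taus):
    mult = intervention_multiplier(scent, taus)
    return (mult["alpha"] / mult["beta"]) ** 2


class TestInterventionMultiplier:
    def test_identity_at_release(self):
        for scent in SCENTS:
            mult = intervention_multiplier(scent, 0.0)
            for arr in mult.values():
                assert np.all(arr == 1.0)

    def test_control_is_identity_everywhere(self):
        mult = intervention_multiplier("control", np.linspace(0, 15, 50))
        for arr in mult.values():
            assert np.all(arr == 1.0)

    def test_unknown_scent_rejected(self):
        with pytest.raises(ValueError, match="unknown scent"):
            intervention_multiplier("vanilla", 1.0)

    def test_lavender_suppression_lasts_ten_minutes(self):
        taus = np.linspace(0.25, 10.0, 100)
        assert np.all(induced_ratio_curve("lavender", taus) < 1.0)

    def test_nadir_ordering_grapefruit_peppermint_lavender(self):
        taus = np.linspace(0.0, 20.0, 2001)
        nadirs = {s: taus[np.argmin(induced_ratio_curve(s, taus))] for s in SCENTS}
        assert nadirs["grapefruit"] < nadirs["peppermint"] < nadirs["lavender"]

    def test_peppermint_recovers_fastest(self):
        taus = np.linspace(8.0, 12.0, 20)
        pep = induced_ratio_curve("peppermint", taus)
        lav = induced_ratio_curve("lavender", taus)
        assert np.all(pep > lav)


class TestSimulateKSS:
    def test_deterministic_constant_scenario(self):
        config = identification_scenario(
            kss_baseline=5.0, kss_drift=0.0, kss_subject_sd=0.0, kss_noise_sd=0.0,
            n_subjects=4,
        )
        records = simulate_kss(config)
        assert {r.score for r in records} == {5}
        assert len(records) == 4 * 2

    def test_scores_always_in_range(self):
        config = intervention_scenario("peppermint", kss_baseline=20.0, n_subjects=6, seed=3)
        assert all(1 <= r.score <= 9 for r in simulate_kss(config))
        config = intervention_scenario("peppermint", kss_baseline=-20.0, n_subjects=6, seed=3)
        assert all(r.score == 1 for r in simulate_kss(config))

    def test_control_drift_matches_calibrated_rise(self):
        """Monte-Carlo mean 40-min minus 28-min rise close to the 2.273 target."""
        diffs = []
        for seed in range(200):
            config = intervention_scenario("control", n_subjects=11, seed=seed)
            records = simulate_kss(config)
            by_t = {}
            for r in records:
                by_t.setdefault(r.time_min, []).append(r.score)
            diffs.append(np.mean(by_t[40.0]) - np.mean(by_t[28.0]))
        assert np.mean(diffs) == pytest.approx(2.273, abs=0.5)

    def test_scent_drop_lowers_post_scores(self):
        config = intervention_scenario("peppermint", n_subjects=50, seed=7)
        records = simulate_kss(config)
        post = [r.score for r in records if r.time_min == 40.0]
        pre = [r.score for r in records if r.time_min == 28.0]
        assert np.mean(post) < np.mean(pre)


class TestSimulateCohort:
    def test_identification_bookkeeping(self):
        ds = simulate_cohort("identification", n_subjects=2, seed=0)
        assert ds.groups() == ["control"]
        for rec in ds.recordings["control"].values():
            assert rec.n_samples == 30 * 60 * 128
        assert len(ds.kss) == 2 * 2

    def test_intervention_bookkeeping(self):
        ds = simulate_cohort("intervention", n_subjects=2, seed=0)
        n_rec = sum(len(v) for v in ds.recordings.values())
        assert n_rec == 4 * 2
        assert len(ds.kss) == 4 * 2 * 2
        assert sorted(ds.kss.time_min.unique()) == [28.0, 40.0]

    def test_same_seed_identical_output(self):
        a = simulate_cohort("identification", n_subjects=2, seed=42)
        b = simulate_cohort("identification", n_subjects=2, seed=42)
        for sid in a.recordings["control"]:
            assert np.array_equal(
                a.recordings["control"][sid].samples, b.recordings["control"][sid].samples
            )
        assert a.kss.equals(b.kss)

    def test_different_seeds_differ(self):
        a = simulate_cohort("identification", n_subjects=2, seed=1)
        b = simulate_cohort("identification", n_subjects=2, seed=2)
        assert not np.array_equal(
            a.recordings["control"]["S01"].samples, b.recordings["control"]["S01"].samples
        )

    def test_rejects_tiny_cohort_and_unknown_study(self):
        with pytest.raises(ValueError):
            simulate_cohort("identification", n_subjects=1)
        with pytest.raises(ValueError, match="unknown study"):
            simulate_cohort("countermeasure")
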
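"""Generator unit and property tests: PK model, per-modality simulators, cohort."""

import numpy as np
import pytest
from scipy import signal as sps

from filmsense.features import segment_signal, window_energy
from filmsense.synth import (
    CohortConfig,
    PKProfile,
    PLACEBO_PK,
    SubjectParams,
    bateman_concentration,
    bateman_tmax,
    effect_profile,
    generate_cohort,
    simulate_ecg,
    simulate_eda,
    simulate_resp,
)


class TestBateman:
    def test_zero_at_time_zero(self):
        assert bateman_concentration(0.0, dose=3.0, ka=0.5, ke=0.05) == 0.0

    def test_peak_time_matches_closed_form(self):
        ka, ke = 0.1, 0.01
        t = np.linspace(0.0, 200.0, 2_000_001)
        curve = bateman_concentration(t, 1.0, ka, ke)
        t_peak = t[np.argmax(curve)]
        assert t_peak == pytest.approx(np.log(ka / ke) / (ka - ke), abs=1e-3)
        assert bateman_tmax(ka, ke) == pytest.approx(np.log(10) / 0.09, rel=1e-12)

    def test_equal_rates_analytic_limit(self):
        # ka == ke: C(t) = dose * ka * t * exp(-ka t)
        val = bateman_concentration(20.0, dose=1.0, ka=0.05, ke=0.05)
        assert val == pytest.approx(0.05 * 20.0 * np.exp(-1.0), rel=1e-12)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            bateman_concentration(-1.0, 1.0, 0.1, 0.01)
        with pytest.raises(ValueError):
            bateman_concentration(1.0, 1.0, -0.1, 0.01)
        with pytest.raises(ValueError):
            bateman_concentration(1.0, 1.0, 0.1, 0.0)

    def test_nonnegative_everywhere(self):
        t = np.linspace(0.0, 500.0, 10_000)
        assert np.all(bateman_concentration(t, 2.0, 0.3, 0.02) >= 0.0)


class TestEffectProfile:
    def test_placebo_is_identically_zero(self):
        t = np.linspace(0.0, 60.0, 1000)
        assert np.all(effect_profile(t, PLACEBO_PK) == 0.0)

    def test_single_compartment_degenerate(self):
        pk = PKProfile(dose_free=1.5, dose_encapsulated=0.0, lag=0.0)
        t = np.linspace(0.0, 60.0, 500)
        expected = bateman_concentration(t, 1.5, pk.ka_free, pk.ke)
        np.testing.assert_allclose(effect_profile(t, pk), expected, rtol=1e-12)

    def test_two_compartments_sum_term_by_term(self):
        # independent evaluation of each Bateman term is the oracle
        pk = PKProfile(dose_free=1.0, dose_encapsulated=1.0, ka_free=0.2,
                       ka_encapsulated=0.02, ke=0.01, lag=0.0)
        t = np.linspace(0.0, 100.0, 2000)
        oracle = (
            pk.dose_free * pk.ka_free / (pk.ka_free - pk.ke)
            * (np.exp(-pk.ke * t) - np.exp(-pk.ka_free * t))
            + pk.dose_encapsulated * pk.ka_encapsulated / (pk.ka_encapsulated - pk.ke)
            * (np.exp(-pk.ke * t) - np.exp(-pk.ka_encapsulated * t))
        )
        np.testing.assert_allclose(effect_profile(t, pk), oracle, rtol=1e-10)

    def test_zero_before_lag(self):
        pk = PKProfile(lag=5.0)
        t = np.linspace(0.0, 20.0, 400)
        assert np.all(effect_profile(t, pk)[t < 5.0] == 0.0)

    def test_rejects_unsorted_grid(self):
        with pytest.raises(ValueError):
            effect_profile(np.array([3.0, 1.0, 2.0]), PKProfile())


class TestSimulateECG:
    def test_sample_count(self, quiet_subject):
        fs, minutes = 80.0, 5.0
        n = int(minutes * 60 * fs)
        rec = simulate_ecg(minutes, fs, quiet_subject, np.zeros(n), seed=0)
        assert rec.n_samples == n
        assert rec.modality == "ECG"

    def test_beat_count_matches_heart_rate(self, quiet_subject):
        # 60 bpm for 5 min: 300 R peaks within 2 % on the noise-free signal
        fs, minutes = 80.0, 5.0
        n = int(minutes * 60 * fs)
        rec = simulate_ecg(minutes, fs, quiet_subject, np.zeros(n), seed=3, noise_sd=0.0)
        peaks, _ = sps.find_peaks(rec.samples, height=0.5, distance=int(0.4 * fs))
        assert abs(peaks.size - 300) <= 6

    def test_deterministic_given_seed(self, quiet_subject):
        fs, minutes = 80.0, 2.0
        eff = np.linspace(0, 1, int(minutes * 60 * fs))
        a = simulate_ecg(minutes, fs, quiet_subject, eff, seed=11)
        b = simulate_ecg(minutes, fs, quiet_subject, eff, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_rejects_mismatched_effect_grid(self, quiet_subject):
        with pytest.raises(ValueError):
            simulate_ecg(5.0, 80.0, quiet_subject, np.zeros(10), seed=0)


class TestSimulateEDA:
    def test_conductance_nonnegative(self):
        sub = SubjectParams("S01", eda_tonic=0.5)
        n = int(5 * 60 * 80)
        rec = simulate_eda(5.0, 80.0, sub, np.zeros(n), seed=5)
        assert np.all(rec.samples >= 0.0)

    def test_scr_event_rate_matches_poisson_expectation(self):
        # 3 events/min for 10 min: mean count 30 across 200 seeds, within 15 %
        sub = SubjectParams("S01", scr_rate=3.0)
        fs, minutes = 50.0, 10.0
        n = int(minutes * 60 * fs)
        zeros = np.zeros(n)
        counts = [
            simulate_eda(minutes, fs, sub, zeros, seed=s, return_events=True)[1].size
            for s in range(200)
        ]
        assert np.mean(counts) == pytest.approx(30.0, rel=0.15)

    def test_terminal_artifact_raises_final_segment_energy(self):
        sub = SubjectParams("S01")
        fs, minutes = 50.0, 20.0
        n = int(minutes * 60 * fs)
        rec = simulate_eda(minutes, fs, sub, np.zeros(n), seed=9,
                           artifact_final_segment=True)
        x = rec.samples - rec.samples.mean()
        energies = [
            window_energy(seg, fs, window_s=5.0).energies.mean()
            for seg in segment_signal(rec.with_samples(x), segment_min=5.0)
        ]
        assert energies[-1] > np.mean(energies[:-1])

    def test_deterministic_given_seed(self):
        sub = SubjectParams("S01")
        n = int(2 * 60 * 80)
        a = simulate_eda(2.0, 80.0, sub, np.zeros(n), seed=4)
        b = simulate_eda(2.0, 80.0, sub, np.zeros(n), seed=4)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSimulateResp:
    def test_dominant_frequency_is_breathing_rate(self):
        # 15 breaths/min = 0.25 Hz; noise-free periodogram peaks there
        sub = SubjectParams("S01", resp_rate=15.0)
        fs, minutes = 80.0, 10.0
        n = int(minutes * 60 * fs)
        rec = simulate_resp(minutes, fs, sub, np.zeros(n), seed=2,
                            noise_sd=0.0, am_depth=0.0)
        freqs, power = sps.periodogram(rec.samples, fs=fs)
        bin_width = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(power)] - 0.25) <= bin_width

    def test_effect_raises_mean_instantaneous_frequency(self):
        # count zero crossings as a frequency proxy
        sub = SubjectParams("S01", resp_rate=15.0)
        fs, minutes = 80.0, 10.0
        n = int(minutes * 60 * fs)
        lo = simulate_resp(minutes, fs, sub, np.zeros(n), seed=6,
                           noise_sd=0.0, am_depth=0.0)
        hi = simulate_resp(minutes, fs, sub, np.full(n, 2.0), seed=6,
                           noise_sd=0.0, am_depth=0.0)
        crossings = lambda x: np.sum(np.diff(np.signbit(x)))
        assert crossings(hi.samples) > crossings(lo.samples)

    def test_deterministic_given_seed(self):
        sub = SubjectParams("S01")
        n = int(2 * 60 * 80)
        a = simulate_resp(2.0, 80.0, sub, np.zeros(n), seed=8)
        b = simulate_resp(2.0, 80.0, sub, np.zeros(n), seed=8)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestGenerateCohort:
    def test_record_count_for_thirteen_subjects(self):
        config = CohortConfig(n_subjects=13, duration_min=10.0, baseline_min=0.0,
                              fs=60.0, seed=1)
        records = generate_cohort(config)
        assert len(records) == 78  # 13 subjects x 3 modalities x 2 conditions

    def test_record_length(self):
        config = CohortConfig(n_subjects=2, duration_min=10.0, baseline_min=0.0,
                              fs=100.0, seed=1)
        for rec in generate_cohort(config):
            assert rec.n_samples == 60_000

    def test_cohort_bit_identical_under_same_seed(self):
        config = CohortConfig(n_subjects=2, duration_min=10.0, baseline_min=0.0,
                              fs=60.0, seed=3)
        a, b = generate_cohort(config), generate_cohort(config)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_placebo_records_independent_of_caffeine_dose(self):
        base = dict(n_subjects=2, duration_min=10.0, baseline_min=0.0, fs=60.0, seed=5)
        a = generate_cohort(CohortConfig(**base, pk=PKProfile()))
        b = generate_cohort(CohortConfig(**base, pk=PKProfile().scaled(3.0)))
        for ra, rb in zip(a, b):
            if ra.condition == "placebo":
                np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_adding_a_subject_preserves_existing_subjects(self):
        base = dict(duration_min=10.0, baseline_min=0.0, fs=60.0, seed=5)
        small = generate_cohort(CohortConfig(n_subjects=2, **base))
        large = generate_cohort(CohortConfig(n_subjects=3, **base))
        for ra, rb in zip(small, large[: len(small)]):
            assert ra.subject_id == rb.subject_id
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            CohortConfig(duration_min=5.0)
        with pytest.raises(ValueError):
            CohortConfig(fs=30.0)
        with pytest.raises(ValueError):
            PKProfile(ka_free=0.01, ka_encapsulated=0.02)
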
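"""Generative model: stimuli, observers, behavioral responses, EEG epochs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flickerdur import reference
from flickerdur.synthetic import (
    EpochSet,
    ObserverParams,
    StimulusSpec,
    gen_epochs,
    make_experiment_design,
    p_flicker,
    respond_flicker,
    respond_longer,
    saliency,
    sample_cohort,
    subjective_duration,
    trials_from_csv,
    trials_to_csv,
)


class TestStimulusSpec:
    def test_derived_periods_are_equal_halves(self):
        s = StimulusSpec(10.0, 2.0)
        assert s.on_period_ms == s.off_period_ms == 50.0

    @pytest.mark.parametrize("kwargs", [
        {"frequency": -1.0, "duration": 2.0},
        {"frequency": 10.0, "duration": 0.0},
        {"frequency": 10.0, "duration": 2.0, "on_period_ms": 50.0, "off_period_ms": 40.0},
        {"frequency": 10.0, "duration": 2.0, "on_period_ms": 80.0, "off_period_ms": 80.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StimulusSpec(**kwargs)

    def test_printed_frequencies_consistent_with_periods(self):
        # nominal frequencies deviate <2% from 1/(on+off) of their periods
        for period, freq in zip(sorted(reference.ON_OFF_PERIODS_MS, reverse=True),
                                sorted(reference.PHASE1_FREQUENCIES_HZ)):
            StimulusSpec(freq, 2.0, on_period_ms=period, off_period_ms=period)


class TestExperimentDesign:
    @pytest.mark.parametrize("n_freq, trials, split, expected", [
        (11, 40, (20, 20), 440),   # the full duration-phase design
        (1, 2, (1, 1), 2),
        (10, 20, None, 200),
        (10, 5, None, 50),         # the EEG-phase design
    ])
    def test_trial_counts(self, n_freq, trials, split, expected, rng):
        freqs = list(reference.PHASE3_FREQUENCIES_HZ)[:n_freq] or [10.0]
        freqs = (list(reference.PHASE3_FREQUENCIES_HZ) * 2)[:n_freq]
        stubs = make_experiment_design(freqs, trials, split, rng=rng)
        assert len(stubs) == expected
        counts = pd.Series([t.frequency for t in stubs]).value_counts()
        assert (counts == trials).all()

    def test_balanced_staircase_split(self, rng):
        stubs = make_experiment_design([10.0], 2, (1, 1), rng=rng)
        assert {t.staircase_id for t in stubs} == {"long", "short"}

    def test_odd_split_rejected(self, rng):
        with pytest.raises(ValueError, match="unbalanced|split"):
            make_experiment_design([10.0], 3, (2, 1), rng=rng)

    def test_order_counterbalanced_within_frequency(self, rng):
        stubs = make_experiment_design([10.0, 20.0], 20, (10, 10), rng=rng)
        df = pd.DataFrame([(t.frequency, t.standard_first) for t in stubs],
                          columns=["f", "first"])
        assert (df.groupby("f")["first"].sum() == 10).all()

    def test_order_reproducible_under_seed(self):
        a = make_experiment_design([10.0, 20.0], 4, (2, 2),
                                   rng=np.random.default_rng(3))
        b = make_experiment_design([10.0, 20.0], 4, (2, 2),
                                   rng=np.random.default_rng(3))
        assert [(t.frequency, t.staircase_id) for t in a] == \
               [(t.frequency, t.staircase_id) for t in b]


class TestFlickerPerception:
    def test_half_point_at_alpha_without_lapse(self):
        obs = ObserverParams(fusion_alpha=49.4, lapse=0.0)
        assert p_flicker(obs, 49.4) == pytest.approx(0.5)

    def test_lapse_floor_at_high_frequency(self):
        obs = ObserverParams(fusion_alpha=49.4, lapse=0.1)
        assert p_flicker(obs, 1e6) == pytest.approx(0.05)

    def test_matches_direct_formula(self):
        # independent arithmetic: alpha=49.4, beta=0.5, lapse=0, f=30
        obs = ObserverParams(fusion_alpha=49.4, fusion_beta=0.5, lapse=0.0)
        expected = 1.0 / (1.0 + math.exp(0.5 * (30.0 - 49.4)))
        assert p_flicker(obs, 30.0) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(1.0, 300.0), st.floats(1.0, 300.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonically_nonincreasing_in_frequency(self, f1, f2):
        obs = ObserverParams(fusion_alpha=49.4, fusion_beta=0.3, lapse=0.07)
        lo, hi = sorted([f1, f2])
        assert p_flicker(obs, lo) >= p_flicker(obs, hi) - 1e-12

    def test_bernoulli_rate_matches_probability(self):
        # pick the frequency where the core logistic gives exactly 0.7
        obs = ObserverParams(fusion_alpha=50.0, fusion_beta=0.4, lapse=0.0)
        f = 50.0 - math.log(0.7 / 0.3) / 0.4
        assert p_flicker(obs, f) == pytest.approx(0.7, abs=1e-9)
        rng = np.random.default_rng(0)
        n = 10_000
        hits = sum(respond_flicker(obs, StimulusSpec(f, 2.0), rng) == "flicker"
                   for _ in range(n))
        se = math.sqrt(0.7 * 0.3 / n)
        assert abs(hits / n - 0.7) < 3 * se

    def test_deterministic_extremes(self, rng):
        always = ObserverParams(fusion_alpha=1e4, lapse=0.0)   # p=1 at low f
        never = ObserverParams(fusion_alpha=1e-2, lapse=0.0)   # p~0 at high f
        stim_lo, stim_hi = StimulusSpec(5.0, 2.0), StimulusSpec(160.0, 2.0)
        assert all(respond_flicker(always, stim_lo, rng) == "flicker" for _ in range(50))
        assert all(respond_flicker(never, stim_hi, rng) == "steady" for _ in range(50))


class TestSubjectiveDuration:
    def test_no_gain_is_veridical(self):
        obs = ObserverParams(dilation_gain=0.0)
        assert subjective_duration(obs, StimulusSpec(5.0, 2.0)) == 2.0

    def test_far_above_threshold_is_veridical(self):
        obs = ObserverParams(dilation_gain=0.5, fusion_alpha=50.0)
        assert subjective_duration(obs, StimulusSpec(500.0, 2.0)) == pytest.approx(2.0)

    def test_full_saliency_dilation_arithmetic(self):
        # kappa=0.33, saliency ~ 1, d=2 s -> 2.66 s
        obs = ObserverParams(dilation_gain=0.33, fusion_alpha=100.0, fusion_beta=1.0)
        assert subjective_duration(obs, StimulusSpec(1.0, 2.0)) == \
            pytest.approx(2.66, abs=1e-3)

    @given(st.floats(0.5, 5.0), st.floats(0.5, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linear_in_physical_duration(self, d1, d2):
        obs = ObserverParams(dilation_gain=0.4)
        f = 12.0
        r1 = subjective_duration(obs, StimulusSpec(f, d1)) / d1
        r2 = subjective_duration(obs, StimulusSpec(f, d2)) / d2
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestDurationJudgment:
    def test_obvious_difference(self):
        obs = ObserverParams(dilation_gain=0.0, duration_noise_sd=1e-9)
        rng = np.random.default_rng(0)
        assert respond_longer(obs, StimulusSpec(10.0, 3.5),
                              StimulusSpec(165.7, 2.0), rng) == "longer"

    def test_identical_stimuli_are_a_coin_flip(self):
        obs = ObserverParams(dilation_gain=0.0, duration_noise_sd=0.3)
        rng = np.random.default_rng(1)
        s = StimulusSpec(165.7, 2.0)
        n = 4000
        k = sum(respond_longer(obs, s, s, rng) == "longer" for _ in range(n))
        assert abs(k / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_psychometric_traces_gaussian_cdf(self):
        """P(longer) as a function of test duration follows the closed-form
        normal CDF centered on the analytic point of subjective equality."""
        from scipy.stats import norm

        obs = ObserverParams(dilation_gain=0.33, duration_noise_sd=0.3, rng_seed=5)
        f, fref = 4.0, 165.7
        gain_f = 1.0 + obs.dilation_gain * float(saliency(obs, f))
        gain_ref = 1.0 + obs.dilation_gain * float(saliency(obs, fref))
        pse = 2.0 * gain_ref / gain_f
        rng = np.random.default_rng(2)
        std = StimulusSpec(fref, 2.0)
        n = 3000
        for d in (pse - 0.3, pse, pse + 0.3):
            p_true = norm.cdf((d * gain_f - 2.0 * gain_ref) / obs.duration_noise_sd)
            k = sum(respond_longer(obs, StimulusSpec(f, d), std, rng) == "longer"
                    for _ in range(n))
            se = math.sqrt(max(p_true * (1 - p_true), 1e-4) / n)
            assert abs(k / n - p_true) < 4 * se


class TestEpochGeneration:
    def test_noise_free_amplitude_recovered_exactly(self):
        """With uniform channel gains, zero noise, and a frequency expressible
        on the trimmed grid, the spectrum returns the injected amplitude."""
        from flickerdur.ssvep import amplitude_spectrum, trim_and_average

        obs = ObserverParams(ssvep_amp_uv=2.5, ssvep_peak_hz=100.0,
                             ssvep_threshold_true=200.0)
        es = gen_epochs(obs, StimulusSpec(8.0, 6.0), n_trials=3, n_channels=2,
                        fs=256.0, epoch_len=6.0, pink_sd_uv=0.0, white_sd_uv=0.0,
                        channel_gain_sd=0.0, channel_phase_sd=0.0)
        trace, nc = trim_and_average(es, 8.0, 2.0)
        spec = amplitude_spectrum(trace, 256.0, nc)
        assert spec.at(8.0) == pytest.approx(2.5, rel=1e-9)

    def test_amplitude_zero_above_true_threshold(self):
        obs = ObserverParams(ssvep_amp_uv=2.0, ssvep_threshold_true=60.0)
        es = gen_epochs(obs, StimulusSpec(82.9, 2.0), n_trials=2, n_channels=2,
                        fs=512.0, epoch_len=2.0, pink_sd_uv=0.0, white_sd_uv=0.0)
        assert np.allclose(es.data, 0.0)

    def test_zero_amplitude_curve_gives_pure_noise(self):
        obs = ObserverParams(ssvep_amp_uv=0.0)
        rng = np.random.default_rng(0)
        es = gen_epochs(obs, StimulusSpec(10.0, 2.0), n_trials=2, n_channels=2,
                        fs=256.0, epoch_len=2.0, rng=rng)
        assert es.data.std() > 0

    def test_aliasing_rejected(self):
        obs = ObserverParams()
        with pytest.raises(ValueError, match="alias"):
            gen_epochs(obs, StimulusSpec(165.7, 2.0), fs=256.0, epoch_len=2.0)

    def test_bit_reproducible_under_seed(self):
        obs = ObserverParams(rng_seed=9)
        kwargs = dict(n_trials=2, n_channels=3, fs=256.0, epoch_len=2.0)
        a = gen_epochs(obs, StimulusSpec(12.0, 2.0), seed=77, **kwargs)
        b = gen_epochs(obs, StimulusSpec(12.0, 2.0), seed=77, **kwargs)
        assert np.array_equal(a.data, b.data)

    def test_hdf5_round_trip(self, tmp_path):
        obs = ObserverParams(participant_id="obs007", rng_seed=1)
        es = gen_epochs(obs, StimulusSpec(15.7, 2.0), n_trials=2, n_channels=2,
                        fs=256.0, epoch_len=2.0, seed=3)
        es.seed = 3
        path = tmp_path / "e.h5"
        es.to_hdf5(path)
        back = EpochSet.from_hdf5(path)
        assert np.array_equal(back.data, es.data)
        assert back.fs == es.fs and back.stim_freq == es.stim_freq
        assert back.participant_id == "obs007" and back.seed == 3


class TestCohortAndIO:
    def test_cohort_distribution_and_reproducibility(self):
        a = sample_cohort(30, seed=4)
        b = sample_cohort(30, seed=4)
        assert [o.fusion_alpha for o in a] == [o.fusion_alpha for o in b]
        alphas = np.array([o.fusion_alpha for o in a])
        assert 40 < alphas.mean() < 60  # centered near the group mean
        assert all(o.ssvep_threshold_true in reference.PHASE1_FREQUENCIES_HZ
                   for o in a)

    def test_trial_csv_round_trip(self, tmp_path, rng):
        stubs = make_experiment_design([10.0, 20.0], 4, (2, 2), rng=rng)
        for t in stubs:
            t.response = "longer"
        path = tmp_path / "trials.csv"
        trials_to_csv(stubs, path)
        df = trials_from_csv(path)
        assert len(df) == 8
        assert list(df.columns[:7]) == ["participant_id", "phase", "frequency_hz",
                                        "duration_s", "response", "staircase_id",
                                        "trial_index"]

    def test_observer_params_validation(self):
        with pytest.raises(ValueError):
            ObserverParams(lapse=0.2)
        with pytest.raises(ValueError):
            ObserverParams(fusion_beta=-1.0)
        with pytest.raises(ValueError):
            ObserverParams(duration_noise_sd=0.0)
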
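import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from v1calcium import preprocess as pp
from v1calcium.errors import (DegenerateBaselineError, DegenerateTraceError,
                              InvalidArgumentError)


def rolling_percentile_oracle(F, n_win, q):
    """Explicit per-window percentile, centered and truncated at edges."""
    n = len(F)
    out = np.empty(n)
    for t in range(n):
        a = max(0, t - n_win // 2)
        b = min(n, t + (n_win + 1) // 2)
        out[t] = np.percentile(F[a:b], q)
    return out


class TestNeuropilCorrect:
    @pytest.mark.parametrize("soma, npil, r, expected", [
        (100.0, 50.0, 0.7, 65.0),
        (80.0, 100.0, 0.8, 0.0),
        (42.0, 0.0, 0.5, 42.0),
    ])
    def test_linear_formula(self, soma, npil, r, expected):
        out = pp.neuropil_correct(np.full(5, soma), np.full(5, npil), r)
        assert np.allclose(out, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.neuropil_correct(np.zeros(5), np.zeros(4), 0.7)

    def test_indicator_factors(self):
        assert pp.neuropil_factor("GCaMP6f") == 0.7
        assert pp.neuropil_factor("jGCaMP8m") == 0.8
        with pytest.raises(InvalidArgumentError):
            pp.neuropil_factor("nonsense")


class TestBaseline:
    def test_constant_trace(self):
        F = np.full(600, 3.5)
        assert np.allclose(pp.rolling_percentile_baseline(F, 30, 5), 3.5)

    def test_matches_per_window_oracle(self):
        rng = np.random.default_rng(0)
        F = rng.normal(5, 1, 900)
        got = pp.rolling_percentile_baseline(F, 30.0, window_s=5.0)
        want = rolling_percentile_oracle(F, 150, 30)
        assert np.allclose(got, want, atol=1e-10)

    def test_transient_plateau(self):
        # transients to 10 occupy < 30% of every window -> F0 stays at 1
        F = np.ones(3000)
        F[::10] = 10.0  # 10% duty cycle
        F0 = pp.rolling_percentile_baseline(F, 30.0, window_s=10.0)
        interior = F0[200:-200]
        assert np.allclose(interior, 1.0)

    def test_ramp_baseline_below_trace(self):
        F = np.linspace(0.0, 10.0, 30 * 600)  # 10-min linear ramp
        F0 = pp.rolling_percentile_baseline(F, 30.0)
        interior = slice(30 * 80, -30 * 80)
        assert np.all(F0[interior] < F[interior])

    def test_empty_trace_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.rolling_percentile_baseline(np.array([]), 30.0)


class TestDff:
    def test_arithmetic(self):
        assert np.allclose(pp.dff(np.array([11.0, 9.0]), np.array([10.0, 10.0])),
                           [0.1, -0.1])
        F0 = np.full(7, 2.0)
        assert np.allclose(pp.dff(F0, F0), 0.0)
        assert np.allclose(pp.dff(2 * F0, F0), 1.0)

    def test_nonpositive_baseline_names_frames(self):
        F0 = np.array([1.0, -1.0, 1.0, 0.0])
        with pytest.raises(DegenerateBaselineError) as err:
            pp.dff(np.ones(4), F0)
        assert list(err.value.frames) == [1, 3]


class TestStandardize:
    def test_median_zero_sd_one(self):
        rng = np.random.default_rng(1)
        out = pp.standardize(rng.normal(3, 7, 501))
        assert abs(np.median(out)) < 1e-9
        assert abs(np.std(out, ddof=1) - 1) < 1e-9

    def test_sample_sd_convention(self):
        # median 0, sample SD (ddof=1) = 2
        assert np.allclose(pp.standardize(np.array([0.0, 0.0, 0.0, 4.0])),
                           [0, 0, 0, 2])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = pp.standardize(rng.normal(size=301))
        assert np.allclose(pp.standardize(x), x, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateTraceError):
            pp.standardize(np.ones(10))


class TestInclusion:
    def test_threshold_rule(self):
        vals = np.array([[0.0, 2.9, -5.0], [0.1, 3.0, 0.2], [1.0, 1.0, 1.0]])
        mask = pp.roi_inclusion_mask(vals, threshold=3)
        assert list(mask) == [False, True, False]  # >= is inclusive

    def test_zero_threshold_includes_all(self):
        rng = np.random.default_rng(3)
        assert pp.roi_inclusion_mask(pp.standardize(
            rng.normal(size=(4, 200))), 0).all()


def resample_oracle(trace, src_rate):
    """Brute-force: explicit interpolation + window loop + decimation."""
    n = len(trace)
    duration = (n - 1) / src_rate
    t10 = np.arange(int(np.floor(duration * 10)) + 1) / 10.0
    interp = np.interp(t10, np.arange(n) / src_rate, trace)
    sm = np.empty_like(interp)
    for i in range(len(interp)):
        a, b = max(0, i - 2), min(len(interp), i + 3)
        sm[i] = interp[a:b].mean()
    return sm[::2]


class TestResample5Hz:
    def test_constant_trace_and_length(self):
        out = pp.resample_5hz(np.full(30 * 730, 2.5), 30.0)
        assert np.allclose(out, 2.5)
        # floor(duration*5) + 1 grid points
        duration = (30 * 730 - 1) / 30
        assert out.size == int(np.floor(duration * 5)) + 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.normal(size=rng.integers(50, 2000))
            assert np.allclose(pp.resample_5hz(x, 30.0),
                               resample_oracle(x, 30.0), atol=1e-10)

    def test_sine_amplitude_matches_ma_gain(self):
        f = 0.1
        t = np.arange(30 * 200) / 30.0
        out = pp.resample_5hz(np.sin(2 * np.pi * f * t), 30.0)
        # analytic 5-point MA gain on the 10 Hz grid
        gain = np.sin(5 * np.pi * f / 10) / (5 * np.sin(np.pi * f / 10))
        interior = out[50:-50]  # whole cycles, away from edge-truncated MA
        amp = np.sqrt(2 * np.mean(interior ** 2))
        assert abs(amp - gain) < 0.01 * gain

    def test_smoothing_contracts_variance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(3000)
        assert np.var(pp.resample_5hz(x, 30.0)) < np.var(x)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.resample_5hz(np.ones(3), 30.0)


class TestPipeline:
    def test_shift_invariance_of_standardized_output(self):
        """Adding a constant to the corrected trace leaves standardized
        dF/F0 unchanged up to baseline edge effects."""
        rng = np.random.default_rng(6)
        soma = 2.0 + np.abs(rng.normal(0, 0.2, (2, 3000)))
        npil = np.ones_like(soma)
        a = pp.preprocess_traces(soma, npil, 30.0, r=0.7, window_s=10)
        b = pp.preprocess_traces(soma + 5.0, npil, 30.0, r=0.7, window_s=10)
        assert np.corrcoef(a.values[0], b.values[0])[0, 1] > 0.999

    def test_rate_recovery_low_noise(self, ):
        """With vanishing noise, trial responses rank-track the true rate."""
        from scipy.stats import spearmanr
        from v1calcium import synthetic as syn, tuning as tn

        sched = syn.StimulusSchedule.orientation(n_repeats=10, seed=11)
        speed = syn.gen_locomotion(sched.duration_s, seed=12)
        nrn = [syn.GroundTruthNeuron(id=0, visual_gain=50.0, baseline_rate=0.0,
                                     noise_sd=1e-4, neuropil_weight=0.0,
                                     tuning_concentration=2.0,
                                     pref_orientation=90.0)]
        rec = syn.gen_recording(nrn, sched, speed, seed=15)
        act = pp.preprocess_traces(rec.f_soma, rec.f_neuropil, 30.0)
        table = tn.extract_trial_responses(act, sched)
        wins = [(int(np.floor(r.stim_on_s * 30)), int(np.floor(r.stim_off_s * 30)))
                for r in sched.trials.itertuples(index=False)]
        rate = np.array([rec.event_rate[0, a:b].mean() for a, b in wins])
        assert spearmanr(table.responses[0], rate).statistic > 0.9


@settings(max_examples=30, deadline=None)
@given(hnp.arrays(np.float64, hst.integers(10, 200),
                  elements=hst.floats(-50, 50, allow_nan=False)))
def test_standardize_property(x):
    from hypothesis import assume
    sd = np.std(x, ddof=1)
    if sd == 0:
        with pytest.raises(DegenerateTraceError):
            pp.standardize(x)
    else:
        assume(sd > 1e-6)  # exclude numerically degenerate scales
        out = pp.standardize(x)
        assert abs(np.median(out)) < 1e-9
        assert abs(np.std(out, ddof=1) - 1) < 1e-9
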
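"""Tests of trace extraction, change-point step fitting (against an
exhaustive-search oracle), and binomial stoichiometry inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smassay as sm
from smassay.bleach import StepFit, StepHistogram
from smassay.errors import EdgeError, InputError, ParameterError

from oracles import exhaustive_step_fit


def make_fit(n_steps, final_level=0.0, flags=None, residual_sd=1.0):
    levels = np.linspace(100.0 * n_steps, final_level, n_steps + 1)
    return StepFit(n_steps=n_steps,
                   change_frames=np.arange(1, n_steps + 1) * 10,
                   levels=levels, residual_sd=residual_sd,
                   flags=list(flags or []))


class TestExtractTrace:
    def test_constant_spot_flat_trace(self, small_field):
        pp = sm.PhotophysicsParams(copies_n=1, p_mature=1.0, bleach_rate=1e-9,
                                   unit_intensity=500.0, background_level=0.0,
                                   read_noise_sd=0.0, shot_noise=False,
                                   n_frames=5)
        stack, truth = sm.simulate_field(small_field, pp, seed=0)
        spot = sm.Spot(x=truth.spots.x[0], y=truth.spots.y[0],
                       intensity=0, snr=0)
        tr = sm.extract_trace(stack, spot, aperture_radius_px=4.0,
                              annulus_radii_px=(6.0, 9.0))
        total = 2 * np.pi * small_field.psf_sigma_px ** 2 * 500.0
        # aperture misses some PSF tail; within a few % of the full integral
        assert np.allclose(tr.intensities, tr.intensities[0])
        assert tr.intensities[0] == pytest.approx(total, rel=0.05)

    def test_background_location_near_zero(self, rng):
        data = rng.poisson(100, (20, 64, 64)).astype(float)
        spot = sm.Spot(x=32.0, y=32.0, intensity=0, snr=0)
        tr = sm.extract_trace(data, spot)
        assert abs(tr.intensities.mean()) < 3 * tr.intensities.std()

    def test_two_step_segment_ratio(self):
        fp = sm.FieldParams(rows=64, cols=64, spot_density=1,
                            min_separation_px=0, edge_margin_px=20)
        pp = sm.PhotophysicsParams(copies_n=2, p_mature=1.0, bleach_rate=1 / 30,
                                   unit_intensity=400.0, frame_interval_s=0.25,
                                   n_frames=480)
        stack, truth = sm.simulate_field(fp, pp, seed=11)
        spot = sm.Spot(x=truth.spots.x[0], y=truth.spots.y[0],
                       intensity=0, snr=0)
        tr = sm.extract_trace(stack, spot)
        steps = truth.steps.sort_values("bleach_frame")
        f1, f2 = steps.bleach_frame.tolist()
        if f2 - f1 > 20 and f1 > 20 and f2 < 460:  # well-separated steps
            lv2 = tr.intensities[:f1 - 1].mean()
            lv1 = tr.intensities[f1 + 1:f2 - 1].mean()
            lv0 = tr.intensities[f2 + 1:].mean()
            assert lv2 / lv1 == pytest.approx(2.0, rel=0.1)
            assert abs(lv0) < 0.05 * lv2

    def test_edge_spot_rejected(self, rng):
        data = rng.poisson(50, (5, 32, 32)).astype(float)
        with pytest.raises(EdgeError):
            sm.extract_trace(data, sm.Spot(x=3.0, y=16.0, intensity=0, snr=0))


class TestFitSteps:
    def test_noiseless_staircase_exact(self):
        x = np.array([200.0] * 30 + [100.0] * 30 + [0.0] * 60)
        fit = sm.fit_steps(x)
        assert fit.n_steps == 2
        assert fit.change_frames.tolist() == [30, 60]
        np.testing.assert_allclose(fit.levels, [200.0, 100.0, 0.0])
        assert fit.accepted

    def test_flat_noise_rarely_splits(self, rng):
        flat = rng.normal(0.0, 7.0, (100, 240))
        false_rate = np.mean([sm.fit_steps(t).n_steps > 0 for t in flat])
        assert false_rate <= 0.05

    def test_dimer_step_count_recovery_at_snr5(self):
        pp = sm.PhotophysicsParams(copies_n=2, p_mature=1.0, bleach_rate=1 / 30,
                                   unit_intensity=50.0, background_level=0.0,
                                   read_noise_sd=10.0, shot_noise=False,
                                   frame_interval_s=0.1, n_frames=1200)
        ts, truth = sm.simulate_traces(pp, 200, seed=21)
        correct = 0
        for i in range(200):
            fit = sm.fit_steps(ts.intensities[i])
            correct += fit.n_steps == truth.traces.n_steps_in_movie[i]
        assert correct / 200 >= 0.90

    def test_agrees_with_exhaustive_search(self):
        pp = sm.PhotophysicsParams(copies_n=2, p_mature=1.0, bleach_rate=1 / 30,
                                   unit_intensity=100.0, background_level=0.0,
                                   read_noise_sd=10.0, shot_noise=False,
                                   frame_interval_s=0.6, n_frames=100)
        ts, _ = sm.simulate_traces(pp, 50, seed=17)
        for i in range(50):
            fit = sm.fit_steps(ts.intensities[i])
            oracle = exhaustive_step_fit(ts.intensities[i])
            assert tuple(fit.change_frames) == oracle

    def test_upward_step_flagged(self):
        x = np.array([0.0] * 40 + [100.0] * 40)
        fit = sm.fit_steps(x)
        assert "upward-step" in fit.flags
        assert not fit.accepted

    def test_short_trace_rejected(self):
        with pytest.raises(InputError):
            sm.fit_steps(np.array([1.0, 2.0, 3.0]), min_dwell_frames=2)

    def test_min_dwell_merges_short_segments(self):
        x = np.array([200.0] * 50 + [100.0] * 2 + [0.0] * 50)
        fit = sm.fit_steps(x, min_dwell_frames=4)
        assert fit.n_steps == 1


class TestHistogram:
    def test_bookkeeping(self):
        fits = [make_fit(2)] * 408 + [make_fit(1)] * 192
        hist = sm.classify_and_histogram(fits)
        assert hist.counts.tolist() == [192, 408, 0, 0]
        assert hist.n_accepted == 600
        assert hist.n_rejected == 0

    def test_all_upward_rejected(self):
        fits = [make_fit(2, flags=["upward-step"])] * 10
        hist = sm.classify_and_histogram(fits)
        assert hist.n_accepted == 0
        assert hist.reject_reasons == {"upward-step": 10}

    def test_conservation(self, clean_trace_params, rng):
        ts, _ = sm.simulate_traces(clean_trace_params, 300, seed=5)
        fits = [sm.fit_steps(t) for t in ts.intensities]
        hist = sm.classify_and_histogram(fits)
        assert hist.counts.sum() + hist.n_rejected == 300

    def test_nonzero_final_level_rejected(self):
        fits = [make_fit(1, final_level=50.0, residual_sd=1.0)]
        hist = sm.classify_and_histogram(fits)
        assert hist.n_accepted == 0
        assert hist.reject_reasons == {"nonzero-final-level": 1}

    def test_open_top_bin(self):
        fits = [make_fit(k) for k in (1, 4, 5, 7)]
        hist = sm.classify_and_histogram(fits, k_max=4)
        assert hist.counts.tolist() == [1, 0, 0, 3]


class TestBinomialModel:
    def test_dimer_80pct_maturation_thirds(self):
        pmf = sm.binomial_conditional_pmf(2, 0.8)
        np.testing.assert_allclose(pmf, [1 / 3, 2 / 3], atol=1e-12)

    def test_full_maturation_dimer(self):
        np.testing.assert_allclose(sm.binomial_conditional_pmf(2, 1.0),
                                   [0.0, 1.0], atol=1e-15)

    def test_monomer_degenerate(self):
        np.testing.assert_allclose(sm.binomial_conditional_pmf(1, 0.3), [1.0])

    def test_dark_limit_rejected(self):
        with pytest.raises(ParameterError):
            sm.binomial_conditional_pmf(2, 0.0)

    @given(n=st.integers(1, 6), p=st.floats(0.05, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_pmf_sums_to_one(self, n, p):
        assert sm.binomial_conditional_pmf(n, p).sum() == pytest.approx(
            1.0, abs=1e-12)

    @given(p=st.floats(1e-6, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_two_step_fraction_round_trip(self, p):
        f2 = sm.binomial_conditional_pmf(2, p)[1]
        assert sm.estimate_p_two_step(f2) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("f2,expected", [
        (2 / 3, 0.8), (1.0, 1.0), (0.59, 2 * 0.59 / 1.59), (0.0, 0.0)])
    def test_p_from_two_step_fraction(self, f2, expected):
        assert sm.estimate_p_two_step(f2) == pytest.approx(expected, abs=1e-9)


class TestStoichiometryFit:
    def test_exact_dimer_counts(self):
        hist = StepHistogram(np.array([200, 400, 0, 0]), 4, 600, 0)
        fit = sm.fit_stoichiometry(hist)
        assert fit.n_hat == 2
        assert fit.p_hat == pytest.approx(0.8, abs=1e-3)

    def test_all_one_step_prefers_monomer(self):
        hist = StepHistogram(np.array([300, 0, 0, 0]), 4, 300, 0)
        fit = sm.fit_stoichiometry(hist)
        assert fit.n_hat == 1

    def test_trimer_parameter_recovery(self, rng):
        pmf = sm.binomial_conditional_pmf(3, 0.7)
        hits = 0
        for seed in range(10):
            counts4 = np.zeros(4, dtype=int)
            draw = np.random.default_rng(seed).multinomial(1000, pmf)
            counts4[:3] = draw
            hist = StepHistogram(counts4, 4, 1000, 0)
            fit = sm.fit_stoichiometry(hist)
            if fit.n_hat == 3 and abs(fit.p_hat - 0.7) < 0.05:
                hits += 1
        assert hits >= 8

    def test_candidates_below_max_k_infeasible(self):
        hist = StepHistogram(np.array([50, 50, 30, 0]), 4, 130, 0)
        fit = sm.fit_stoichiometry(hist)
        assert fit.n_hat >= 3

    def test_fixed_p_mode(self):
        hist = StepHistogram(np.array([200, 400, 0, 0]), 4, 600, 0)
        fit = sm.fit_stoichiometry(hist, fixed_p=0.8)
        assert fit.n_hat == 2
        assert fit.p_hat == 0.8

    def test_too_few_traces_rejected(self):
        hist = StepHistogram(np.array([5, 5, 0, 0]), 4, 10, 0)
        with pytest.raises(InputError):
            sm.fit_stoichiometry(hist)


def test_trace_pipeline_round_trip(clean_trace_params):
    """Simulated dimer traces at 80% visibility recover (n=2, p~0.8)."""
    ts, _ = sm.simulate_traces(clean_trace_params, 700, seed=42)
    idx = np.flatnonzero(ts.detectable)[:600]
    fits = [sm.fit_steps(ts.intensities[i]) for i in idx]
    hist = sm.classify_and_histogram(fits)
    fit = sm.fit_stoichiometry(hist)
    assert fit.n_hat == 2
    assert 0.74 <= fit.p_hat <= 0.86
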
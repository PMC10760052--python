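"""Tests of digital-ELISA quantification: AEB Poisson correction, standard
curves, LOD and attomole arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smassay as sm
from smassay.errors import CurveError, InputError, SaturationError


def runs_for(aeb_target, n_beads=20_000, n=3, label="", rng=None):
    f_on = 1.0 - math.exp(-aeb_target)
    runs = []
    for r in range(n):
        on = (int(round(f_on * n_beads)) if rng is None
              else int(rng.binomial(n_beads, f_on)))
        runs.append(sm.SimoaRun(n_beads, on, replicate_id=str(r),
                                sample_label=label))
    return runs


class TestAeb:
    def test_zero_on_fraction(self):
        assert sm.compute_aeb(1000, 0) == 0.0

    def test_ten_percent_on(self):
        assert sm.compute_aeb(1000, 100) == pytest.approx(0.10536, abs=1e-5)

    def test_inversion_identity(self):
        n = 10_000
        on = int(round((1 - math.exp(-1.0)) * n))
        assert sm.compute_aeb(n, on) == pytest.approx(1.0, abs=1e-3)

    def test_saturated_array_rejected(self):
        with pytest.raises(SaturationError):
            sm.compute_aeb(100, 100)

    @given(f=st.floats(0.0, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_through_zero_class(self, f):
        n = 1_000_000
        on = int(round(f * n))
        aeb = sm.compute_aeb(n, on)
        assert 1.0 - math.exp(-aeb) == pytest.approx(on / n, abs=1e-9)


class TestStandardCurve:
    def test_exact_line_recovered(self):
        slope = 3e11
        levels = [(0.0, [0.0, 0.0, 0.0])]
        for conc in (1e-14, 3e-14, 1e-13, 3e-13):
            levels.append((conc, [slope * conc] * 3))
        curve = sm.fit_standard_curve(levels)
        assert curve.slope == pytest.approx(slope, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared > 1 - 1e-9

    def test_simulated_back_calculation_within_10pct(self):
        concs = (1e-14, 3e-14, 1e-13, 3e-13, 1e-12)
        levels = [(0.0, [sm.simulate_simoa(
            sm.SimoaSimParams(concentration_molar=0.0), seed=s)[0]
            for s in range(3)])]
        k = 10
        for conc in concs:
            reps = []
            for _ in range(3):
                run, _ = sm.simulate_simoa(
                    sm.SimoaSimParams(concentration_molar=conc), seed=k)
                k += 1
                reps.append(run)
            levels.append((conc, reps))
        curve = sm.fit_standard_curve(levels)
        for conc, reps in levels[1:]:
            back = curve.concentration_from_aeb(
                float(np.mean([r.aeb for r in reps])))
            assert back == pytest.approx(conc, rel=0.10)

    def test_blank_only_rejected(self):
        with pytest.raises(InputError):
            sm.fit_standard_curve([(0.0, [0.0, 0.0, 0.0])])

    def test_saturated_levels_excluded(self):
        levels = [(0.0, [0.0] * 3)]
        for conc in (1e-14, 3e-14, 1e-13, 3e-13):
            levels.append((conc, [3e11 * conc] * 3))
        levels.append((1e-10, runs_for(1.5, n=3)))  # f_on ~ 0.78, saturated
        curve = sm.fit_standard_curve(levels)
        assert any("saturated" in f for f in curve.flags)
        assert 1e-10 not in curve.concentrations

    def test_linearity_of_digital_range(self):
        """Mean AEB is linear in concentration while f_on < 0.7."""
        concs = np.array([1e-14, 3e-14, 1e-13, 3e-13, 1e-12, 2e-12])
        means = []
        k = 0
        for conc in concs:
            aebs = []
            for _ in range(3):
                run, _ = sm.simulate_simoa(
                    sm.SimoaSimParams(concentration_molar=float(conc)),
                    seed=900 + k)
                k += 1
                aebs.append(run.aeb)
            means.append(np.mean(aebs))
        r = np.corrcoef(concs, means)[0, 1]
        assert r ** 2 > 0.99


class TestLod:
    def test_zero_blank_sd(self):
        curve = sm.StandardCurve(np.array([1e-13]), np.array([1.0]),
                                 slope=1e13, intercept=0.1, r_squared=1.0,
                                 blank_mean=0.2, blank_sd=0.0, n_blank=3)
        assert sm.estimate_lod(curve) == pytest.approx((0.2 - 0.1) / 1e13)

    def test_lod_increases_with_blank_sd(self):
        mk = lambda sd: sm.StandardCurve(
            np.array([1e-13]), np.array([1.0]), slope=1e13, intercept=0.0,
            r_squared=1.0, blank_mean=0.05, blank_sd=sd, n_blank=10)
        assert sm.estimate_lod(mk(0.02)) > sm.estimate_lod(mk(0.01))

    def test_nonpositive_slope_rejected(self):
        curve = sm.StandardCurve(np.array([1e-13]), np.array([1.0]),
                                 slope=-1.0, intercept=0.0, r_squared=1.0,
                                 blank_mean=0.0, blank_sd=0.0, n_blank=3)
        with pytest.raises(CurveError):
            sm.estimate_lod(curve)

    def test_too_few_blanks_rejected(self):
        curve = sm.StandardCurve(np.array([1e-13]), np.array([1.0]),
                                 slope=1.0, intercept=0.0, r_squared=1.0,
                                 blank_mean=0.0, blank_sd=0.0, n_blank=2)
        with pytest.raises(InputError):
            sm.estimate_lod(curve)


class TestQuantification:
    def curve(self):
        return sm.StandardCurve(np.array([1e-12]), np.array([0.3]),
                                slope=1.0e11, intercept=0.0, r_squared=1.0,
                                blank_mean=0.001, blank_sd=0.0005, n_blank=3)

    def test_known_concentration_times_volume(self):
        # 2.75 pM in 20 uL of lysate is 55 attomoles
        assert sm.attomoles(2.75e-12, 20e-6) == pytest.approx(55.0)
        assert sm.attomoles(0.0, 20e-6) == 0.0
        # 100 pM applied in 10 uL is 1000 attomoles (1 pM -> 10 amol)
        assert sm.attomoles(100e-12, 10e-6) == pytest.approx(1000.0)

    def test_quantify_organ_back_calculation(self):
        curve = self.curve()
        aeb = 2.75e-12 * curve.slope
        n = 50_000
        run = sm.SimoaRun(n, int(round((1 - math.exp(-aeb)) * n)),
                          sample_label="cochlea")
        q = sm.quantify_organ(run, curve, lysate_volume_L=20e-6)
        assert q.attomoles_per_organ == pytest.approx(55.0, rel=0.01)
        assert not q.below_lod

    def test_below_lod_flagged(self):
        curve = self.curve()
        run = sm.SimoaRun(50_000, 30, sample_label="ko")  # ~blank level
        q = sm.quantify_organ(run, curve, lysate_volume_L=20e-6)
        assert q.below_lod

    def test_replicate_summary_arithmetic(self):
        quants = [
            sm.OrganQuantification("s", str(i), 0.1, 1e-12, 20e-6, 1.0,
                                   amol, False)
            for i, amol in enumerate((50.0, 60.0))]
        df = sm.summarize_replicates(quants)
        assert df.mean_amol[0] == pytest.approx(55.0)
        assert df.sd_amol[0] == pytest.approx(np.std([50, 60], ddof=1))

    def test_identical_replicates_zero_cv(self):
        quants = [sm.OrganQuantification("s", str(i), 0.1, 1e-12, 20e-6,
                                         1.0, 42.0, False) for i in range(3)]
        assert sm.summarize_replicates(quants).cv[0] == 0.0

    def test_single_replicate_flagged(self):
        quants = [sm.OrganQuantification("s", "0", 0.1, 1e-12, 20e-6, 1.0,
                                         42.0, False)]
        df = sm.summarize_replicates(quants)
        assert df["flags"][0] == "single-replicate"
        assert np.isnan(df.sd_amol[0])

    def test_duplicate_cv_consistent_with_counting_noise(self):
        """CV of duplicates tracks binomial bead-counting noise."""
        sp = sm.SimoaSimParams(concentration_molar=3e-13)
        curve_levels = [(0.0, [0.0] * 3)]
        for conc in (1e-13, 3e-13, 1e-12):
            curve_levels.append((conc, [sp.expected_mean_enzymes_per_bead
                                        / sp.concentration_molar * conc] * 3))
        curve = sm.fit_standard_curve(curve_levels)
        amols = []
        for seed in range(20):
            run, _ = sm.simulate_simoa(sp, seed=seed)
            run.sample_label = "dup"
            amols.append(sm.quantify_organ(run, curve, 20e-6,
                                           lod_concentration=0.0)
                         .attomoles_per_organ)
        lam = sp.expected_mean_enzymes_per_bead
        n_loaded = sp.n_beads * sp.bead_load_fraction
        f = 1 - math.exp(-lam)
        pred_cv = math.sqrt(f / (1 - f) / n_loaded) / lam
        obs_cv = np.std(amols, ddof=1) / np.mean(amols)
        assert obs_cv == pytest.approx(pred_cv, rel=0.6)


def test_runs_csv_round_trip(tmp_path):
    import pandas as pd
    from smassay.simoa import read_runs_csv
    df = pd.DataFrame({"sample_label": ["blank", "std:1e-13", "cochlea"],
                       "replicate_id": [0, 0, 0],
                       "beads_analyzed": [10000, 10000, 10000],
                       "beads_on": [5, 900, 700]})
    path = tmp_path / "runs.csv"
    df.to_csv(path, index=False)
    runs = read_runs_csv(path)
    assert len(runs) == 3
    assert runs[2].sample_label == "cochlea"


def test_malformed_runs_csv_names_row(tmp_path):
    import pandas as pd
    from smassay.simoa import read_runs_csv
    df = pd.DataFrame({"sample_label": ["a"], "replicate_id": [0],
                       "beads_analyzed": [100], "beads_on": [200]})
    path = tmp_path / "runs.csv"
    df.to_csv(path, index=False)
    with pytest.raises(InputError, match="row 0"):
        read_runs_csv(path)
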
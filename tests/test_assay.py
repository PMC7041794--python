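import numpy as np
import pytest

from idrens import assay as A


class TestConcentrationArithmetic:
    def test_study_mixing_gives_42_micromolar(self):
        c = A.molar_concentration(1.0, 21.5, 63.0, 7.0)
        assert round(c) == 42

    def test_zero_reagent_volume_undiluted(self):
        assert A.molar_concentration(1.0, 21.5, 63.0, 0.0) == pytest.approx(
            1.0 / 21.5 * 1000)

    def test_hand_arithmetic(self):
        assert A.molar_concentration(2.0, 20.0, 50.0, 50.0) == pytest.approx(50.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            A.molar_concentration(0.0, 21.5, 63.0, 7.0)
        with pytest.raises(ValueError):
            A.molar_concentration(1.0, 21.5, 63.0, -1.0)

    def test_aliquot_study_value(self):
        assert round(A.aliquot_amount(8.0, 42.0), 2) == 0.34

    def test_aliquot_zero(self):
        assert A.aliquot_amount(0.0, 123.0) == 0.0

    def test_aliquot_hand_arithmetic(self):
        assert A.aliquot_amount(10.0, 100.0) == pytest.approx(1.00)


class TestPlateStatistics:
    def test_identical_replicates_sem_zero(self):
        plate = A.LuminescencePlate({"a": [5.0, 5.0, 5.0], "b": [2.0, 2.0, 2.0]})
        s = A.summarize_plate(plate)
        assert s.loc["a", "sem"] == 0.0

    def test_hand_sem(self):
        plate = A.LuminescencePlate({"x": [1.0, 2.0, 3.0]})
        s = A.summarize_plate(plate)
        assert s.loc["x", "mean"] == pytest.approx(2.0)
        assert s.loc["x", "sem"] == pytest.approx(1.0 / np.sqrt(3))

    def test_replicate_order_irrelevant(self):
        a = A.summarize_plate(A.LuminescencePlate({"x": [3.0, 1.0, 2.0]}))
        b = A.summarize_plate(A.LuminescencePlate({"x": [1.0, 2.0, 3.0]}))
        assert a.loc["x", "mean"] == b.loc["x", "mean"]
        assert a.loc["x", "sem"] == b.loc["x", "sem"]

    def test_single_replicate_flagged(self):
        plate = A.LuminescencePlate({"x": [1.0], "y": [2.0]})
        with pytest.warns(UserWarning, match="SEM undefined"):
            s = A.summarize_plate(plate)
        assert np.isnan(s.loc["x", "sem"])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            A.LuminescencePlate({"x": [-1.0, 2.0]})

    def test_unbalanced_flagged(self):
        with pytest.warns(UserWarning, match="unbalanced"):
            A.LuminescencePlate({"x": [1.0, 2.0], "y": [1.0, 2.0, 3.0]})

    def test_csv_round_trip(self, tmp_path):
        plate = A.simulate_plate(seed=5)
        path = plate.write_csv(tmp_path / "plate.csv")
        back = A.LuminescencePlate.read_csv(path)
        for s in plate.samples:
            assert np.allclose(back.intensities[s], plate.intensities[s])


class TestAnova:
    def test_identical_groups_not_significant(self):
        plate = A.LuminescencePlate({"ctrl": [5.0, 5.0, 5.0], "x": [5.0, 5.0, 5.0]})
        res = A.anova_vs_control(plate, "ctrl")
        assert not res.loc["x", "significant"]
        assert res.loc["x", "p"] == 1.0

    def test_zero_variance_different_means_significant(self):
        plate = A.LuminescencePlate({"ctrl": [0.0, 0.0, 0.0], "x": [10.0, 10.0, 10.0]})
        res = A.anova_vs_control(plate, "ctrl")
        assert res.loc["x", "significant"]
        assert res.loc["x", "p"] == 0.0
        assert np.isinf(res.loc["x", "F"])

    def test_f_matches_brute_force_sums_of_squares(self):
        a = np.array([4.0, 6.0, 5.0])
        b = np.array([8.0, 9.0, 10.0])
        plate = A.LuminescencePlate({"ctrl": b, "x": a})
        res = A.anova_vs_control(plate, "ctrl")
        grand = np.concatenate([a, b]).mean()
        ss_between = 3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_expected = (ss_between / 1) / (ss_within / 4)
        assert res.loc["x", "F"] == pytest.approx(f_expected, rel=1e-10)

    def test_two_group_anova_equals_t_squared(self):
        from scipy import stats
        a = np.array([4.0, 6.0, 5.0])
        b = np.array([8.0, 9.0, 10.0])
        plate = A.LuminescencePlate({"ctrl": b, "x": a})
        res = A.anova_vs_control(plate, "ctrl")
        t, p = stats.ttest_ind(a, b)
        assert res.loc["x", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.loc["x", "p"] == pytest.approx(p, rel=1e-10)

    def test_missing_control_rejected(self):
        plate = A.LuminescencePlate({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="control"):
            A.anova_vs_control(plate, "ctrl")

    def test_bonferroni_tightens_alpha(self):
        rng = np.random.default_rng(0)
        plate = A.LuminescencePlate({
            "ctrl": rng.normal(10, 1, 3),
            **{f"s{k}": rng.normal(12.5, 1, 3) for k in range(10)},
        })
        plain = A.anova_vs_control(plate, "ctrl")
        corr = A.anova_vs_control(plate, "ctrl", bonferroni=True)
        assert corr["significant"].sum() <= plain["significant"].sum()

    def test_global_anova_runs(self):
        plate = A.simulate_plate(seed=1)
        f, p = A.anova_global(plate)
        assert f > 0 and p < 0.05


class TestSimulatePlate:
    def test_zero_noise_equals_profile(self):
        plate = A.simulate_plate(noise_sd=0.0, seed=9)
        for sample, mean in A.DEFAULT_EFFECT_PROFILE.items():
            assert np.allclose(plate.intensities[sample], mean)

    def test_seed_reproducibility(self):
        a = A.simulate_plate(seed=7)
        b = A.simulate_plate(seed=7)
        for s in a.samples:
            assert np.array_equal(a.intensities[s], b.intensities[s])

    def test_default_round_trip_reproduces_impaired_partition(self):
        plate = A.simulate_plate(seed=1)
        flags = A.anova_vs_control(plate, "WT")
        significant = set(flags.index[flags["significant"]])
        assert significant == {"GFP", "E44A", "E50A", "EE50AA", "R55A"}


class TestTransitionWindow:
    def _flat_trace(self, level=600.0, n=1000, t_switch=500.0):
        t = np.arange(n, dtype=float)
        return A.NPSTrace(time=t, wavelength=np.full(n, level),
                          transitions={"water_to_iron": t_switch}, scenario="test")

    def test_constant_trace_zero_dlambda(self):
        win = A.transition_window(self._flat_trace(), 500.0)
        assert len(win) == 400
        assert np.allclose(win.dlambda, 0.0)

    def test_clean_step_recovers_height(self):
        t = np.arange(1000, dtype=float)
        lam = np.where(t >= 500, 610.0, 600.0)
        trace = A.NPSTrace(time=t, wavelength=lam,
                           transitions={"s": 500.0}, scenario="step")
        win = A.transition_window(trace, 500.0)
        assert np.allclose(win.pre_switch, 0.0)
        assert np.allclose(win.post_switch, 10.0)
        assert win.plateau() == pytest.approx(10.0)

    def test_window_is_400_samples_zero_mean_baseline(self):
        trace = A.simulate_nps_trace("Mms6", seed=0)
        for t_switch in trace.transitions.values():
            win = A.transition_window(trace, t_switch)
            assert len(win) == 400
            assert win.pre_switch.mean() == pytest.approx(0.0, abs=1e-9)

    def test_rebaselining_idempotent(self):
        # subtracting the window's baseline from the whole trace first
        # changes nothing: the second baseline is ~0
        trace = A.simulate_nps_trace("Mms6MM", seed=2)
        win = A.transition_window(trace, 900.0)
        rebased = A.NPSTrace(
            time=trace.time, wavelength=trace.wavelength - win.baseline,
            transitions=trace.transitions, scenario="re")
        win2 = A.transition_window(rebased, 900.0)
        assert np.allclose(win2.dlambda, win.dlambda, atol=1e-12)

    def test_out_of_bounds_rejected(self):
        trace = self._flat_trace(n=450, t_switch=400.0)
        with pytest.raises(ValueError, match="bounds|grid"):
            A.transition_window(trace, 400.0)

    def test_nonuniform_trace_rejected(self):
        with pytest.raises(ValueError, match="1 Hz"):
            A.NPSTrace(time=np.array([0.0, 1.0, 3.0]),
                       wavelength=np.zeros(3), transitions={})

    def test_transition_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            A.NPSTrace(time=np.arange(10.0), wavelength=np.zeros(10),
                       transitions={"x": 50.0})


class TestDrift:
    def _window(self, y):
        t = np.arange(-100.0, 300.0)
        return A.TransitionWindow(time_rel=t, dlambda=y, baseline=0.0, t_switch=0.0)

    def test_constant_plateau_zero_slope(self):
        slope, decaying = A.post_switch_drift(self._window(np.full(400, 3.0)))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert not decaying

    def test_linear_ramp_recovered(self):
        t = np.arange(-100.0, 300.0)
        slope, decaying = A.post_switch_drift(self._window(-0.01 * t))
        assert slope == pytest.approx(-0.01, abs=1e-9)
        assert decaying

    def test_pure_noise_below_threshold(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, A.DEFAULT_NPS_NOISE_SD, 400)
        slope, decaying = A.post_switch_drift(self._window(y))
        assert abs(slope) < abs(A.DECAY_SLOPE_THRESHOLD)
        assert not decaying


class TestNPSGenerator:
    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            A.simulate_nps_trace("bogus")

    def test_seed_reproducibility(self):
        a = A.simulate_nps_trace("Mms6", seed=4)
        b = A.simulate_nps_trace("Mms6", seed=4)
        assert np.array_equal(a.wavelength, b.wavelength)

    def test_protein_free_no_adsorption_shift(self):
        trace = A.simulate_nps_trace("protein_free", noise_sd=0.0)
        win = A.transition_window(trace, trace.transitions["buffer_to_protein"])
        assert np.allclose(win.dlambda, 0.0, atol=1e-9)

    def test_triple_mutant_iron_decay_wildtype_stable(self):
        mm = A.simulate_nps_trace("Mms6MM", noise_sd=0.0)
        wt = A.simulate_nps_trace("Mms6", noise_sd=0.0)
        t_iron = mm.transitions["water_to_iron"]
        slope_mm, decaying_mm = A.post_switch_drift(A.transition_window(mm, t_iron))
        slope_wt, decaying_wt = A.post_switch_drift(A.transition_window(wt, t_iron))
        assert slope_mm < 0 and decaying_mm
        assert abs(slope_wt) < abs(A.DECAY_SLOPE_THRESHOLD) * 2 and not decaying_wt

    def test_water_shift_large_for_wildtype_only(self):
        wt = A.simulate_nps_trace("Mms6", noise_sd=0.0)
        mm = A.simulate_nps_trace("Mms6MM", noise_sd=0.0)
        free = A.simulate_nps_trace("protein_free", noise_sd=0.0)
        t_water = wt.transitions["iron_to_water"]
        t_iron = wt.transitions["water_to_iron"]
        wt_water = A.transition_window(wt, t_water).plateau()
        wt_iron = A.transition_window(wt, t_iron).plateau()
        mm_water = A.transition_window(mm, t_water).plateau()
        free_water = A.transition_window(free, t_water).plateau()
        assert wt_water > 5 * wt_iron          # water shift >> iron shift
        assert free_water > 5 * mm_water       # suppressed for the triple mutant
        assert wt_water > 5 * mm_water

    def test_trace_csv_round_trip(self, tmp_path):
        trace = A.simulate_nps_trace("Mms6MM", seed=3)
        path, sidecar = trace.write_csv(tmp_path / "mm.csv")
        back = A.NPSTrace.read_csv(path)
        assert np.allclose(back.wavelength, trace.wavelength)
        assert back.transitions == dict(trace.transitions)
        assert back.scenario == "Mms6MM"

    def test_window_features_table(self):
        df = A.analyze_trace(A.simulate_nps_trace("Mms6MM", seed=0))
        assert set(df.index) == set(A.TRANSITION_LABELS)
        assert bool(df.loc["water_to_iron", "decaying"])
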
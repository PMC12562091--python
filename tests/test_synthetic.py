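"""Instrument simulator: transduction, line shapes, transport, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ftranskit as fk


class TestRnpShift:
    def test_zero_at_reference_conditions(self):
        model = fk.TransductionModel()
        assert fk.rnp_shift(model.reference_RI, 0.0, model) == 0.0

    def test_bulk_term_water_to_hexane(self):
        # S = 350 nm/RIU over the 1.33 -> 1.37 step reproduces the 14 nm
        # resonance displacement between water and hexane
        model = fk.TransductionModel(bulk_sensitivity_nm_per_RIU=350.0,
                                     reference_RI=1.33)
        assert fk.rnp_shift(1.37, 0.0, model) == pytest.approx(14.0)

    def test_surface_term_is_linear_in_coverage(self):
        model = fk.TransductionModel(surface_coeff_nm_per_unit_coverage=2.0)
        assert fk.rnp_shift(model.reference_RI, 0.5, model) == pytest.approx(1.0)

    def test_guard_clips_with_warning(self):
        model = fk.TransductionModel(max_shift_nm=5.0)
        with pytest.warns(RuntimeWarning, match="clip"):
            s = fk.rnp_shift(1.40, 0.0, model)
        assert s == pytest.approx(5.0)

    def test_coverage_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fk.rnp_shift(1.33, 1.5, fk.TransductionModel())


class TestGenerateSpectrum:
    def test_dip_depth_at_center(self, resonance, grid):
        spec = fk.generate_spectrum(resonance, 0.0, grid)
        i = int(np.argmin(np.abs(grid - resonance.center_nm)))
        expected = resonance.background_level * (1.0 - resonance.depth)
        assert spec.intensities[i] == pytest.approx(expected, rel=1e-12)

    def test_half_depth_at_half_width(self, resonance, grid):
        spec = fk.generate_spectrum(resonance, 0.0, grid)
        lam = resonance.center_nm + resonance.fwhm_nm / 2.0
        i = int(np.argmin(np.abs(grid - lam)))
        expected = resonance.background_level * (1.0 - resonance.depth / 2.0)
        assert spec.intensities[i] == pytest.approx(expected, rel=1e-9)

    def test_same_seed_same_frame_is_bit_identical(self, resonance, grid):
        noise = fk.NoiseModel(multiplicative_sd=1e-4, seed=42)
        a = fk.generate_spectrum(resonance, 0.3, grid, noise, 10.0, 2)
        b = fk.generate_spectrum(resonance, 0.3, grid, noise, 10.0, 2)
        assert np.array_equal(a.intensities, b.intensities)

    def test_different_frames_differ(self, resonance, grid):
        noise = fk.NoiseModel(multiplicative_sd=1e-4, seed=42)
        a = fk.generate_spectrum(resonance, 0.3, grid, noise, 10.0, 2)
        b = fk.generate_spectrum(resonance, 0.3, grid, noise, 15.0, 3)
        assert not np.array_equal(a.intensities, b.intensities)

    def test_center_leaving_stopband_warns_but_produces(self, resonance, grid):
        with pytest.warns(RuntimeWarning, match="stop band"):
            spec = fk.generate_spectrum(resonance, 30.0, grid)
        assert np.all(np.isfinite(spec.intensities))

    def test_fano_shape_is_asymmetric(self, grid):
        model = fk.ResonanceModel(shape="fano", fano_q=2.0, sense="peak")
        spec = fk.generate_spectrum(model, 0.0, grid)
        c = model.center_nm
        left = spec.intensities[np.argmin(np.abs(grid - (c - 1.0)))]
        right = spec.intensities[np.argmin(np.abs(grid - (c + 1.0)))]
        assert left != pytest.approx(right, rel=1e-3)


class TestDeadTime:
    def test_chamber_at_50uL_per_min(self):
        assert fk.dead_time(126.0, 50.0) == pytest.approx(151.2)

    def test_one_chamber_volume_per_minute(self):
        assert fk.dead_time(126.0, 126.0) == pytest.approx(60.0)

    @pytest.mark.parametrize("vol,rate", [(0.0, 50.0), (126.0, 0.0),
                                          (-1.0, 50.0)])
    def test_non_positive_inputs_rejected(self, vol, rate):
        with pytest.raises(ValueError):
            fk.dead_time(vol, rate)


def rk4_oracle(schedule, binding, sample_times, role="analyte", dt=0.02):
    """Independent fine-step explicit (RK4) integration of dG/dt.

    Integrates piecewise between exact event times (delayed concentration
    switches, un-delayed regeneration strips) so the discontinuities are
    honoured to machine precision; kinetics themselves are solved
    numerically, never with the closed form under test.
    """
    kon, koff, gmax = (binding.kon_per_ugmL_per_s, binding.koff_per_s,
                       binding.gamma_max)
    starts = schedule.start_times_s()
    events = []       # (time, kind, value)
    for start, seg in zip(starts, schedule.segments):
        delay = fk.dead_time(schedule.chamber_volume_uL,
                             seg.flow_rate_uL_per_min)
        events.append((start + delay, "conc",
                       seg.concentration_ug_mL if seg.role == role else 0.0))
        if seg.role == "regeneration":
            events.append((start, "strip", seg.stripping_efficiency))
    events.sort(key=lambda e: (e[0], e[1] == "conc"))

    def advance(g, c, span):
        def f(gg):
            return kon * c * (gmax - gg) - koff * gg
        n = max(1, int(np.ceil(span / dt)))
        h = span / n
        for _ in range(n):
            k1 = f(g)
            k2 = f(g + h / 2 * k1)
            k3 = f(g + h / 2 * k2)
            k4 = f(g + h * k3)
            g += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        return g

    checkpoints = sorted(set([e[0] for e in events])
                         | set(float(t) for t in sample_times))
    samples = {float(t): None for t in sample_times}
    g, t, c = 0.0, 0.0, 0.0
    for ck in checkpoints:
        if ck > t:
            g = advance(g, c, ck - t)
            t = ck
        for et, kind, val in events:
            if et == ck:
                if kind == "strip":
                    g *= (1.0 - val)
                else:
                    c = val
        if ck in samples:
            samples[ck] = g
    return np.array([samples[float(t)] for t in sample_times])


class TestSimulateBinding:
    def test_equilibrium_at_KD_is_half_saturation(self):
        binding = fk.BindingModel(kon_per_ugmL_per_s=1e-3, koff_per_s=1e-3)
        schedule = fk.FlowSchedule([fk.FlowSegment(
            "analyte", binding.KD_ugmL, 50.0, 50_000.0, role="analyte")])
        _, g = fk.simulate_binding(schedule, binding, 10.0)
        assert g[-1] == pytest.approx(binding.gamma_max / 2.0, rel=0.01)

    def test_irreversible_limit_saturates(self):
        binding = fk.BindingModel(kon_per_ugmL_per_s=1e-3, koff_per_s=0.0)
        schedule = fk.FlowSchedule([fk.FlowSegment(
            "analyte", 5.0, 50.0, 10_000.0, role="analyte")])
        _, g = fk.simulate_binding(schedule, binding, 10.0)
        assert g[-1] == pytest.approx(binding.gamma_max, rel=1e-6)

    def test_closed_form_matches_rk4_oracle(self):
        binding = fk.BindingModel(kon_per_ugmL_per_s=1e-3, koff_per_s=1e-4)
        schedule = fk.FlowSchedule([fk.FlowSegment(
            "IL-8", 5.0, 50.0, 2000.0, role="analyte")])
        t, g = fk.simulate_binding(schedule, binding, 5.0)
        oracle = rk4_oracle(schedule, binding, t)
        assert np.max(np.abs(g - oracle)) < 1e-6

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_schedules_match_oracle_and_stay_bounded(self, seed):
        rng = np.random.default_rng(seed)
        binding = fk.BindingModel(
            kon_per_ugmL_per_s=float(10 ** rng.uniform(-4, -2)),
            koff_per_s=float(10 ** rng.uniform(-5, -3)),
            gamma_max=float(rng.uniform(0.3, 1.0)))
        roles = ["buffer", "analyte", "regeneration", "analyte"]
        segments = [fk.FlowSegment(
            r, float(rng.uniform(1, 20)) if r == "analyte" else 0.0,
            float(rng.uniform(20, 100)), float(rng.uniform(200, 1500)),
            role=r, stripping_efficiency=(float(rng.uniform(0, 1))
                                          if r == "regeneration" else 0.0))
            for r in roles]
        schedule = fk.FlowSchedule(segments)
        t, g = fk.simulate_binding(schedule, binding, 7.0)
        assert np.all(g >= 0.0) and np.all(g <= binding.gamma_max + 1e-12)
        oracle = rk4_oracle(schedule, binding, t)
        assert np.max(np.abs(g - oracle)) < 1e-6

    def test_regeneration_strips_configured_fraction(self):
        binding = fk.BindingModel(kon_per_ugmL_per_s=1e-3, koff_per_s=0.0)
        segments = [
            fk.FlowSegment("IL-8", 50.0, 50.0, 2000.0, role="analyte"),
            fk.FlowSegment("HCl", 0.0, 50.0, 500.0, role="regeneration",
                           stripping_efficiency=0.75),
        ]
        t, g = fk.simulate_binding(fk.FlowSchedule(segments), binding, 1.0)
        before = g[np.searchsorted(t, 2000.0) - 1]
        after = g[np.searchsorted(t, 2000.0)]
        assert after == pytest.approx(0.25 * before, rel=1e-6)

    def test_receptor_species_ignores_regeneration(self):
        binding = fk.BindingModel(kon_per_ugmL_per_s=1e-3, koff_per_s=0.0)
        segments = [
            fk.FlowSegment("ab", 50.0, 50.0, 2000.0, role="receptor"),
            fk.FlowSegment("HCl", 0.0, 50.0, 500.0, role="regeneration",
                           stripping_efficiency=1.0),
        ]
        t, g = fk.simulate_binding(fk.FlowSchedule(segments), binding, 1.0,
                                   role="receptor",
                                   stripped_by_regeneration=False)
        i = np.searchsorted(t, 2000.0)
        assert g[i] == pytest.approx(g[i - 1], rel=1e-9)


class TestSimulateExperiment:
    def test_single_buffer_segment_is_flat(self, resonance):
        schedule = fk.FlowSchedule([fk.FlowSegment("PBS", 0.0, 50.0, 600.0)])
        stack, truth = fk.simulate_experiment(
            resonance, fk.TransductionModel(), None, schedule,
            sampling_period_s=10.0)
        assert np.all(truth.shift_nm == 0.0)
        assert np.allclose(stack.intensities, stack.intensities[0])

    def test_bulk_step_after_dead_time(self, resonance):
        # 1.33 -> 1.37 with S = 350: the shift trace steps 0 -> 14 nm
        # one dead time after the switch
        schedule = fk.FlowSchedule([
            fk.FlowSegment("water", 0.0, 50.0, 400.0, medium_RI=1.33),
            fk.FlowSegment("hexane", 0.0, 50.0, 600.0, medium_RI=1.37),
        ])
        stack, truth = fk.simulate_experiment(
            resonance, fk.TransductionModel(), None, schedule,
            sampling_period_s=5.0)
        t = truth.times_s
        switch = 400.0 + fk.dead_time(126.0, 50.0)
        assert np.all(truth.shift_nm[t < switch] == 0.0)
        assert np.allclose(truth.shift_nm[t >= switch], 14.0)

    def test_association_area_trace_monotone_noise_free(self):
        scenario = fk.il8_scenario(noise_sd=0.0)
        _, truth = scenario.run()
        t = truth.times_s
        # inside the immobilization segment (post dead time, pre switch)
        mask = (t > 700.0) & (t < 3500.0)
        assert np.all(np.diff(truth.true_area_nm[mask]) >= -1e-12)

    def test_determinism_bit_identical_stacks(self):
        scenario = fk.il8_scenario(seed=7)
        s1, _ = scenario.run(seed=7)
        s2, _ = scenario.run(seed=7)
        assert np.array_equal(s1.intensities, s2.intensities)


class TestBulkSeries:
    def test_single_liquid_constant_position(self, window):
        stack, truth = fk.bulk_series([1.33], [400.0], sampling_period_s=20.0)
        pos = fk.resonance_position(stack.spectrum(len(stack) - 1),
                                    window, "dip")
        assert pos == pytest.approx(566.0, abs=0.01)
        assert np.all(truth.shift_nm == 0.0)

    def test_three_liquids_land_on_linear_model(self):
        # linear transduction: 1.33/1.36/1.37 -> 566/576.5/580 for S = 350
        stack, truth = fk.bulk_series([1.33, 1.36, 1.37],
                                      [400.0, 400.0, 400.0],
                                      sampling_period_s=20.0)
        t = truth.times_s
        search = fk.WavelengthWindow(554.0, 586.0)
        expected = {380.0: 566.0, 780.0: 576.5, 1180.0: 580.0}
        for t_end, pos_true in expected.items():
            i = int(np.searchsorted(t, t_end))
            pos = fk.resonance_position(stack.spectrum(i), search, "dip")
            assert pos == pytest.approx(pos_true, abs=0.02)

    def test_empty_ri_list_rejected(self):
        with pytest.raises(ValueError):
            fk.bulk_series([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fk.bulk_series([1.33, 1.36], [100.0])


class TestNoiseBaseline:
    def test_ftrans_baseline_p2p_order_of_magnitude(self, resonance, grid,
                                                    reference, window):
        # with multiplicative sd 5e-5 the literal p2p of baseline Ftrans
        # values inside the window stays within [5e-5, 5e-4] across seeds
        mask = (grid >= window.lo_nm) & (grid <= window.hi_nm)
        for seed in range(100):
            noise = fk.NoiseModel(multiplicative_sd=5e-5, seed=seed)
            sig = fk.generate_spectrum(resonance, 0.0, grid, noise, 0.0, 0)
            curve = fk.compute_ftrans(sig, reference)
            p2p = fk.peak_to_peak(curve.values[mask])
            assert 5e-5 <= p2p <= 5e-4

    def test_zero_noise_zero_drift_is_deterministic(self, resonance, grid):
        noise = fk.NoiseModel(multiplicative_sd=0.0, drift_per_s=0.0, seed=1)
        a = fk.generate_spectrum(resonance, 0.0, grid, noise, 5.0, 1)
        b = fk.generate_spectrum(resonance, 0.0, grid,
                                 fk.NoiseModel(0.0, 0.0, seed=99), 5.0, 7)
        assert np.array_equal(a.intensities, b.intensities)


class TestAreaShiftResponse:
    def test_monotone_up_to_one_fwhm(self, resonance):
        shifts = np.linspace(0.0, resonance.fwhm_nm, 21)
        areas = fk.area_shift_response(resonance, shifts)
        assert np.all(np.diff(areas) > 0)

    def test_inversion_round_trip(self, resonance):
        target = 0.92
        s = fk.shift_for_area_step(resonance, target)
        base, shifted = fk.area_shift_response(resonance, np.array([0.0, s]))
        assert shifted - base == pytest.approx(target, abs=1e-8)


class TestScenarioSerialization:
    def test_yaml_round_trip_preserves_simulation(self, tmp_path):
        scenario = fk.il8_scenario(seed=3)
        path = tmp_path / "scenario.yaml"
        scenario.to_yaml(path)
        loaded = fk.Scenario.from_yaml(path)
        s1, _ = scenario.run(seed=3)
        s2, _ = loaded.run(seed=3)
        assert np.array_equal(s1.intensities, s2.intensities)
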
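import numpy as np
import pytest

from rhinoflow import (
    SyntheticSpec,
    classify_cycle,
    default_thresholds,
    dominant_frequency,
    draw_effective_spec,
    generate_cycle,
    generate_effective_cycle,
    generate_ineffective_cycle,
    generate_recording,
    peak_to_peak,
)


class TestEffectiveCycles:
    def test_reference_spec_is_effective(self, thresholds):
        spec = SyntheticSpec(
            frequency_hz=0.3, pressure_amp_pa=200.0, flow_amp_cm3s=500.0, seed=1
        )
        lc = generate_effective_cycle(spec)
        assert len(lc.cycle) in (333, 334)
        assert lc.truth_label == "effective"
        assert 300.0 <= peak_to_peak(lc.cycle.pressure) <= 1000.0
        assert 100.0 <= peak_to_peak(lc.cycle.flow) <= 1650.0
        assert classify_cycle(lc.cycle, thresholds).is_effective

    def test_seeded_determinism(self):
        spec = SyntheticSpec(seed=77)
        a = generate_effective_cycle(spec)
        b = generate_effective_cycle(spec)
        np.testing.assert_array_equal(a.cycle.pressure, b.cycle.pressure)
        np.testing.assert_array_equal(a.cycle.flow, b.cycle.flow)

    def test_noise_free_periodic_fundamental(self):
        # tiling the single cycle restores a pure periodic signal whose
        # dominant frequency is the nominal rate to within one FFT bin
        spec = SyntheticSpec(frequency_hz=0.25, noise_sigma_frac=0.0, seed=0)
        cyc = generate_effective_cycle(spec).cycle
        bin_hz = 100.0 / 16384
        for channel in (cyc.pressure, cyc.flow):
            f = dominant_frequency(np.tile(channel, 10), 100.0)
            assert abs(f - 0.25) <= bin_hz + 1e-12

    def test_single_cycle_peak_stays_in_band(self):
        # the zero-padded spectrum of one period peaks below 1/T but must
        # stay inside the classifier window for the whole breathing range
        for f0 in (0.2, 0.3, 0.4, 0.5):
            spec = SyntheticSpec(frequency_hz=f0, noise_sigma_frac=0.0, seed=0)
            cyc = generate_effective_cycle(spec).cycle
            f = dominant_frequency(cyc.flow, 100.0)
            assert 0.12 <= f <= 0.6
            assert f <= f0  # single-period bias is downward

    def test_sign_convention(self):
        spec = SyntheticSpec(noise_sigma_frac=0.0, insp_fraction=0.45, seed=0)
        flow = generate_effective_cycle(spec).cycle.flow
        n_insp = int(round(0.45 * len(flow)))
        assert np.all(flow[:n_insp] > 0)
        assert np.all(flow[n_insp:] < 0)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_effective_cycle(SyntheticSpec(pressure_amp_pa=0.0))
        with pytest.raises(ValueError, match="degenerate"):
            generate_effective_cycle(SyntheticSpec(noise_sigma_frac=1.5))

    def test_scenario_mismatch(self):
        with pytest.raises(ValueError):
            generate_effective_cycle(SyntheticSpec(scenario="multiple_breaths"))
        with pytest.raises(ValueError):
            generate_ineffective_cycle(SyntheticSpec(scenario="none"))


class TestIneffectiveCycles:
    def test_weak_below_pressure_floor(self, thresholds):
        spec = SyntheticSpec(
            scenario="saturated_or_weak",
            scenario_params={"variant": "weak"},
            pressure_amp_pa=100.0,
            seed=5,
        )
        lc = generate_ineffective_cycle(spec)
        assert peak_to_peak(lc.cycle.pressure) < 300.0
        assert not classify_cycle(lc.cycle, thresholds).is_effective

    def test_saturated_clipped_above_ceiling(self, thresholds):
        spec = SyntheticSpec(scenario="saturated_or_weak",
                             scenario_params={"variant": "saturated"}, seed=5)
        lc = generate_ineffective_cycle(spec)
        vpp = peak_to_peak(lc.cycle.pressure)
        assert vpp > 1000.0
        result = classify_cycle(lc.cycle, thresholds)
        assert not result.is_effective
        assert "vpp_pressure" in result.failed_criteria

    def test_zeroed_pressure_channel(self, thresholds):
        spec = SyntheticSpec(
            scenario="not_worn_properly",
            scenario_params={"variant": "zeroed", "zeroed_channel": "pressure"},
            seed=5,
        )
        lc = generate_ineffective_cycle(spec)
        assert peak_to_peak(lc.cycle.pressure) == 0.0
        result = classify_cycle(lc.cycle, thresholds)
        assert not result.is_effective
        assert "fft_pressure" in result.failed_criteria

    def test_one_signed(self, thresholds):
        spec = SyntheticSpec(
            scenario="not_worn_properly",
            scenario_params={"variant": "one_signed"},
            pressure_amp_pa=450.0,
            seed=5,
        )
        lc = generate_ineffective_cycle(spec)
        # near-zero band-limited noise can dip just below zero; the signal
        # content is one-signed
        assert np.min(lc.cycle.flow) > -0.1 * np.max(lc.cycle.flow)
        assert not classify_cycle(lc.cycle, thresholds).is_effective

    def test_drift_shifts_spectrum_left(self, thresholds):
        spec = SyntheticSpec(
            scenario="not_worn_properly", scenario_params={"variant": "drift"}, seed=5
        )
        lc = generate_ineffective_cycle(spec)
        f = dominant_frequency(lc.cycle.pressure, 100.0)
        assert f < 0.12
        assert not classify_cycle(lc.cycle, thresholds).is_effective

    def test_multiple_breaths_high_frequency_energy(self):
        spec = SyntheticSpec(
            frequency_hz=0.3,
            scenario="multiple_breaths",
            scenario_params={"burst_freq_hz": 1.2, "burst_amp_frac": 0.8,
                             "burst_phase": "inspiratory"},
            seed=5,
        )
        lc = generate_ineffective_cycle(spec)
        assert len(lc.cycle) in (333, 334)  # base period retained
        flow = lc.cycle.flow - np.mean(lc.cycle.flow)
        freqs = np.fft.rfftfreq(16384, d=0.01)
        mag = np.abs(np.fft.rfft(flow, 16384))
        high = mag[freqs > 0.6].max()
        assert high > 0.2 * mag[1:].max()

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            generate_ineffective_cycle(
                SyntheticSpec(scenario="saturated_or_weak",
                              scenario_params={"variant": "nope"})
            )


class TestGeneratorInvariants:
    def test_effective_acceptance_rate(self, thresholds):
        rng = np.random.default_rng(2024)
        n, accepted = 1000, 0
        for _ in range(n):
            cyc = generate_effective_cycle(draw_effective_spec(rng)).cycle
            accepted += classify_cycle(cyc, thresholds).is_effective
        assert accepted / n >= 0.99

    @pytest.mark.parametrize(
        "scenario,params",
        [
            ("saturated_or_weak", {"variant": "saturated"}),
            ("saturated_or_weak", {"variant": "weak"}),
            ("not_worn_properly", {"variant": "zeroed", "zeroed_channel": "pressure"}),
            ("not_worn_properly", {"variant": "zeroed", "zeroed_channel": "flow"}),
            ("not_worn_properly", {"variant": "one_signed"}),
        ],
    )
    def test_guaranteed_rejection(self, thresholds, scenario, params):
        rng = np.random.default_rng(7)
        for _ in range(100):
            spec = draw_effective_spec(rng)
            bad = SyntheticSpec(
                frequency_hz=spec.frequency_hz,
                pressure_amp_pa=spec.pressure_amp_pa,
                flow_amp_cm3s=spec.flow_amp_cm3s,
                scenario=scenario,
                scenario_params=params,
                seed=spec.seed,
            )
            lc = generate_ineffective_cycle(bad)
            assert not classify_cycle(lc.cycle, thresholds).is_effective

    def test_pure_function_of_spec(self):
        spec = SyntheticSpec(scenario="multiple_breaths", seed=42)
        a, b = generate_cycle(spec), generate_cycle(spec)
        np.testing.assert_array_equal(a.cycle.pressure, b.cycle.pressure)
        np.testing.assert_array_equal(a.cycle.flow, b.cycle.flow)


class TestGenerateRecording:
    def test_length_bookkeeping(self):
        specs = [SyntheticSpec(frequency_hz=0.3, seed=s) for s in (1, 2, 3)]
        rec, labeled, bounds = generate_recording(specs, gap_s=0.2, seed=0)
        total = sum(len(lc.cycle) for lc in labeled) + 2 * 20
        assert len(rec) == total
        assert bounds[0][0] == 0
        assert bounds[-1][1] == total

    def test_dc_offset(self):
        specs = [SyntheticSpec(dc_offset_pa=50.0, seed=s) for s in (1, 2)]
        rec, _, _ = generate_recording(specs, gap_s=0.2, seed=0)
        # the asymmetric pressure waveform itself has a small positive mean
        assert abs(np.mean(rec.pressure) - 50.0) < 15.0

    def test_seed_determinism(self):
        specs = [SyntheticSpec(seed=s) for s in (4, 5)]
        rec1, _, _ = generate_recording(specs, gap_s=0.3, seed=11)
        rec2, _, _ = generate_recording(specs, gap_s=0.3, seed=11)
        np.testing.assert_array_equal(rec1.pressure, rec2.pressure)
        np.testing.assert_array_equal(rec1.flow, rec2.flow)

    def test_empty_specs(self):
        with pytest.raises(ValueError):
            generate_recording([], gap_s=0.1, seed=0)
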
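"""Generator contracts: reproducibility, ground-truth consistency, errors."""

import numpy as np
import pytest

from slicephys import (
    TachySpec,
    band_distance_from_sl,
    gen_diffraction_observation,
    gen_dose_response,
    gen_mea_recording,
    gen_stretch_samples,
    gen_striated_image,
    gen_transient_train,
)


class TestDiffractionObservation:
    def test_noise_free_matches_forward_projection(self):
        observed, truth = gen_diffraction_observation(2.0, noise_cm=0.0, seed=1)
        assert observed == pytest.approx(band_distance_from_sl(2.0), rel=1e-12)
        assert truth.derived_truths["sl_um"] == 2.0

    def test_sub_wavelength_sl_rejected(self):
        with pytest.raises(ValueError):
            gen_diffraction_observation(0.633)

    def test_seed_reproducibility(self):
        a, _ = gen_diffraction_observation(2.0, noise_cm=0.3, seed=42)
        b, _ = gen_diffraction_observation(2.0, noise_cm=0.3, seed=42)
        c, _ = gen_diffraction_observation(2.0, noise_cm=0.3, seed=43)
        assert a == b
        assert a != c


class TestMeaRecording:
    def test_isotropic_activation_time_is_distance_over_speed(self):
        _, truth = gen_mea_recording(50.0, 50.0, stim_channel=7)
        delays = truth.derived_truths["activation_time_s"]
        # neighbouring electrode one pitch (0.7 mm) away: 0.07 cm / 50 cm/s
        assert delays[8] == pytest.approx(1.4e-3, rel=1e-12)

    def test_anisotropy_in_ground_truth(self):
        _, truth = gen_mea_recording(60.0, 20.0)
        assert truth.derived_truths["anisotropy_ratio"] == pytest.approx(3.0)

    def test_spike_extremum_at_activation_time(self):
        rec, truth = gen_mea_recording(50.0, 25.0, noise_sd_uv=0.0, fs_hz=50_000.0)
        delays = truth.derived_truths["activation_time_s"]
        for cid in (0, 20, 40, 59):
            if cid == rec.stim_channel:
                continue
            peak_sample = np.argmax(np.abs(rec.traces[cid]))
            expected = (rec.stim_times[0] + delays[cid]) * rec.fs_hz
            assert abs(peak_sample - expected) <= 1

    def test_unknown_stim_electrode_rejected(self):
        with pytest.raises(ValueError):
            gen_mea_recording(50.0, 25.0, stim_channel=999)

    def test_transverse_faster_than_longitudinal_rejected(self):
        with pytest.raises(ValueError):
            gen_mea_recording(20.0, 60.0)

    def test_seed_reproducibility(self):
        a, _ = gen_mea_recording(50.0, 25.0, noise_sd_uv=10.0, seed=3)
        b, _ = gen_mea_recording(50.0, 25.0, noise_sd_uv=10.0, seed=3)
        np.testing.assert_array_equal(a.traces, b.traces)


class TestTransientTrain:
    def test_analytic_time_to_peak(self):
        # t* = tr*td/(td-tr) * ln(td/tr) for tr=0.02, td=0.2
        _, truth = gen_transient_train(tau_rise_s=0.02, tau_decay_s=0.2)
        assert truth.derived_truths["time_to_peak_s"] == pytest.approx(
            0.0512, abs=5e-5
        )

    def test_amplitude_linearity(self):
        t1, _ = gen_transient_train(amplitude=1.0, n_beats=3)
        t2, _ = gen_transient_train(amplitude=2.0, n_beats=3)
        np.testing.assert_allclose(t2.signal, 2.0 * t1.signal, rtol=1e-12)

    def test_aftercontraction_rate_by_construction(self):
        _, truth = gen_transient_train(
            n_beats=60,
            pacing_hz=1.0,
            aftercontractions=[(5.6, 0.2), (20.7, 0.3), (44.8, 0.25)],
            fs_hz=250.0,
        )
        assert truth.derived_truths["aftercontraction_rate_per_min"] == pytest.approx(3.0)

    def test_aftercontraction_outside_diastole_rejected(self):
        # 0.1 s after the stimulus is still within the paced beat's decay
        with pytest.raises(ValueError):
            gen_transient_train(aftercontractions=[(2.1, 0.2)])

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            gen_transient_train(tau_rise_s=0.2, tau_decay_s=0.1)

    def test_seed_reproducibility(self):
        a, _ = gen_transient_train(noise_sd=0.05, seed=11)
        b, _ = gen_transient_train(noise_sd=0.05, seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)


class TestDoseResponse:
    def test_midpoint_at_ec50(self):
        table, _ = gen_dose_response(
            ec50_m=1e-8, bottom=2.0, top=10.0, concentrations_m=[1e-9, 3e-9, 1e-8, 3e-8, 1e-7]
        )
        at_ec50 = table.loc[table["concentration_m"] == 1e-8, "response"].iloc[0]
        assert at_ec50 == pytest.approx(6.0)

    def test_response_approaches_top_at_high_dose(self):
        table, _ = gen_dose_response(
            ec50_m=1e-8, hill=1.0, bottom=0.0, top=1.0,
            concentrations_m=[1e-9, 1e-8, 1e-7, 1e-6, 1e-2],
        )
        assert table["response"].iloc[-1] == pytest.approx(1.0, abs=1e-5)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            gen_dose_response(concentrations_m=[0.0, 1e-8, 1e-7, 1e-6, 1e-5])

    def test_nonincreasing_concentrations_rejected(self):
        with pytest.raises(ValueError):
            gen_dose_response(concentrations_m=[1e-7, 1e-8, 1e-6, 1e-5, 1e-4])


class TestStriatedImage:
    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            gen_striated_image(period_um=0.19, pixel_um=0.1)

    def test_positive_fraction_by_construction(self):
        image, _, _ = gen_striated_image(positive_fraction=0.5)
        fraction = float((image > 0.5).mean())
        assert fraction == pytest.approx(0.5, abs=0.02)

    def test_seed_reproducibility(self):
        a, _, _ = gen_striated_image(phase_jitter_sd_um=0.3, seed=9)
        b, _, _ = gen_striated_image(phase_jitter_sd_um=0.3, seed=9)
        np.testing.assert_array_equal(a, b)


class TestStretchSamples:
    def test_printed_coefficients_evaluated_at_sl(self):
        table, _ = gen_stretch_samples(
            true_slope=41.67, true_intercept=-69.26, sd=0.0, sls_um=[1.8], n_per_sl=1
        )
        assert table["percent_stretch"].iloc[0] == pytest.approx(5.746, abs=1e-3)

    def test_empty_sls_rejected(self):
        with pytest.raises(ValueError):
            gen_stretch_samples(sls_um=[])

    def test_seed_reproducibility(self):
        a, _ = gen_stretch_samples(seed=2)
        b, _ = gen_stretch_samples(seed=2)
        assert a.equals(b)
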
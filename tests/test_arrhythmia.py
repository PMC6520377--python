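"""Dose-escalation analysis: aftercontractions, tachyarrhythmia, scoring, EC50."""

import numpy as np
import pytest

from slicephys import (
    TachySpec,
    arrhythmogenicity_score,
    assess_dose_escalation,
    detect_aftercontractions,
    detect_sustained_tachyarrhythmia,
    fit_dose_response,
    gen_dose_response,
    gen_transient_train,
    isoproterenol_series,
)


class TestSeries:
    def test_eight_half_log_levels(self):
        series = isoproterenol_series()
        assert len(series) == 8
        assert series[0] == 1e-9
        assert series[-1] == 3e-6
        assert all(a < b for a, b in zip(series, series[1:]))


class TestScore:
    def test_full_lookup_is_linear_and_decreasing(self):
        series = isoproterenol_series()
        scores = [arrhythmogenicity_score("pre-drug")]
        scores += [arrhythmogenicity_score(c) for c in series]
        scores.append(arrhythmogenicity_score(None))
        assert scores == list(range(9, -1, -1))

    def test_unknown_concentration_rejected(self):
        with pytest.raises(ValueError):
            arrhythmogenicity_score(5e-8)


class TestAftercontractions:
    def test_injected_events_recovered(self):
        trace, truth = gen_transient_train(
            n_beats=60,
            aftercontractions=[(5.6, 0.25), (20.7, 0.3), (44.8, 0.25)],
            fs_hz=250.0,
        )
        assert detect_aftercontractions(trace) == pytest.approx(
            truth.derived_truths["aftercontraction_rate_per_min"]
        )

    def test_clean_train_rate_zero(self):
        trace, _ = gen_transient_train(n_beats=30, fs_hz=250.0)
        assert detect_aftercontractions(trace) == 0.0

    def test_events_below_prominence_gate_ignored(self):
        trace, _ = gen_transient_train(
            n_beats=30, aftercontractions=[(5.6, 0.05), (20.7, 0.05)], fs_hz=250.0
        )
        assert detect_aftercontractions(trace, prominence_fraction=0.10) == 0.0

    def test_gain_invariance(self):
        trace, _ = gen_transient_train(
            n_beats=30, aftercontractions=[(5.6, 0.25)], noise_sd=0.01, fs_hz=250.0
        )
        r1 = detect_aftercontractions(trace)
        trace.signal = 50.0 * trace.signal
        assert detect_aftercontractions(trace) == pytest.approx(r1)


class TestTachyarrhythmia:
    def test_sustained_fast_activity_detected(self):
        trace, _ = gen_transient_train(
            n_beats=10, pacing_hz=1.0, tachy=TachySpec(onset_s=10.0, rate_hz=3.0),
            post_s=15.0, fs_hz=250.0,
        )
        assert detect_sustained_tachyarrhythmia(trace) is True

    def test_quiescent_after_stim_stop(self):
        trace, _ = gen_transient_train(n_beats=10, post_s=15.0, fs_hz=250.0)
        assert detect_sustained_tachyarrhythmia(trace) is False

    def test_short_burst_not_sustained(self):
        # fast activity for only ~5 s, then quiescence
        trace, _ = gen_transient_train(
            n_beats=10, tachy=TachySpec(onset_s=10.0, rate_hz=3.0), post_s=30.0,
            fs_hz=250.0,
        )
        stop = int(15.0 * trace.fs_hz)
        trace.signal[stop:] = trace.signal[stop]
        assert detect_sustained_tachyarrhythmia(trace) is False

    def test_insufficient_post_stimulation_recording_rejected(self):
        trace, _ = gen_transient_train(n_beats=10, post_s=2.0, fs_hz=250.0)
        with pytest.raises(ValueError):
            detect_sustained_tachyarrhythmia(trace)


class TestDoseResponseFit:
    def test_generative_identity_noise_free(self):
        table, _ = gen_dose_response(ec50_m=1e-8, hill=1.0, bottom=0.2, top=1.4)
        fit = fit_dose_response(table["concentration_m"], table["response"])
        assert fit.ec50_m == pytest.approx(1e-8, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)

    def test_noisy_recovery_median_log_error(self):
        errors = []
        for seed in range(50):
            table, _ = gen_dose_response(ec50_m=1e-8, noise_sd=0.05, seed=seed)
            fit = fit_dose_response(table["concentration_m"], table["response"])
            errors.append(abs(np.log10(fit.ec50_m) + 8.0))
        assert np.median(errors) < 0.15

    def test_flat_responses_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1e-9, 1e-8, 1e-7, 1e-6, 1e-5], [1.0] * 5)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1e-9, 1e-8, 1e-7], [0.1, 0.5, 0.9])


class TestEscalationEndToEnd:
    def _escalation(self, threshold_conc):
        """Traces per concentration; tachyarrhythmia appears at and above the
        threshold concentration, aftercontraction burden grows with dose."""
        series = isoproterenol_series()
        traces = {}
        for i, conc in enumerate(series):
            tachy = (
                TachySpec(onset_s=10.0, rate_hz=3.0)
                if threshold_conc is not None and conc >= threshold_conc
                else None
            )
            acs = [(5.6 + k, 0.3) for k in range(min(i, 3))]
            trace, _ = gen_transient_train(
                n_beats=10,
                aftercontractions=acs,
                tachy=tachy,
                post_s=15.0,
                fs_hz=250.0,
                seed=100 + i,
            )
            traces[conc] = trace
        return traces

    @pytest.mark.parametrize("threshold, expected_score", [(1e-9, 8), (1e-6, 2), (None, 0)])
    def test_threshold_and_score_recovered(self, threshold, expected_score):
        assessment = assess_dose_escalation(self._escalation(threshold))
        assert assessment.tachy_threshold_m == threshold
        assert assessment.score == expected_score

    def test_pre_drug_tachyarrhythmia_scores_nine(self):
        pre, _ = gen_transient_train(
            n_beats=10, tachy=TachySpec(onset_s=10.0, rate_hz=3.0), post_s=15.0,
            fs_hz=250.0,
        )
        assessment = assess_dose_escalation(self._escalation(3e-8), pre_drug_trace=pre)
        assert assessment.tachy_threshold_m == "pre-drug"
        assert assessment.score == 9

    def test_aftercontraction_rates_reported_per_concentration(self):
        assessment = assess_dose_escalation(self._escalation(None))
        rates = assessment.aftercontraction_rate_per_min
        assert len(rates) == 8
        assert rates[1e-9] == 0.0
        assert rates[3e-6] > 0.0
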
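import numpy as np
import pytest

from ppg2bp.preprocess import (
    PreprocessConfig,
    Segment,
    extract_bp_refs,
    lowpass,
    preprocess_pipeline,
    remove_baseline,
    segment_signal,
)

FS = 125.0


class TestRemoveBaseline:
    def test_constant_signal_becomes_zero(self):
        out = remove_baseline(np.full(1000, 3.7), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_slow_sinusoidal_drift_removed(self):
        """A 0.2 Hz drift is tracked by sub-second median windows and
        subtracted to under 10% of its amplitude."""
        t = np.arange(int(20 * FS)) / FS
        drift = np.sin(2 * np.pi * 0.2 * t)
        out = remove_baseline(drift, FS)
        interior = out[int(2 * FS):-int(2 * FS)]
        assert np.max(np.abs(interior)) < 0.10

    def test_pulse_train_preserved_under_drift(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(20 * FS)) / FS
        pulses = np.zeros_like(t)
        for tp in np.arange(0.5, 19.5, 0.8):
            pulses += np.exp(-0.5 * ((t - tp) / 0.05) ** 2)
        drift = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        corrected = remove_baseline(pulses + drift, FS)
        reference = remove_baseline(pulses, FS)
        interior = slice(int(2 * FS), -int(2 * FS))
        assert np.max(np.abs(corrected[interior] - reference[interior])) < 0.1

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="longer than signal"):
            remove_baseline(np.zeros(50), FS, window_s=1.0, window2_s=None)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        out = lowpass(np.full(2000, 5.0), FS, 5.0)
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    @pytest.mark.parametrize("freq,min_gain,max_gain", [
        (1.0, 0.99, 1.01),    # passband: amplitude preserved within 1%
        (20.0, 0.0, 0.10),    # stopband at 4x cutoff: >=90% attenuation
    ])
    def test_tone_gains(self, freq, min_gain, max_gain):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        out = lowpass(x, FS, 5.0)
        gain = np.max(np.abs(out[int(5 * FS):-int(5 * FS)]))
        assert min_gain <= gain <= max_gain

    def test_attenuation_at_twice_cutoff_exceeds_20db(self):
        t = np.arange(int(30 * FS)) / FS
        out = lowpass(np.sin(2 * np.pi * 10.0 * t), FS, 5.0)
        gain = np.max(np.abs(out[int(5 * FS):-int(5 * FS)]))
        assert 20 * np.log10(1 / gain) >= 20

    def test_zero_phase(self):
        """Forward-backward filtering leaves a passband tone undelayed."""
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        out = lowpass(x, FS, 5.0)
        mid = slice(int(5 * FS), -int(5 * FS))
        lag = np.argmax(np.correlate(out[mid], x[mid], "full")) - (len(x[mid]) - 1)
        assert lag == 0

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), FS, 62.5)


class TestSegmentation:
    @pytest.mark.parametrize("dur,window,overlap,expected", [
        (10.0, 2.0, 0.0, 5),
        (10.0, 4.0, 0.5, 4),   # starts at 0, 2, 4, 6 s
        (1.0, 2.0, 0.0, 0),    # shorter than one window: empty, not an error
    ])
    def test_segment_counts(self, dur, window, overlap, expected):
        x = np.arange(int(dur * FS), dtype=float)
        segs = segment_signal(x, FS, window, overlap)
        assert len(segs) == expected
        if expected:
            starts = [s.start_index for s in segs]
            assert starts == sorted(starts)
            assert all(len(s.x) == int(window * FS) for s in segs)

    def test_windows_are_left_aligned_half_open(self):
        x = np.arange(int(10 * FS), dtype=float)
        segs = segment_signal(x, FS, 2.0, 0.0)
        np.testing.assert_array_equal(segs[1].x, x[250:500])

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            segment_signal(np.zeros(2000), FS, 2.0, 1.0)


class TestBpRefs:
    def test_noise_free_refs_match_truth_exactly(self, clean_record):
        """On a noise-free record the window references reproduce the mean
        of the truth-table pressures for the beats inside the window."""
        rec, truth = clean_record
        segs = segment_signal(rec.channel("PPG"), rec.fs, 8.0, 0.0)
        filled = extract_bp_refs(rec.channel("ABP"), rec.fs, segs)
        assert len(filled) > 0
        for seg in filled:
            lo, hi = seg.start_index, seg.start_index + len(seg.x)
            inside = truth[(truth.peak_idx >= lo) & (truth.peak_idx < hi)]
            expected_sbp = inside.sbp.mean()
            # per-beat minima pair with the inter-peak intervals: the onset of
            # each beat after the first detected one
            expected_dbp = inside.dbp.iloc[1:].mean()
            assert seg.sbp_ref == pytest.approx(expected_sbp, abs=1e-9)
            assert seg.dbp_ref == pytest.approx(expected_dbp, abs=1e-9)

    def test_constant_abp_excludes_window(self):
        segs = [Segment(np.ones(1000), 0, FS)]
        filled = extract_bp_refs(np.full(1000, 100.0), FS, segs)
        assert filled == []

    def test_abp_not_covering_segment_rejected(self):
        segs = [Segment(np.ones(1000), 0, FS)]
        with pytest.raises(ValueError, match="does not cover"):
            extract_bp_refs(np.zeros(500), FS, segs)


class TestPipeline:
    def test_end_to_end_on_clean_record(self, clean_record):
        rec, truth = clean_record
        segs = preprocess_pipeline(rec)
        n = int(round(rec.duration / 8.0))
        assert len(segs) in (n - 1, n)
        for seg in segs:
            lo, hi = seg.start_index, seg.start_index + len(seg.x)
            inside = truth[(truth.peak_idx >= lo) & (truth.peak_idx < hi)]
            assert seg.sbp_ref == pytest.approx(inside.sbp.mean(), abs=0.5)
            assert seg.sbp_ref > seg.dbp_ref

    def test_idempotent_on_clean_signal(self, clean_record):
        """Re-running baseline removal + low-pass on an already clean
        segment changes it by under 2% of its amplitude."""
        rec, _ = clean_record
        cfg = PreprocessConfig()
        once = lowpass(
            remove_baseline(rec.channel("PPG"), rec.fs,
                            cfg.baseline_window1_s, cfg.baseline_window2_s),
            rec.fs, cfg.lowpass_cutoff_hz, cfg.lowpass_order,
        )
        twice = lowpass(
            remove_baseline(once, rec.fs, cfg.baseline_window1_s,
                            cfg.baseline_window2_s),
            rec.fs, cfg.lowpass_cutoff_hz, cfg.lowpass_order,
        )
        interior = slice(int(2 * rec.fs), -int(2 * rec.fs))
        amp = np.ptp(once[interior])
        assert np.max(np.abs(twice[interior] - once[interior])) < 0.02 * amp

    def test_inference_mode_needs_no_abp(self):
        rng = np.random.default_rng(3)
        from ppg2bp.signal_io import WaveformRecord
        rec = WaveformRecord(rng.normal(size=(1, int(20 * FS))), FS, ["PPG"])
        segs = preprocess_pipeline(rec, require_abp=False)
        assert len(segs) == 2
        assert all(s.sbp_ref is None for s in segs)
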
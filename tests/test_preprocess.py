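"""Preprocessing pipeline: lead selection, resampling, zero-phase
filtering, windowing, label mapping and stratified splitting."""

import numpy as np
import pytest

import rtafnet as rt
from rtafnet.preprocess import (
    AF, EXCLUDED, NONAF, WINDOW_SAMPLES, assign_window_label,
    map_rhythm_label, read_record_csv, segment_windows, split_dataset,
    write_record_csv,
)
from rtafnet.synthetic import ECGRecord


def multichannel_record(leads, fs=500.0, n=5000, tag="N"):
    rng = np.random.default_rng(0)
    sig = rng.normal(size=(len(leads), n))
    return ECGRecord("m0", sig, fs, list(leads),
                     [(0.0, n / fs, tag)])


class TestSelectLead:
    def test_picks_lead_ii_when_present(self):
        rec = multichannel_record(["I", "II", "V1"])
        out = rt.select_lead(rec)
        assert out.lead_names == ["II"]
        np.testing.assert_array_equal(out.signal[0], rec.signal[1])

    def test_single_channel_passthrough(self):
        rec = multichannel_record(["MLII"])
        assert rt.select_lead(rec) is rec

    def test_missing_lead_errors_naming_available(self):
        rec = multichannel_record(["I", "V1", "V2"])
        with pytest.raises(ValueError, match="V1"):
            rt.select_lead(rec)

    def test_fallback_first_channel(self, caplog):
        rec = multichannel_record(["I", "V1", "V2"])
        out = rt.select_lead(rec, fallback="first")
        assert out.lead_names == ["I"]


class TestResample:
    def test_length_arithmetic_500_to_400(self):
        y = rt.resample_to(np.zeros(30000), 500, 400)
        assert len(y) == 24000

    def test_identity_when_rates_match(self):
        x = np.random.default_rng(1).normal(size=1000)
        np.testing.assert_allclose(rt.resample_to(x, 400, 400), x)

    def test_sinusoid_against_analytic_reference(self):
        # 10 Hz tone resampled 250 -> 400 Hz vs the closed-form waveform
        t_in = np.arange(2500) / 250.0
        x = np.sin(2 * np.pi * 10 * t_in)
        y = rt.resample_to(x, 250, 400)
        t_out = np.arange(len(y)) / 400.0
        ref = np.sin(2 * np.pi * 10 * t_out)
        core = slice(200, -200)  # exclude filter edge effects
        r = np.corrcoef(y[core], ref[core])[0, 1]
        assert r > 0.999

    def test_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            rt.resample_to(np.zeros(10), 0.0)


class TestBandpass:
    def test_dc_rejected(self):
        x = np.ones(4000)
        y = rt.bandpass_filter(x, 400)
        assert np.abs(y).max() < 1e-3

    def test_passband_gain_near_unity(self):
        t = np.arange(8000) / 400.0
        x = np.sin(2 * np.pi * 10 * t)
        y = rt.bandpass_filter(x, 400)
        mid = y[2000:6000]
        assert 0.95 <= np.abs(mid).max() <= 1.05

    def test_zero_phase_no_peak_shift(self):
        # symmetric Gaussian pulse keeps its peak index
        n = 4000
        t = np.arange(n)
        x = np.exp(-0.5 * ((t - 2000) / 40.0) ** 2)
        y = rt.bandpass_filter(x, 400)
        assert int(np.argmax(y)) == 2000

    def test_rejects_nyquist_violation(self):
        with pytest.raises(ValueError):
            rt.bandpass_filter(np.zeros(100), fs=80, low=0.5, high=45)


class TestSegmentation:
    @pytest.mark.parametrize("n,expected,n_dropped", [
        (24000, 6, 0), (3999, 0, 3999), (8400, 2, 400),
    ])
    def test_window_counts(self, n, expected, n_dropped):
        segs, starts = segment_windows(np.arange(n, dtype=float))
        assert len(segs) == expected
        assert all(len(s) == WINDOW_SAMPLES for s in segs)
        if expected:
            assert starts == [10.0 * i for i in range(expected)]
            # consecutive, non-overlapping: concatenation reproduces prefix
            np.testing.assert_array_equal(
                np.concatenate(segs), np.arange(expected * WINDOW_SAMPLES)
            )

    def test_non_integer_window_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(np.zeros(100), fs=333.3, window_s=0.1)


class TestLabelMapping:
    @pytest.mark.parametrize("fine,expected", [
        ("AF", AF), ("AFL", AF), ("N", NONAF), ("J", NONAF),
        ("NSR", NONAF), ("other", EXCLUDED), ("noisy", EXCLUDED),
    ])
    def test_vocabulary(self, fine, expected):
        assert map_rhythm_label(fine) == expected

    def test_unknown_tag_errors(self):
        with pytest.raises(ValueError, match="VT"):
            map_rhythm_label("VT")

    def test_majority_overlap_rule(self):
        ivs = [(0.0, 6.0, "N"), (6.0, 20.0, "AF")]
        assert assign_window_label(0.0, 10.0, ivs) == (NONAF, "N")
        assert assign_window_label(5.0, 15.0, ivs) == (AF, "AF")

    def test_tie_breaks_toward_af(self):
        ivs = [(0.0, 5.0, "N"), (5.0, 10.0, "AF")]
        assert assign_window_label(0.0, 10.0, ivs) == (AF, "AF")

    def test_window_outside_intervals_errors(self):
        with pytest.raises(ValueError):
            assign_window_label(20.0, 30.0, [(0.0, 10.0, "N")])


class TestRecordPipeline:
    @pytest.mark.parametrize("fs", [250.0, 300.0, 500.0])
    def test_any_input_rate_yields_4000_sample_windows(self, fs):
        n = int(fs * 35)  # 35 s -> 3 windows after resampling
        rec = ECGRecord("r", np.random.default_rng(0).normal(size=(1, n)),
                        fs, ["II"], [(0.0, n / fs, "AF")])
        windows = rt.record_to_windows(rec)
        assert len(windows) == 3
        assert all(w.samples.shape == (WINDOW_SAMPLES,) for w in windows)
        assert all(w.label == AF for w in windows)

    def test_rhythm_change_produces_mixed_labels(self):
        fs, dur = 400.0, 40.0
        rec = ECGRecord("r", np.zeros((1, int(fs * dur))), fs, ["II"],
                        [(0.0, 25.0, "N"), (25.0, 40.0, "AF")])
        windows = rt.record_to_windows(rec)
        assert [w.label for w in windows] == [NONAF, NONAF, AF, AF]
        # window 20-30 s is 5 s N / 5 s AF: tie goes to AF
        assert windows[2].fine_rhythm == "AF"

    def test_excluded_rhythms_dropped(self):
        fs = 400.0
        rec = ECGRecord("r", np.zeros((1, int(fs * 20))), fs, ["II"],
                        [(0.0, 10.0, "other"), (10.0, 20.0, "AF")])
        windows = rt.record_to_windows(rec)
        assert len(windows) == 1 and windows[0].label == AF


class TestSplitting:
    def test_window_level_stratification_arithmetic(self, small_windows):
        splits = split_dataset(small_windows, level="window", seed=3)
        counts = splits.counts()
        n_af = sum(c[AF] for c in counts.values())
        for name, ratio in (("train", 0.70), ("val", 0.15), ("test", 0.15)):
            assert counts[name][AF] == pytest.approx(ratio * n_af, abs=1)

    def test_record_level_no_leakage_and_proportions(self, small_windows):
        splits = split_dataset(small_windows, level="record", seed=3)
        ids = [
            {w.record_id for w in getattr(splits, s)}
            for s in ("train", "val", "test")
        ]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        total = len(small_windows)
        fracs = [len(getattr(splits, s)) / total for s in ("train", "val", "test")]
        for frac, target in zip(fracs, (0.70, 0.15, 0.15)):
            assert abs(frac - target) <= 0.10

    def test_each_split_sees_both_classes(self, small_splits):
        for name, c in small_splits.counts().items():
            assert c[AF] > 0 and c[NONAF] > 0, name

    def test_deterministic_under_seed(self, small_windows):
        a = split_dataset(small_windows, level="record", seed=5)
        b = split_dataset(small_windows, level="record", seed=5)
        assert [w.record_id for w in a.train] == [w.record_id for w in b.train]
        assert [w.start_time for w in a.test] == [w.start_time for w in b.test]

    def test_single_class_stratification_errors(self):
        from conftest import make_window
        ws = [make_window("AF", record_id=f"r{i}") for i in range(10)]
        with pytest.raises(ValueError, match="absent"):
            split_dataset(ws, level="window", seed=0)

    def test_too_few_records_errors(self):
        from conftest import make_window
        ws = [make_window("AF", record_id="r0"), make_window("NonAF", record_id="r1")]
        with pytest.raises(ValueError):
            split_dataset(ws, level="record", seed=0)


class TestCsvRoundTrip:
    def test_record_round_trips_through_csv(self, tmp_path):
        rec = rt.generate_record(
            rt.default_rhythm_specs()["AF"],
            rt.SynthConfig(duration=5.0, seed=3),
            record_id="af_rt",
        )
        sig_path, iv_path = write_record_csv(rec, tmp_path)
        back = read_record_csv(sig_path)
        assert back.record_id == "af_rt"
        assert back.fs == rec.fs
        assert back.lead_names == rec.lead_names
        assert back.rhythm_intervals == rec.rhythm_intervals
        np.testing.assert_allclose(back.signal, rec.signal, atol=1e-6)

    def test_missing_annotation_file_errors(self, tmp_path):
        rec = rt.generate_record(
            rt.default_rhythm_specs()["NSR"],
            rt.SynthConfig(duration=2.0, seed=0), record_id="n0",
        )
        sig_path, iv_path = write_record_csv(rec, tmp_path)
        iv_path.unlink()
        with pytest.raises(FileNotFoundError, match="annotation"):
            read_record_csv(sig_path)
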
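"""Signal conditioning and 2D construction: filtering, Welch PSD,
normalization, splicing, slicing, dimension expansion."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dse_ecg import (
    DegenerateRecordError,
    EcgRecord,
    EcgPreprocessor,
    FilterSpec,
    SlicingPolicy,
    bandpass,
    expand_dims,
    minmax_normalize,
    preprocess_record,
    slice_two_dim,
    to_two_dimensional,
    welch_psd,
)
from dse_ecg.preprocess import bandpass_response

FS = 500.0


def _sine_record(freq: float, seconds: float = 20.0, fs: float = FS) -> EcgRecord:
    t = np.arange(0, seconds, 1 / fs)
    return EcgRecord("sine", np.tile(np.sin(2 * np.pi * freq * t), (12, 1)), fs=fs)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_dc_component_removed(self):
        rec = EcgRecord("dc", np.ones((12, 5000)), fs=FS)
        out = bandpass(rec)
        assert np.abs(out.signal).mean() < 0.01

    @pytest.mark.parametrize("freq", [10.0, 50.0])
    def test_attenuation_matches_designed_response(self, freq):
        """Empirical RMS ratio equals the designed |H|² at the tone frequency."""
        expected = bandpass_response(FilterSpec(), FS, [freq])[0]
        out = bandpass(_sine_record(freq))
        ratio = _rms(out.signal[0]) / _rms(_sine_record(freq).signal[0])
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_passband_tone_survives(self):
        out = bandpass(_sine_record(10.0))
        assert _rms(out.signal[0]) == pytest.approx(_rms(_sine_record(10.0).signal[0]), rel=0.10)

    def test_output_length_preserved(self, example_record):
        assert bandpass(example_record).n_samples == example_record.n_samples

    def test_high_cut_above_nyquist_rejected(self):
        rec = EcgRecord("x", np.random.default_rng(0).normal(size=(12, 100)), fs=90)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, FilterSpec(high_cut=49.0))


class TestWelch:
    def test_white_noise_psd_integrates_to_variance(self):
        x = np.random.default_rng(0).standard_normal(65536)
        f, p = welch_psd(x, fs=FS, window="hanning", nperseg=1024)
        power = np.trapezoid(p, f)
        assert power == pytest.approx(x.var(), rel=0.2)

    @pytest.mark.parametrize("window", ["blackman", "hanning", "triangular"])
    @pytest.mark.parametrize("nperseg", [256, 512, 1024])
    def test_pure_tone_peak_located_within_one_bin(self, window, nperseg):
        x = np.sin(2 * np.pi * 10.0 * np.arange(0, 40, 1 / FS))
        f, p = welch_psd(x, fs=FS, window=window, nperseg=nperseg)
        assert abs(f[np.argmax(p)] - 10.0) <= f[1] - f[0]

    def test_frequency_grid_spans_zero_to_nyquist(self):
        f, _ = welch_psd(np.random.default_rng(1).normal(size=4096), fs=FS)
        assert f[0] == 0.0 and f[-1] == FS / 2

    def test_unknown_window_lists_supported_names(self):
        with pytest.raises(ValueError, match="blackman.*hanning.*triangular"):
            welch_psd(np.zeros(1024), window="hamming")

    def test_diagnostic_plot_export(self, example_record, tmp_path):
        from dse_ecg import welch_diagnostic_plot
        out = tmp_path / "psd.png"
        welch_diagnostic_plot(example_record, out)
        assert out.stat().st_size > 10_000

    def test_filtering_attenuates_high_frequency_density(self, small_dataset):
        """After the 0.5–49 Hz bandpass, the PSD above 60 Hz drops at every bin."""
        records, _ = small_dataset
        rec = records[0]
        out = bandpass(rec)
        f, p_raw = welch_psd(rec.signal[0], fs=rec.fs, nperseg=1024)
        _, p_filt = welch_psd(out.signal[0], fs=rec.fs, nperseg=1024)
        mask = f >= 60
        assert np.all(p_filt[mask] < p_raw[mask])


class TestMinmaxNormalize:
    def test_printed_endpoints_example(self):
        """The [−20.9, 20.7] mV range maps to [−3, 3] with 0 → ≈0.0144 mV."""
        A = np.array([[-20.9, 0.0, 20.7]])
        out, params = minmax_normalize(A)
        expected_mid = -3 + 6 * 20.9 / 41.6
        np.testing.assert_allclose(out, [[-3.0, expected_mid, 3.0]])
        assert expected_mid == pytest.approx(0.0144, abs=5e-4)
        assert (params.a_min, params.a_max) == (-20.9, 20.7)

    def test_symmetric_input_midpoint_maps_to_zero(self):
        out, _ = minmax_normalize(np.array([[-1.0, 0.0, 1.0]]))
        assert out[0, 1] == 0.0

    def test_constant_record_rejected(self):
        with pytest.raises(DegenerateRecordError, match="zero amplitude range"):
            minmax_normalize(np.full((100, 12), 0.7))

    def test_endpoints_attained_exactly(self):
        A = np.random.default_rng(3).normal(size=(5000, 12)) * 7
        out, _ = minmax_normalize(A)
        assert out.min() == -3.0 and out.max() == 3.0

    def test_order_preserved(self):
        """The map is affine increasing: ordering of values is preserved."""
        A = np.random.default_rng(4).normal(size=(200, 12))
        out, _ = minmax_normalize(A)
        flat_in, flat_out = A.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)


class TestTwoDimensional:
    def test_columns_are_leads(self):
        sig = np.arange(1, 13, dtype=float)[:, None] * np.ones((12, 50))
        A = to_two_dimensional(EcgRecord("c", sig))
        for j in range(12):
            assert np.all(A[:, j] == j + 1)

    def test_transpose_relation_and_degenerate_length(self):
        sig = np.random.default_rng(0).normal(size=(12, 1))
        rec = EcgRecord("t", sig)
        A = to_two_dimensional(rec)
        assert A.shape == (1, 12)
        np.testing.assert_array_equal(A, sig.T)


class TestSlicing:
    def test_short_record_zero_padded(self):
        A = np.random.default_rng(0).normal(size=(5000, 12))
        out = slice_two_dim(A)
        assert len(out) == 1
        window, offset = out[0]
        assert window.shape == (8192, 12) and offset == 0
        np.testing.assert_array_equal(window[:5000], A)
        assert np.all(window[5000:] == 0)

    def test_medium_record_tail_truncated(self):
        A = np.random.default_rng(1).normal(size=(10000, 12))
        out = slice_two_dim(A)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0][0], A[:8192])

    def test_long_record_slice_count_and_offsets(self):
        A = np.zeros((20480, 12))
        out = slice_two_dim(A)
        assert len(out) == 4  # ⌊2·20480/8192⌋ − 1
        assert [off for _, off in out] == [0, 4096, 8192, 12288]

    def test_boundary_exactly_one_and_a_half_slices(self):
        out = slice_two_dim(np.zeros((12288, 12)))
        assert len(out) == 2  # ⌊2·12288/8192⌋ − 1

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            slice_two_dim(np.zeros((0, 12)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(L=st.integers(min_value=12288, max_value=80000))
    def test_slice_count_formula_over_random_lengths(self, L):
        out = slice_two_dim(np.zeros((L, 1)), SlicingPolicy())
        n = len(out)
        assert n == (2 * L) // 8192 - 1
        # consecutive offsets 4096 apart; adjacent slices share 4096 samples
        offsets = [off for _, off in out]
        assert offsets == [4096 * i for i in range(n)]
        assert offsets[-1] + 8192 <= L
        # joint coverage of the head of the record
        assert offsets[-1] + 8192 == 4096 * (n - 1) + 8192

    def test_slice_length_is_16_384_seconds_at_500hz(self):
        assert SlicingPolicy().slice_len / FS == pytest.approx(16.384)


class TestExpandDims:
    def test_adds_channel_axis_without_touching_values(self):
        w = np.random.default_rng(2).normal(size=(8192, 12))
        out = expand_dims(w)
        assert out.shape == (8192, 12, 1)
        np.testing.assert_array_equal(out[:, :, 0], w)

    def test_double_expansion_rejected(self):
        with pytest.raises(ValueError, match="already expanded"):
            expand_dims(np.zeros((8192, 12, 1)))


class TestPipeline:
    def test_long_record_yields_bounded_slices(self, quiet_config):
        from dse_ecg import synth_record
        rec = synth_record("Normal", quiet_config,
                           np.random.default_rng(0), duration=40.96)
        slices = preprocess_record(rec)
        assert len(slices) == 4
        for s in slices:
            assert s.values.shape == (8192, 12, 1)
            assert s.values.min() >= -3.0 and s.values.max() <= 3.0
        assert max(s.values.max() for s in slices) == 3.0
        assert min(s.values.min() for s in slices) == -3.0

    def test_short_record_single_padded_slice(self, example_record):
        slices = preprocess_record(example_record)   # 10 s -> one slice
        assert len(slices) == 1
        assert np.all(slices[0].values[5000:] == 0)

    def test_constant_record_error_propagates(self):
        rec = EcgRecord("const", np.zeros((12, 4000)))
        with pytest.raises(DegenerateRecordError):
            preprocess_record(rec)

    def test_transformer_matches_function_pipeline(self, example_record):
        got = EcgPreprocessor().fit_transform([example_record])
        want = preprocess_record(example_record)
        assert len(got) == len(want)
        np.testing.assert_array_equal(got[0].values, want[0].values)
        assert got[0].label == want[0].label
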
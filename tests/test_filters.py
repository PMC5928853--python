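"""Filter bank: enumeration, design correctness, zero-phase application."""

import numpy as np
import pytest
from scipy import signal

from ppgfilt import (
    DEFAULT_BAND,
    FAMILIES,
    ORDER_GRIDS,
    BandSpec,
    FilterSpec,
    PPGRecord,
    apply_zero_phase,
    design_filter,
    enumerate_bank,
    optimal_filter,
    windowed_sqi,
)
from ppgfilt.filters import _IIR_FAMILIES
from ppgfilt.synth import NoiseModel, generate_record

FS = 1000.0


def response_db(f, freq, doubled=True):
    """Magnitude response of a designed linear filter at one frequency, dB.
    ``doubled`` accounts for forward-backward application."""
    w = 2 * np.pi * np.atleast_1d(freq) / f.fs
    if f.kind == "linear_iir":
        _, h = signal.sosfreqz(f.sos, worN=w)
    else:
        _, h = signal.freqz(f.taps, worN=w)
    db = 20 * np.log10(np.maximum(np.abs(h), 1e-300))
    return (2 * db if doubled else db)[0]


class TestEnumeration:
    def test_bank_is_ninety(self):
        assert len(enumerate_bank()) == 90

    def test_nine_families_ten_orders_each(self):
        bank = enumerate_bank()
        fams = {s.family for s in bank}
        assert fams == set(FAMILIES) and len(fams) == 9
        for fam in FAMILIES:
            orders = [s.order_param for s in bank if s.family == fam]
            assert len(orders) == 10
            assert orders == sorted(orders)
            assert orders == list(ORDER_GRIDS[fam])

    def test_deterministic_and_duplicate_free(self):
        a, b = enumerate_bank(), enumerate_bank()
        assert a == b
        assert len({(s.family, s.order_param) for s in a}) == 90


class TestDesign:
    @pytest.mark.parametrize("family", _IIR_FAMILIES)
    @pytest.mark.parametrize("order", ORDER_GRIDS["butterworth"])
    def test_full_iir_grid_stable_in_sos_form(self, family, order):
        f = design_filter(FilterSpec(family, order), FS, DEFAULT_BAND)
        assert f.kind == "linear_iir"
        for section in f.sos:
            assert np.all(np.abs(np.roots(section[3:])) < 1.0)

    def test_cheby2_passband_flat_and_stopband_deep(self):
        f = design_filter(FilterSpec("cheby2", 4), FS, DEFAULT_BAND)
        center = np.sqrt(0.5 * 8.0)  # geometric band center
        assert abs(response_db(f, center, doubled=False)) < 0.1
        for edge in (0.5, 8.0):
            assert response_db(f, edge, doubled=False) <= -19.9

    def test_moving_average_window_odd_forcing(self):
        f = design_filter(FilterSpec("moving_average", 0.05), FS)
        assert f.coefficients["window"] == 51  # 50 forced odd

    @pytest.mark.parametrize("len_s,expected", [(0.1, 101), (0.25, 251), (0.5, 501)])
    def test_window_sample_conversion(self, len_s, expected):
        f = design_filter(FilterSpec("median", len_s), FS)
        assert f.coefficients["window"] == expected

    def test_fir_hamming_symmetric_taps(self):
        f = design_filter(FilterSpec("fir_hamming", 0.05), FS, DEFAULT_BAND)
        taps = f.taps
        assert taps.size == 51
        np.testing.assert_allclose(taps, taps[::-1], rtol=0, atol=1e-15)
        assert abs(response_db(f, np.sqrt(0.5 * 8.0), doubled=False)) < 1.0

    def test_fir_ls_stopband_edges_follow_band(self):
        f = design_filter(FilterSpec("fir_ls", 0.5), FS, DEFAULT_BAND)
        # 0.3 Hz (below f_low - 0.2) and 10 Hz (f_high + 2) lie in stopbands
        assert f.taps.size == 501
        assert response_db(f, 10.0, doubled=False) < -10.0

    def test_fir_ls_low_edge_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            design_filter(FilterSpec("fir_ls", 0.2), FS, BandSpec(0.15, 8.0))
        assert any("clamp" in m for m in caplog.messages)

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError):
            design_filter(FilterSpec("butterworth", 4), FS, BandSpec(0.5, 600.0))
        with pytest.raises(ValueError):
            BandSpec(8.0, 0.5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("brickwall", 4)

    def test_design_constants_defaults(self):
        assert FilterSpec("cheby1", 4).ripple_db == 0.1
        assert FilterSpec("cheby2", 4).atten_db == 20.0
        e = FilterSpec("elliptic", 4)
        assert (e.ripple_db, e.atten_db) == (0.1, 30.0)


class TestApplication:
    @pytest.mark.parametrize(
        "family,order,leak_bound",
        [
            # butter/cheby1 bandpasses place true zeros at DC
            ("butterworth", 4, 1e-6),
            ("cheby1", 4, 1e-6),
            # equiripple stopbands leak DC at the stopband floor
            # (20 dB / 30 dB single-pass, doubled by filtfilt)
            ("cheby2", 4, 1.1e-2),
            ("elliptic", 4, 1.1e-3),
        ],
    )
    def test_bandpass_rejects_dc_per_design(self, family, order, leak_bound):
        rec = PPGRecord(samples=np.full(2100, 2048.0), fs=FS)
        f = design_filter(FilterSpec(family, order), FS, DEFAULT_BAND)
        out = apply_zero_phase(f, rec)
        assert np.max(np.abs(out.samples)) <= leak_bound * 2048.0

    @pytest.mark.parametrize("family,len_s", [("fir_hamming", 0.5), ("fir_ls", 0.5)])
    def test_fir_upper_stopband_rejects_20hz(self, family, len_s):
        t = np.arange(2100) / FS
        tone = np.sin(2 * np.pi * 20.0 * t)
        f = design_filter(FilterSpec(family, len_s), FS, DEFAULT_BAND)
        out = apply_zero_phase(f, PPGRecord(samples=tone, fs=FS)).samples
        mid = slice(600, 1500)
        atten = 20 * np.log10(np.std(tone[mid]) / max(np.std(out[mid]), 1e-300))
        assert atten >= 20.0

    def test_moving_average_preserves_constant(self):
        rec = PPGRecord(samples=np.full(500, 7.0), fs=FS)
        f = design_filter(FilterSpec("moving_average", 0.05), FS)
        np.testing.assert_allclose(apply_zero_phase(f, rec).samples, rec.samples)

    @pytest.mark.parametrize("family,order", [("fir_hamming", 0.2), ("fir_ls", 0.15)])
    def test_time_reversal_symmetry_linear_phase(self, family, order, rng):
        # exact for symmetric-tap FIR; IIR filtfilt is only approximately
        # reversal-symmetric on short records (edge transients), so its
        # zero-phase property is asserted via group delay instead
        x = rng.normal(size=2100)
        f = design_filter(FilterSpec(family, order), FS, DEFAULT_BAND)
        fwd = apply_zero_phase(f, PPGRecord(samples=x, fs=FS)).samples
        rev = apply_zero_phase(f, PPGRecord(samples=x[::-1], fs=FS)).samples
        np.testing.assert_allclose(rev[::-1], fwd, rtol=1e-8, atol=1e-8 * np.abs(fwd).max())

    def test_zero_group_delay_on_narrowband_pulse(self):
        t = np.arange(2100) / FS
        pulse = np.exp(-0.5 * ((t - 1.05) / 0.12) ** 2) * np.sin(2 * np.pi * 3.0 * t)
        rec = PPGRecord(samples=pulse, fs=FS)
        for family, order in [("butterworth", 4), ("cheby2", 4), ("fir_hamming", 0.3)]:
            f = design_filter(FilterSpec(family, order), FS, DEFAULT_BAND)
            out = apply_zero_phase(f, rec).samples
            xc = np.correlate(out - out.mean(), pulse - pulse.mean(), mode="full")
            assert np.argmax(xc) - (2100 - 1) == 0

    @pytest.mark.parametrize("family", ["cheby2", "elliptic"])
    @pytest.mark.parametrize("order", [4, 8, 12, 20])
    def test_fifty_hz_in_designed_stopband(self, family, order):
        f = design_filter(FilterSpec(family, order), FS, DEFAULT_BAND)
        assert response_db(f, 50.0, doubled=False) <= -(f.spec.atten_db - 0.5)

    def test_fifty_hz_tone_attenuated_in_time_domain(self):
        # order 4 only: higher-order IIR edge transients outlast a 2.1 s
        # record and would dominate the residual measurement
        t = np.arange(2100) / FS
        tone = np.sin(2 * np.pi * 50.0 * t)
        f = design_filter(FilterSpec("cheby2", 4), FS, DEFAULT_BAND)
        out = apply_zero_phase(f, PPGRecord(samples=tone, fs=FS)).samples
        mid = slice(300, 1800)
        atten = 20 * np.log10(np.std(tone[mid]) / max(np.std(out[mid]), 1e-300))
        assert atten >= f.spec.atten_db

    def test_moving_average_matches_convolution_oracle(self, rng):
        x = rng.normal(size=40)
        n = 7
        f = design_filter(FilterSpec("moving_average", n / FS), FS)
        assert f.coefficients["window"] == n
        out = apply_zero_phase(f, PPGRecord(samples=x, fs=FS)).samples
        for i in range(x.size):
            h = min(i, n // 2, x.size - 1 - i)
            assert out[i] == pytest.approx(np.mean(x[i - h : i + h + 1]), rel=1e-12)

    def test_median_matches_sliding_sort_oracle(self, rng):
        x = rng.normal(size=35)
        n = 5
        f = design_filter(FilterSpec("median", n / FS), FS)
        out = apply_zero_phase(f, PPGRecord(samples=x, fs=FS)).samples
        for i in range(x.size):
            h = min(i, n // 2, x.size - 1 - i)
            window = sorted(x[i - h : i + h + 1])
            assert out[i] == pytest.approx(window[len(window) // 2], rel=1e-12)

    @pytest.mark.parametrize("level", [1, 4, 10])
    def test_wavelet_output_shape_and_finiteness(self, level, rng):
        x = rng.normal(size=2100) + np.sin(np.arange(2100) * 0.02)
        f = design_filter(FilterSpec("wavelet", level), FS)
        out = apply_zero_phase(f, PPGRecord(samples=x, fs=FS)).samples
        assert out.size == 2100 and np.all(np.isfinite(out))

    def test_wavelet_reduces_white_noise_around_tone(self, rng):
        t = np.arange(2100) / FS
        clean = np.sin(2 * np.pi * 1.5 * t)
        noisy = clean + 0.3 * rng.normal(size=t.size)
        f = design_filter(FilterSpec("wavelet", 4), FS)
        out = apply_zero_phase(f, PPGRecord(samples=noisy, fs=FS)).samples
        assert np.std(out - clean) < np.std(noisy - clean)

    def test_metadata_preserved_and_fs_checked(self, tiny_labeled_records):
        rec = tiny_labeled_records[0]
        f = design_filter(FilterSpec("cheby2", 4), FS, DEFAULT_BAND)
        out = apply_zero_phase(f, rec)
        assert (out.subject_id, out.segment_id, out.label) == (
            rec.subject_id, rec.segment_id, rec.label)
        assert out.n_samples == rec.n_samples
        with pytest.raises(ValueError):
            apply_zero_phase(f, PPGRecord(samples=np.arange(100.0) + 1, fs=500.0))


class TestOptimalFilter:
    def test_is_design_order_four_cheby2(self):
        f = optimal_filter(FS, DEFAULT_BAND)
        assert (f.spec.family, f.spec.order_param) == ("cheby2", 4)
        explicit = design_filter(FilterSpec("cheby2", 4), FS, DEFAULT_BAND)
        np.testing.assert_array_equal(f.sos, explicit.sos)

    def test_changes_clean_records_less_than_unfit_ones(self):
        f = optimal_filter(FS, DEFAULT_BAND)
        deltas = {}
        for grade in ("G1", "G3"):
            ds = []
            for seed in range(1, 11):
                rec = generate_record(grade, seed=seed)
                before = windowed_sqi(rec).record_sqi
                after = windowed_sqi(apply_zero_phase(f, rec)).record_sqi
                ds.append(abs(after - before))
            deltas[grade] = np.mean(ds)
        assert deltas["G1"] < deltas["G3"]
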
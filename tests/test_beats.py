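"""Beat extraction: decay isolation, FFT spectra, FFT(eKE), FFT(dt), revivals."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from beatmap import (
    C_CM_PS,
    BaselineSpec,
    TRPESMap,
    Transient,
    Wavepacket,
    band_magnitude,
    detect_revival,
    fft_spectrum,
    fft_vs_eke,
    fft_vs_time,
    find_beat_peaks,
    isolate_beats,
    smooth_with_irf,
    survival_probability,
)


def tone(t, nu_cm1, amp=1.0, phase=0.0):
    return amp * np.cos(2.0 * np.pi * C_CM_PS * nu_cm1 * t + phase)


class TestIsolateBeats:
    def test_ratio_mode_recovers_fractional_modulation(self):
        """exp(-t/5) * (1 + 0.2 cos) isolates to 0.2 cos within 1%."""
        t = np.arange(0.0, 10.0, 1e-2)
        y = np.exp(-t / 5.0) * (1.0 + 0.2 * tone(t, 180.0))
        iso = isolate_beats(Transient(t, y), "exponential")
        target = 0.2 * tone(t, 180.0)
        sel = t >= 0.2
        assert np.max(np.abs(iso.y[sel] - target[sel])) < 0.01 * 0.2 * 5

    def test_pure_decay_isolates_to_zero(self):
        t = np.arange(0.0, 10.0, 1e-2)
        y = np.exp(-t / 5.0)
        iso = isolate_beats(Transient(t, y), "exponential")
        assert np.max(np.abs(iso.y)) < 1e-6

    def test_constant_input_subtract_mode_all_zeros(self):
        t = np.arange(0.0, 5.0, 1e-2)
        iso = isolate_beats(
            Transient(t, np.full_like(t, 3.0)), "constant", mode="subtract"
        )
        assert iso.y == pytest.approx(np.zeros_like(t), abs=1e-14)

    def test_zero_crossing_baseline_rejected_in_ratio_mode(self):
        t = np.arange(0.0, 5.0, 1e-2)
        y = np.where(t < 2.5, 1.0, -1.0)  # mean-zero-ish constant baseline
        with pytest.raises(ValueError, match="zero"):
            isolate_beats(Transient(t, y), "constant", mode="ratio")

    def test_auto_picks_biexponential_when_needed(self):
        t = np.arange(0.0, 10.0, 1e-2)
        y = 0.7 * np.exp(-t / 0.8) + 0.3 * np.exp(-t / 6.0)
        iso = isolate_beats(Transient(t, y), "auto")
        assert iso.meta["baseline"] == "biexponential"
        assert np.max(np.abs(iso.y)) < 1e-5


class TestFFTSpectrum:
    def test_pure_tone_peak_within_half_resolution(self):
        t = np.arange(0.0, 5.0, 1e-2)
        spec = fft_spectrum(Transient(t, tone(t, 180.0)))
        peaks = find_beat_peaks(spec)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 180.0) < spec.resolution_cm1 / 2.0
        # unit-amplitude cosine -> unit peak under the documented scaling
        assert peaks[0][1] == pytest.approx(1.0, rel=0.05)

    def test_resolution_is_inverse_record_length(self):
        t = np.arange(0.0, 5.0, 1e-2)
        spec = fft_spectrum(Transient(t, tone(t, 180.0)))
        assert spec.resolution_cm1 == pytest.approx(1.0 / (C_CM_PS * t[-1]), rel=1e-6)

    def test_constant_transient_has_no_peaks(self):
        t = np.arange(0.0, 5.0, 1e-2)
        spec = fft_spectrum(Transient(t, np.full_like(t, 2.0)))
        assert find_beat_peaks(spec) == []

    def test_negative_delays_excluded(self):
        t = np.arange(-1.0, 5.0, 1e-2)
        y = np.where(t >= 0.0, tone(t, 180.0), 50.0)  # garbage before zero
        spec = fft_spectrum(Transient(t, y))
        peaks = find_beat_peaks(spec)
        assert abs(peaks[0][0] - 180.0) < spec.resolution_cm1

    def test_too_short_record_rejected(self):
        t = np.arange(0.0, 0.05, 1e-2)
        with pytest.raises(ValueError):
            fft_spectrum(Transient(t, np.zeros_like(t)))

    def test_two_tones_resolved_on_7p5ps_record(self):
        """115 and 180 cm^-1 are 65 cm^-1 apart >> 4.4 cm^-1 resolution."""
        t = np.arange(0.0, 7.5, 1e-2)
        spec = fft_spectrum(Transient(t, tone(t, 115.0) + tone(t, 180.0)))
        freqs = sorted(f for f, _ in find_beat_peaks(spec))
        assert len(freqs) == 2
        assert freqs[0] == pytest.approx(115.0, abs=spec.resolution_cm1 / 2)
        assert freqs[1] == pytest.approx(180.0, abs=spec.resolution_cm1 / 2)

    @given(nu=st.floats(20.0, 600.0))
    def test_refined_peak_frequency_property(self, nu):
        """Any pure tone in 20-600 cm^-1 is located within half a
        resolution element after parabolic refinement."""
        t = np.arange(0.0, 5.0, 5e-3)
        spec = fft_spectrum(Transient(t, tone(t, nu)))
        peaks = find_beat_peaks(spec, prominence_frac=0.5)
        assert peaks
        assert abs(peaks[0][0] - nu) < spec.resolution_cm1 / 2.0


class TestPairwiseGapOracle:
    """FFT peaks of a survival probability = pairwise level gaps, with
    magnitude 2 a_n^2 a_m^2 per gap (brute-force pair enumeration)."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_peaks_match_enumerated_gaps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        t = np.arange(0.0, 12.5, 5e-3)
        res = 1.0 / (C_CM_PS * t[-1])
        for _ in range(100):
            e = np.sort(rng.uniform(0.0, 500.0, n))
            gaps = np.abs(e[:, None] - e[None, :])[np.triu_indices(n, 1)]
            d = np.abs(gaps[:, None] - gaps[None, :])[np.triu_indices(len(gaps), 1)]
            # the Hann mainlobe spans ~4 resolution elements, so gaps
            # closer than that merge into a single peak
            if (np.all(np.diff(e) > 2 * res) or n == 2) and (
                d.size == 0 or np.min(d) > 4 * res
            ):
                break
        else:
            pytest.skip("no well-separated level set found")
        # amplitudes within 0.7-1.0 keep every real peak >= 24% of the
        # strongest, well clear of the ~3% Hann sidelobes
        amps = rng.uniform(0.7, 1.0, n)
        wp = Wavepacket.from_levels(e, amps)
        spec = fft_spectrum(survival_probability(wp, t))
        peaks = find_beat_peaks(spec, prominence_frac=0.1)
        found = sorted(f for f, _ in peaks)
        expected = sorted(gaps)
        assert len(found) == len(expected)
        assert found == pytest.approx(expected, abs=res)
        # oracle magnitudes: 2 a_n^2 a_m^2 per pair
        pops = wp.populations
        mag = {}
        for i in range(n):
            for j in range(i + 1, n):
                mag[round(e[j] - e[i], 3)] = 2.0 * pops[i] * pops[j]
        for f, m in peaks:
            key = min(mag, key=lambda g: abs(g - f))
            assert m == pytest.approx(mag[key], rel=0.1)

    def test_irf_attenuates_fast_beats_as_predicted(self, three_level_spectrum):
        """After a 0.1 ps IRF the 358 peak drops relative to 179 by the
        Gaussian transfer-function ratio."""
        from beatmap import PumpPulse, build_wavepacket

        wp = build_wavepacket(three_level_spectrum, PumpPulse(100.0, 1e9))
        t = np.arange(0.0, 7.5, 5e-3)
        raw = survival_probability(wp, t)
        sm = smooth_with_irf(raw, 0.1)
        spec = fft_spectrum(sm)
        peaks = dict_by_freq(find_beat_peaks(spec, prominence_frac=0.001))
        pops = wp.populations
        atten = lambda nu: math.exp(  # noqa: E731
            -((math.pi * C_CM_PS * nu) ** 2) * 0.01 / (4 * math.log(2))
        )
        expected_ratio = (2 * pops[0] * pops[2] * atten(358.0)) / (
            (2 * pops[0] * pops[1] + 2 * pops[1] * pops[2]) * atten(179.0)
        )
        measured = peaks[358.0][1] / peaks[179.0][1]
        assert measured == pytest.approx(expected_ratio, rel=0.05)


def dict_by_freq(peaks, targets=(179.0, 358.0), tol=5.0):
    out = {}
    for f, m in peaks:
        for tgt in targets:
            if abs(f - tgt) < tol:
                out[tgt] = (f, m)
    return out


class TestFFTvsEKE:
    @staticmethod
    def _separable_map():
        t = np.arange(0.0, 5.0, 1e-2)
        eke = np.arange(0.0, 2000.0, 100.0)
        base = np.exp(-t / 8.0)
        z = np.empty((t.size, eke.size))
        for i, e in enumerate(eke):
            beat = 0.3 * tone(t, 180.0) if e < 1000.0 else 0.0
            z[:, i] = base * (1.0 + beat) * (0.5 + 1e-4 * e)
        return TRPESMap(t, eke, z)

    def test_equals_columnwise_fft_exactly(self):
        m = self._separable_map()
        fe = fft_vs_eke(
            m, None, eke_bin_cm1=None, intensity_floor_frac=0.0
        )
        for i in range(m.eke_cm1.size):
            col = fft_spectrum(Transient(m.t_ps, m.intensity[:, i]))
            assert np.array_equal(fe.magnitude[i], col.magnitude)
        assert np.all(fe.mask)

    def test_beat_localized_in_eke(self):
        m = self._separable_map()
        fe = fft_vs_eke(m, "exponential", eke_bin_cm1=None, intensity_floor_frac=0.0)
        i180 = np.argmin(np.abs(fe.freq_cm1 - 180.0))
        has_beat = fe.magnitude[:, i180] > 0.1
        assert np.array_equal(has_beat, m.eke_cm1 < 1000.0)

    def test_beat_free_map_is_flat(self):
        t = np.arange(0.0, 5.0, 1e-2)
        eke = np.arange(0.0, 1000.0, 100.0)
        z = np.outer(np.exp(-t / 8.0), np.linspace(1.0, 2.0, eke.size))
        fe = fft_vs_eke(TRPESMap(t, eke, z), "exponential", eke_bin_cm1=None)
        sel = fe.freq_cm1 > 3 * fe.resolution_cm1
        assert np.max(fe.magnitude[:, sel]) < 1e-5

    def test_weak_columns_masked_not_zero_filled(self):
        t = np.arange(0.0, 5.0, 1e-2)
        eke = np.array([100.0, 200.0, 300.0])
        z = np.column_stack(
            [np.exp(-t / 8.0), 1e-4 * np.exp(-t / 8.0), np.exp(-t / 4.0)]
        )
        fe = fft_vs_eke(
            TRPESMap(t, eke, z), "exponential", eke_bin_cm1=None,
            intensity_floor_frac=0.01,
        )
        assert list(fe.mask) == [True, False, True]
        assert np.all(fe.magnitude[1] == 0.0)

    def test_empty_map_rejected(self):
        t = np.arange(0.0, 5.0, 1e-2)
        with pytest.raises(ValueError):
            fft_vs_eke(
                TRPESMap(t, np.array([100.0]), np.zeros((t.size, 1))),
                None,
                intensity_floor_frac=2.0,
            )


class TestSpectrogram:
    def test_stationary_tone_band_is_flat(self):
        t = np.arange(0.0, 10.0, 1e-2)
        sg = fft_vs_time(Transient(t, tone(t, 180.0)), 2.5, 0.25)
        band = band_magnitude(sg, 180.0, 15.0)
        interior = (sg.window_center_ps > 2.5) & (sg.window_center_ps < 7.5)
        assert np.ptp(band[interior]) / np.mean(band[interior]) < 0.02

    def test_damped_tone_band_decay_recovers_lifetime(self):
        """Band magnitude of a tau=1.4 ps damped tone decays with a
        lifetime recovered within 15% by a log-linear fit."""
        t = np.arange(0.0, 12.5, 1e-2)
        tau = 1.4
        sg = fft_vs_time(
            Transient(t, np.exp(-t / tau) * tone(t, 180.0)), 2.5, 0.25
        )
        b = band_magnitude(sg, 180.0, 15.0)
        sel = (sg.window_center_ps > 1.0) & (sg.window_center_ps < 5.0) & (b > 1e-8)
        slope = np.polyfit(sg.window_center_ps[sel], np.log(b[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.15)

    def test_dephasing_doublet_revives_at_inverse_splitting(self):
        """55 + 63 cm^-1 doublet rephases with period 1/(c * 8) = 4.17 ps."""
        t = np.arange(0.0, 12.5, 1e-2)
        y = tone(t, 55.0) + tone(t, 63.0)
        sg = fft_vs_time(Transient(t, y), 2.5, 0.1)
        revivals = detect_revival(sg, 59.0, 12.0)
        t_rephase = 1.0 / (C_CM_PS * 8.0)
        assert revivals
        assert min(abs(r - t_rephase) for r in revivals) <= 0.2

    def test_undamped_tone_has_no_revivals(self):
        t = np.arange(0.0, 10.0, 1e-2)
        sg = fft_vs_time(Transient(t, tone(t, 180.0)), 2.5, 0.25)
        assert detect_revival(sg, 180.0, 15.0) == []

    def test_monotonically_damped_tone_has_no_revivals(self):
        t = np.arange(0.0, 10.0, 1e-2)
        sg = fft_vs_time(
            Transient(t, np.exp(-t / 1.5) * tone(t, 180.0)), 2.5, 0.25
        )
        assert detect_revival(sg, 180.0, 15.0) == []

    def test_per_window_max_normalization(self):
        t = np.arange(0.0, 10.0, 1e-2)
        sg = fft_vs_time(
            Transient(t, np.exp(-t / 1.5) * tone(t, 180.0)),
            2.5,
            0.5,
            normalization="per-window-max",
        )
        assert np.max(sg.magnitude, axis=1) == pytest.approx(
            np.ones(sg.window_center_ps.size)
        )

    def test_window_longer_than_record_rejected(self):
        t = np.arange(0.0, 2.0, 1e-2)
        with pytest.raises(ValueError, match="exceeds"):
            fft_vs_time(Transient(t, tone(t, 100.0)), 5.0, 0.5)

    def test_band_outside_range_rejected(self):
        t = np.arange(0.0, 10.0, 1e-2)
        sg = fft_vs_time(Transient(t, tone(t, 180.0)), 2.5, 0.5)
        with pytest.raises(ValueError, match="outside"):
            detect_revival(sg, 1e6, 10.0)
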
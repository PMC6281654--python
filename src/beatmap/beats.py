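"""Quantum-beat extraction from pump-probe transients and TR-PES maps.

The analysis chain mirrors standard practice in time-resolved photoelectron
spectroscopy:

1. :func:`isolate_beats` — remove the slowly varying population decay
   (constant, single- or bi-exponential baseline, optionally blurred by the
   instrument response) so only the oscillatory part remains;
2. :func:`fft_spectrum` — tapered, zero-padded magnitude spectrum of a
   transient, with the frequency axis in cm^-1;
3. :func:`fft_vs_eke` — the same, column-by-column across the electron
   kinetic energy axis of a 2-D map, revealing *where* in eKE each beat
   appears (beats require a common cation final state);
4. :func:`fft_vs_time` — sliding-window spectrogram FFT(dt), revealing beat
   dampening (IVR) and dephasing/rephasing revivals;
5. :func:`find_beat_peaks` / :func:`detect_revival` — peak reading.

Negative pump-probe delays carry no beat information and are excluded from
every FFT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, get_window
from scipy.special import erfcx

import lmfit

from .units import C_CM_PS, fwhm_to_sigma
from .dynamics import Transient

__all__ = [
    "TRPESMap",
    "FFTSpectrum",
    "FFTvsEKE",
    "Spectrogram",
    "BaselineSpec",
    "isolate_beats",
    "fft_spectrum",
    "fft_vs_eke",
    "fft_vs_time",
    "find_beat_peaks",
    "detect_revival",
    "band_magnitude",
]


# --------------------------------------------------------------------------
# containers


@dataclass
class TRPESMap:
    """2-D time-resolved photoelectron intensity, delay x electron kinetic energy."""

    t_ps: np.ndarray
    eke_cm1: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ps, dtype=float)
        e = np.asarray(self.eke_cm1, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or e.ndim != 1:
            raise ValueError("axes must be 1-D")
        if np.any(np.diff(t) <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("axes must be strictly increasing")
        if z.shape != (t.size, e.size):
            raise ValueError(
                f"intensity shape {z.shape} does not match grids ({t.size}, {e.size})"
            )
        self.t_ps, self.eke_cm1, self.intensity = t, e, z

    def integrate_eke(self, lo_cm1: float | None = None, hi_cm1: float | None = None) -> Transient:
        """Integrate over an eKE region of interest, yielding a 1-D transient."""
        lo = self.eke_cm1[0] if lo_cm1 is None else lo_cm1
        hi = self.eke_cm1[-1] if hi_cm1 is None else hi_cm1
        sel = (self.eke_cm1 >= lo) & (self.eke_cm1 <= hi)
        if not np.any(sel):
            raise ValueError(f"empty eKE selection [{lo}, {hi}] cm^-1")
        y = np.trapezoid(self.intensity[:, sel], self.eke_cm1[sel], axis=1)
        return Transient(
            t_ps=self.t_ps.copy(),
            y=y,
            meta=dict(self.meta, eke_range_cm1=[float(lo), float(hi)]),
        )


@dataclass
class FFTSpectrum:
    """Beat-frequency magnitude spectrum of a single transient.

    Magnitude is normalised so that a unit-amplitude cosine spanning the
    record gives a unit peak.  ``resolution_cm1 = 1 / (c T)`` with ``T``
    the record length is the nominal two-point resolution.
    """

    freq_cm1: np.ndarray
    magnitude: np.ndarray
    resolution_cm1: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_cm1, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("freq and magnitude must be 1-D of equal length")
        if f[0] != 0.0:
            raise ValueError("frequency axis must start at 0")
        self.freq_cm1, self.magnitude = f, m


@dataclass
class FFTvsEKE:
    """FFT(eKE): one beat spectrum per electron-kinetic-energy bin.

    ``mask[i]`` is False where the eKE bin fell below the intensity floor;
    its magnitude row is zero-filled but flagged invalid rather than
    interpreted as beat-free.
    """

    eke_cm1: np.ndarray
    freq_cm1: np.ndarray
    magnitude: np.ndarray  # (n_eke, n_freq)
    mask: np.ndarray
    resolution_cm1: float
    meta: dict = field(default_factory=dict)


@dataclass
class Spectrogram:
    """Sliding-window FFT(dt): beat magnitude vs (window centre, frequency)."""

    window_center_ps: np.ndarray
    freq_cm1: np.ndarray
    magnitude: np.ndarray  # (n_windows, n_freq)
    window_fwhm_ps: float
    step_ps: float
    normalization: str = "global"
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# decay isolation


@dataclass(frozen=True)
class BaselineSpec:
    """Descriptor of the slowly varying population-decay baseline.

    ``kind`` is one of ``constant``, ``exponential``, ``biexponential`` or
    ``auto`` (fit both exponential forms, keep the lower corrected-AIC).
    ``irf_fwhm_ps`` blurs the step onset of the exponentials with the
    instrument response (0 = ideal step).  ``fit_offset`` frees a constant
    pedestal.
    """

    kind: str = "auto"
    irf_fwhm_ps: float = 0.0
    fit_offset: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exponential", "biexponential", "auto"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.irf_fwhm_ps < 0:
            raise ValueError("IRF FWHM must be >= 0")


def smeared_exp(t: np.ndarray, tau: float, sigma: float) -> np.ndarray:
    """Gaussian-blurred one-sided exponential ``G(sigma) * [H(t) exp(-t/tau)]``.

    Evaluated in the numerically stable form
    ``0.5 erfcx(z) exp(-t^2 / (2 sigma^2))`` with
    ``z = (sigma/tau - t/sigma) / sqrt(2)``; for ``sigma == 0`` it reduces
    to the ideal step response.
    """
    t = np.asarray(t, dtype=float)
    if sigma == 0.0:
        return np.where(t >= 0.0, np.exp(-np.clip(t, 0.0, None) / tau), 0.0)
    z = (sigma / tau - t / sigma) / math.sqrt(2.0)
    # far above the rise (z << 0) erfc(z) -> 2 and erfcx overflows: use the
    # plain exponential branch there
    out = np.empty_like(t)
    late = z < -6.0
    out[late] = np.exp(sigma * sigma / (2.0 * tau * tau) - t[late] / tau)
    zl = z[~late]
    tl = t[~late]
    out[~late] = 0.5 * erfcx(zl) * np.exp(-(tl * tl) / (2.0 * sigma * sigma))
    return out


def _baseline_model(t: np.ndarray, params: lmfit.Parameters, n_exp: int, sigma: float) -> np.ndarray:
    y = np.full_like(t, params["offset"].value, dtype=float)
    for j in range(n_exp):
        y = y + params[f"a{j}"].value * smeared_exp(t, params[f"tau{j}"].value, sigma)
    return y


def _fit_baseline(tr: Transient, n_exp: int, spec: BaselineSpec):
    sigma = fwhm_to_sigma(spec.irf_fwhm_ps)
    t, y = tr.t_ps, tr.y
    span = max(tr.span_ps, tr.dt_ps)
    params = lmfit.Parameters()
    params.add("offset", value=float(np.min(y)) if spec.fit_offset else 0.0,
               vary=spec.fit_offset)
    scale = float(np.max(y) - np.min(y)) or float(np.max(np.abs(y))) or 1.0
    for j in range(n_exp):
        params.add(f"a{j}", value=scale / n_exp)
        # stagger initial lifetimes so the bi-exponential explores two scales
        params.add(f"tau{j}", value=span / (2.0 * 4.0**j), min=tr.dt_ps / 10.0)
    result = lmfit.minimize(
        lambda p: _baseline_model(t, p, n_exp, sigma) - y,
        params,
        method="least_squares",
    )
    return result


def _aicc(result) -> float:
    n, k = result.ndata, result.nvarys
    denom = n - k - 1
    return result.aic + (2.0 * k * (k + 1) / denom if denom > 0 else np.inf)


def isolate_beats(
    tr: Transient,
    decay_spec: BaselineSpec | str = "auto",
    *,
    mode: str = "ratio",
) -> Transient:
    """Remove the population decay, leaving the oscillatory beat signal.

    ``ratio`` mode (default) returns ``y / baseline - 1`` — the beats as a
    fractional modulation of the decaying signal; ``subtract`` mode returns
    ``y - baseline``.

    Raises
    ------
    ValueError
        If the baseline fit fails to converge, or if the fitted baseline
        touches zero in ratio mode.
    """
    if isinstance(decay_spec, str):
        decay_spec = BaselineSpec(kind=decay_spec)
    if mode not in ("ratio", "subtract"):
        raise ValueError(f"mode must be ratio|subtract, got {mode!r}")

    if decay_spec.kind == "constant":
        baseline = np.full_like(tr.y, float(np.mean(tr.y)))
        fit_info: dict = {"baseline": "constant", "baseline_mean": float(np.mean(tr.y))}
    else:
        candidates = []
        kinds = (
            [("exponential", 1), ("biexponential", 2)]
            if decay_spec.kind == "auto"
            else [(decay_spec.kind, 1 if decay_spec.kind == "exponential" else 2)]
        )
        for name, n_exp in kinds:
            res = _fit_baseline(tr, n_exp, decay_spec)
            if res.success:
                candidates.append((name, n_exp, res))
        if not candidates:
            raise ValueError("baseline fit failed to converge")
        name, n_exp, res = min(candidates, key=lambda c: _aicc(c[2]))
        sigma = fwhm_to_sigma(decay_spec.irf_fwhm_ps)
        baseline = _baseline_model(tr.t_ps, res.params, n_exp, sigma)
        fit_info = {
            "baseline": name,
            "baseline_params": {k: float(v.value) for k, v in res.params.items()},
            "baseline_aicc": float(_aicc(res)),
        }

    if mode == "ratio":
        peak = float(np.max(np.abs(baseline)))
        if peak == 0.0 or np.min(baseline) <= 1e-12 * peak:
            raise ValueError("baseline crosses zero; ratio mode is undefined")
        y = tr.y / baseline - 1.0
    else:
        y = tr.y - baseline
    return Transient(t_ps=tr.t_ps.copy(), y=y, meta=dict(tr.meta, isolate_mode=mode, **fit_info))


# --------------------------------------------------------------------------
# FFT spectra


def _positive_delays(tr: Transient) -> Transient:
    if tr.t_ps[0] >= 0.0:
        return tr
    sel = tr.t_ps >= 0.0
    return Transient(t_ps=tr.t_ps[sel], y=tr.y[sel], meta=dict(tr.meta))


def fft_spectrum(
    tr: Transient,
    window: str = "hann",
    pad_factor: int = 8,
) -> FFTSpectrum:
    """Tapered, zero-padded magnitude spectrum with the axis in cm^-1.

    The taper-weighted mean is removed before transforming (exact DC
    suppression under the taper); magnitude is scaled so a unit-amplitude
    cosine filling the record gives a peak of 1.  Zero-padding by
    ``pad_factor`` interpolates the spectrum for peak refinement; it does
    not add resolution.
    """
    tr = _positive_delays(tr)
    n = tr.t_ps.size
    if n < 8:
        raise ValueError("need at least 8 positive-delay samples for an FFT")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    w = get_window(window, n, fftbins=False)
    wsum = float(np.sum(w))
    y = tr.y - float(np.sum(w * tr.y)) / wsum
    nfft = int(pad_factor) * n
    mag = np.abs(np.fft.rfft(y * w, n=nfft)) / (wsum / 2.0)
    dt = tr.dt_ps
    freq = np.fft.rfftfreq(nfft, d=dt) / C_CM_PS
    res = 1.0 / (C_CM_PS * tr.span_ps)
    return FFTSpectrum(
        freq_cm1=freq,
        magnitude=mag,
        resolution_cm1=res,
        meta=dict(tr.meta, window=window, pad_factor=int(pad_factor)),
    )


def find_beat_peaks(
    spec: FFTSpectrum,
    prominence_frac: float = 0.1,
    min_freq_cm1: float | None = None,
) -> list[tuple[float, float]]:
    """Local maxima of a beat spectrum, parabolic-refined, DC excluded.

    Peaks below ``min_freq_cm1`` (default 1.5x the nominal resolution) are
    discarded as DC/window leakage.  Returns ``(freq_cm1, magnitude)``
    pairs sorted by descending magnitude; may be empty.
    """
    if min_freq_cm1 is None:
        min_freq_cm1 = 1.5 * spec.resolution_cm1
    f, m = spec.freq_cm1, spec.magnitude
    valid = f >= min_freq_cm1
    if not np.any(valid):
        return []
    ref = float(np.max(m[valid]))
    if ref <= 0.0:
        return []
    idx, _ = find_peaks(m, prominence=prominence_frac * ref)
    idx = idx[f[idx] >= min_freq_cm1]
    df = f[1] - f[0]
    out = []
    for k in idx:
        if 0 < k < m.size - 1:
            a, b, c = m[k - 1], m[k], m[k + 1]
            denom = a - 2.0 * b + c
            delta = 0.5 * (a - c) / denom if denom != 0.0 else 0.0
            out.append((float(f[k] + delta * df), float(b - 0.25 * (a - c) * delta)))
        else:
            out.append((float(f[k]), float(m[k])))
    out.sort(key=lambda p: -p[1])
    return out


# --------------------------------------------------------------------------
# FFT(eKE)


def _bin_columns(map_: TRPESMap, eke_bin_cm1: float | None):
    """Group eKE columns into bins of at least ``eke_bin_cm1`` width."""
    e = map_.eke_cm1
    if eke_bin_cm1 is None or e.size < 2:
        return e.copy(), map_.intensity.copy()
    spacing = float(np.median(np.diff(e)))
    per_bin = max(1, int(math.ceil(eke_bin_cm1 / spacing)))
    if per_bin == 1:
        return e.copy(), map_.intensity.copy()
    n_bins = e.size // per_bin
    trimmed = map_.intensity[:, : n_bins * per_bin]
    centers = e[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    binned = trimmed.reshape(map_.t_ps.size, n_bins, per_bin).mean(axis=2)
    return centers, binned


def fft_vs_eke(
    map_: TRPESMap,
    decay_spec: BaselineSpec | str | None = "auto",
    window: str = "hann",
    pad_factor: int = 8,
    *,
    eke_bin_cm1: float | None = 50.0,
    intensity_floor_frac: float = 0.05,
) -> FFTvsEKE:
    """Column-wise beat spectra across the electron kinetic energy axis.

    Each eKE bin is decay-isolated (unless ``decay_spec`` is None) and
    Fourier transformed independently.  Bins whose peak intensity falls
    below ``intensity_floor_frac`` of the map maximum are masked out, not
    zero-filled: low signal means "no information", not "no beats".  A
    column whose fitted baseline touches zero (ratio mode is then
    undefined) falls back to subtract-mode isolation for that column.
    """
    if map_.t_ps.size == 0 or map_.eke_cm1.size == 0:
        raise ValueError("empty TR-PES map")
    centers, cols = _bin_columns(map_, eke_bin_cm1)
    global_peak = float(np.max(np.abs(cols))) or 1.0
    spectra: list[np.ndarray | None] = []
    mask = np.zeros(centers.size, dtype=bool)
    freq = None
    res = None
    for i in range(centers.size):
        col = Transient(t_ps=map_.t_ps, y=cols[:, i])
        if float(np.max(np.abs(col.y))) < intensity_floor_frac * global_peak:
            spectra.append(None)
            continue
        if decay_spec is not None:
            try:
                col = isolate_beats(col, decay_spec)
            except ValueError:
                col = isolate_beats(col, decay_spec, mode="subtract")
        sp = fft_spectrum(col, window=window, pad_factor=pad_factor)
        freq, res = sp.freq_cm1, sp.resolution_cm1
        spectra.append(sp.magnitude)
        mask[i] = True
    if freq is None:
        raise ValueError("every eKE bin fell below the intensity floor")
    magnitude = np.zeros((centers.size, freq.size))
    for i, s in enumerate(spectra):
        if s is not None:
            magnitude[i] = s
    return FFTvsEKE(
        eke_cm1=centers,
        freq_cm1=freq,
        magnitude=magnitude,
        mask=mask,
        resolution_cm1=res,
        meta=dict(
            map_.meta,
            window=window,
            pad_factor=int(pad_factor),
            eke_bin_cm1=eke_bin_cm1,
            intensity_floor_frac=intensity_floor_frac,
        ),
    )


# --------------------------------------------------------------------------
# FFT(dt) spectrogram


def fft_vs_time(
    tr: Transient,
    window_fwhm_ps: float = 2.5,
    step_ps: float = 0.1,
    taper: str = "gaussian",
    *,
    pad_factor: int = 4,
    normalization: str = "global",
) -> Spectrogram:
    """Sliding-window beat spectrogram FFT(dt).

    A Gaussian (or Hann) taper of the given FWHM slides across the
    positive-delay record in steps of ``step_ps``; each window yields a
    magnitude spectrum normalised like :func:`fft_spectrum` (so a
    stationary unit cosine gives a flat band of height ~1 in ``global``
    mode).  ``per-window-max`` rescales each window to unit maximum,
    emphasising weak late-time structure at the cost of absolute scale.
    """
    if normalization not in ("global", "per-window-max"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if taper not in ("gaussian", "hann"):
        raise ValueError(f"unknown taper {taper!r}")
    tr = _positive_delays(tr)
    t, y = tr.t_ps, tr.y
    if window_fwhm_ps > tr.span_ps:
        raise ValueError(
            f"window FWHM {window_fwhm_ps} ps exceeds record length {tr.span_ps} ps"
        )
    dt = tr.dt_ps
    nfft = int(pad_factor) * t.size
    freq = np.fft.rfftfreq(nfft, d=dt) / C_CM_PS
    centers = np.arange(t[0], t[-1] + 1e-12, step_ps)
    mags = np.empty((centers.size, freq.size))
    for i, tc in enumerate(centers):
        if taper == "gaussian":
            x = (t - tc) / window_fwhm_ps
            w = np.exp(-4.0 * math.log(2.0) * x * x)
        else:
            half = window_fwhm_ps  # Hann with total width 2*FWHM
            x = np.clip((t - tc) / (2.0 * half), -0.5, 0.5)
            w = np.cos(math.pi * x) ** 2
            w[np.abs(t - tc) > half] = 0.0
        wsum = float(np.sum(w))
        z = (y - float(np.sum(w * y)) / wsum) * w
        mags[i] = np.abs(np.fft.rfft(z, n=nfft)) / (wsum / 2.0)
    if normalization == "per-window-max":
        peak = mags.max(axis=1, keepdims=True)
        peak[peak == 0.0] = 1.0
        mags = mags / peak
    return Spectrogram(
        window_center_ps=centers,
        freq_cm1=freq,
        magnitude=mags,
        window_fwhm_ps=window_fwhm_ps,
        step_ps=step_ps,
        normalization=normalization,
        meta=dict(tr.meta, taper=taper, pad_factor=int(pad_factor)),
    )


def band_magnitude(
    sg: Spectrogram, freq_cm1: float, band_halfwidth_cm1: float
) -> np.ndarray:
    """Mean spectrogram magnitude over a frequency band, one value per window."""
    lo, hi = freq_cm1 - band_halfwidth_cm1, freq_cm1 + band_halfwidth_cm1
    if hi < sg.freq_cm1[0] or lo > sg.freq_cm1[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] cm^-1 lies outside the spectrogram frequency range"
        )
    sel = (sg.freq_cm1 >= lo) & (sg.freq_cm1 <= hi)
    if not np.any(sel):
        raise ValueError("band narrower than one frequency bin")
    return sg.magnitude[:, sel].mean(axis=1)


def detect_revival(
    sg: Spectrogram,
    freq_cm1: float,
    band_halfwidth_cm1: float,
    *,
    prominence_frac: float = 0.2,
) -> list[float]:
    """Times (ps) at which a dephased beat band re-coheres.

    The band magnitude trace is scanned for local maxima occurring after
    its first local minimum (the initial dampening); maxima must be
    prominent by ``prominence_frac`` of the trace's dynamic range.  An
    undamped (monotone) band yields an empty list.
    """
    b = band_magnitude(sg, freq_cm1, band_halfwidth_cm1)
    minima, _ = find_peaks(-b)
    if minima.size == 0:
        return []
    i0 = int(minima[0])
    rng = float(b.max() - b.min())
    if rng <= 0.0:
        return []
    peaks, _ = find_peaks(b[i0:], prominence=prominence_frac * rng)
    return [float(sg.window_center_ps[i0 + k]) for k in peaks]
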
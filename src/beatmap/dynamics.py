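"""Free evolution of the vibrational wavepacket and its survival probability.

A wavepacket ``|Psi(t)> = sum_n a_n |psi_n> exp(-i 2 pi c E_n t)`` prepared
by a broadband pump evolves freely; pump-probe signal that projects the
wavepacket onto a common final state is modulated at the pairwise level
gaps ``|E_n - E_m|`` — quantum beats.  The observable modelled here is the
survival probability of the time-autocorrelation, augmented with per-level
phase offsets:

    C(t) = sum_n a_n^2 exp(-i (2 pi c E_n t + phi_n)),     P(t) = |C(t)|^2

The plain autocorrelation (all ``phi_n = 0``) is insensitive to phases; the
phase-augmented form lets individual beat components be shifted in time,
which is how a mode-dependent ionisation window manifests in the measured
transients.  With zero phases ``P(0) = 1`` exactly and ``P`` is even in t.

Finite pump/probe pulse durations blur the signal in time; this is modelled
as convolution with a unit-area Gaussian instrument response function (IRF).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .units import C_CM_PS, fwhm_to_sigma
from .vibronic import StickSpectrum, label_matches

__all__ = [
    "Wavepacket",
    "Transient",
    "survival_probability",
    "apply_mode_phase",
    "smooth_with_irf",
]

_NORM_TOL = 1e-9
_UNIFORM_TOL_PS = 1e-9


@dataclass(frozen=True)
class Wavepacket:
    """Coherent superposition of vibronic eigenstates.

    ``amplitudes`` are real and non-negative with ``sum(a^2) == 1``;
    complex character lives entirely in ``phases_rad``.
    """

    energies_cm1: np.ndarray
    amplitudes: np.ndarray
    phases_rad: np.ndarray

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.energies_cm1, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        p = np.atleast_1d(np.asarray(self.phases_rad, dtype=float))
        if not (e.shape == a.shape == p.shape):
            raise ValueError("energies, amplitudes and phases must have equal length")
        if e.size == 0:
            raise ValueError("wavepacket must contain at least one level")
        if np.any(np.diff(e) <= 0):
            raise ValueError("wavepacket energies must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("wavepacket amplitudes must be non-negative")
        norm = float(np.sum(a * a))
        if abs(norm - 1.0) > _NORM_TOL:
            raise ValueError(f"wavepacket populations must sum to 1, got {norm!r}")
        for name, arr in (("energies_cm1", e), ("amplitudes", a), ("phases_rad", p)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.energies_cm1.size

    @property
    def populations(self) -> np.ndarray:
        return self.amplitudes**2

    def pairwise_gaps_cm1(self) -> np.ndarray:
        """Sorted unique pairwise level gaps (the possible beat frequencies)."""
        e = self.energies_cm1
        gaps = np.abs(e[:, None] - e[None, :])[np.triu_indices(e.size, k=1)]
        return np.unique(gaps)

    @classmethod
    def from_levels(
        cls,
        energies_cm1,
        amplitudes=None,
        phases_rad=None,
    ) -> "Wavepacket":
        """Build a wavepacket, normalising amplitudes (equal weights if omitted)."""
        e = np.atleast_1d(np.asarray(energies_cm1, dtype=float))
        a = (
            np.ones_like(e)
            if amplitudes is None
            else np.atleast_1d(np.asarray(amplitudes, dtype=float))
        )
        a = a / math.sqrt(float(np.sum(a * a)))
        p = (
            np.zeros_like(e)
            if phases_rad is None
            else np.atleast_1d(np.asarray(phases_rad, dtype=float))
        )
        return cls(energies_cm1=e, amplitudes=a, phases_rad=p)


@dataclass
class Transient:
    """1-D pump-probe transient on a uniform delay grid.

    ``meta`` is a free-form provenance record (pump/probe identifiers,
    integrated eKE range, IRF width, ...), echoed into file headers.
    """

    t_ps: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ps, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("t_ps and y must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("delay grid must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > _UNIFORM_TOL_PS:
                raise ValueError("delay grid must be uniform to within 1e-9 ps")
        self.t_ps = t
        self.y = y

    @property
    def dt_ps(self) -> float:
        return float(self.t_ps[1] - self.t_ps[0])

    @property
    def span_ps(self) -> float:
        return float(self.t_ps[-1] - self.t_ps[0])


def autocorrelation(wp: Wavepacket, t_ps: np.ndarray) -> np.ndarray:
    """Complex phase-augmented autocorrelation ``C(t)`` (see module docstring)."""
    t = np.asarray(t_ps, dtype=float)
    # phase matrix: levels x times
    arg = 2.0 * math.pi * C_CM_PS * np.outer(wp.energies_cm1, t) + wp.phases_rad[:, None]
    return np.sum(wp.populations[:, None] * np.exp(-1j * arg), axis=0)


def survival_probability(wp: Wavepacket, t_ps: np.ndarray) -> Transient:
    """Survival probability ``P(t) = |C(t)|^2`` on the given uniform delay grid.

    For a single level ``P == 1`` identically; for two levels with equal
    populations and zero phases ``P(t) = (1 + cos(2 pi c dE t)) / 2``.
    """
    c = autocorrelation(wp, t_ps)
    p = np.abs(c) ** 2
    return Transient(
        t_ps=np.asarray(t_ps, dtype=float),
        y=p,
        meta={
            "kind": "survival_probability",
            "n_levels": len(wp),
            "energies_cm1": [float(x) for x in wp.energies_cm1],
        },
    )


def apply_mode_phase(
    wp: Wavepacket,
    mode_label: str,
    phase_rad: float,
    spectrum: StickSpectrum,
    *,
    on_missing: str = "warn",
    energy_tol_cm1: float = 1e-6,
) -> Wavepacket:
    """Add ``phase_rad`` to every wavepacket level assigned to ``mode_label``.

    Assignment is looked up in ``spectrum``: a wavepacket level matches when
    a stick at the same energy (within ``energy_tol_cm1``) carries the mode
    name among its label components (``"179"`` matches ``"179(2)"`` and
    ``"179(1)+421(1)"``).  If no level matches, behaviour follows
    ``on_missing``: ``"warn"`` (default) returns an unchanged copy with a
    warning, ``"raise"`` raises, ``"ignore"`` is silent.
    """
    if on_missing not in ("warn", "raise", "ignore"):
        raise ValueError(f"on_missing must be warn|raise|ignore, got {on_missing!r}")
    matched_sticks = [
        lv for lv in spectrum.levels if label_matches(lv.mode_label, mode_label)
    ]
    phases = wp.phases_rad.copy()
    hit = False
    for lv in matched_sticks:
        idx = np.nonzero(np.abs(wp.energies_cm1 - lv.energy_cm1) <= energy_tol_cm1)[0]
        if idx.size:
            phases[idx] += phase_rad
            hit = True
    if not hit:
        msg = f"no wavepacket level matches mode label {mode_label!r}"
        if on_missing == "raise":
            raise ValueError(msg)
        if on_missing == "warn":
            warnings.warn(msg, stacklevel=2)
        return replace(wp, phases_rad=wp.phases_rad.copy())
    return replace(wp, phases_rad=phases)


def apply_mode_phases(
    wp: Wavepacket, phases: Mapping[str, float], spectrum: StickSpectrum, **kw
) -> Wavepacket:
    """Apply several per-mode phase offsets in sequence."""
    for mode, ph in phases.items():
        wp = apply_mode_phase(wp, mode, ph, spectrum, **kw)
    return wp


def gaussian_smooth(y: np.ndarray, dt: float, fwhm: float, axis: int = -1) -> np.ndarray:
    """Discrete convolution with a unit-area Gaussian (reflected edges).

    Shared by the 1-D transient smoother and the 2-D synthetic map
    generator so that both apply the numerically identical filter.
    """
    sigma_samples = fwhm_to_sigma(fwhm) / dt
    return gaussian_filter1d(y, sigma_samples, axis=axis, mode="reflect", truncate=8.0)


def smooth_with_irf(tr: Transient, irf_fwhm_ps: float) -> Transient:
    """Blur a transient with a Gaussian instrument response of the given FWHM.

    ``irf_fwhm_ps == 0`` returns a bit-identical copy.  A cosine at
    ``nu`` cm^-1 is attenuated by ``exp(-(pi c nu)^2 w^2 / (4 ln 2))``
    with its phase preserved, which is why beats much faster than the
    pump-probe cross-correlation disappear from measured transients.
    """
    if irf_fwhm_ps < 0:
        raise ValueError("IRF FWHM must be >= 0")
    if irf_fwhm_ps == 0.0:
        return Transient(t_ps=tr.t_ps.copy(), y=tr.y.copy(), meta=dict(tr.meta))
    if tr.t_ps.size < 2:
        raise ValueError("transient too short to smooth")
    dt = tr.dt_ps
    if dt >= irf_fwhm_ps / 3.0:
        raise ValueError(
            f"delay grid spacing {dt} ps too coarse for IRF FWHM {irf_fwhm_ps} ps "
            "(need spacing < FWHM/3)"
        )
    y = gaussian_smooth(tr.y, dt, irf_fwhm_ps)
    meta = dict(tr.meta)
    meta["irf_fwhm_ps"] = irf_fwhm_ps
    return Transient(t_ps=tr.t_ps.copy(), y=y, meta=meta)
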
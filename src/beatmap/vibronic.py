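"""Vibronic level structure of the excited state and pump-pulse selection.

An excitation (LIF-type) stick spectrum locates the vibronic levels of the
first excited singlet state relative to its origin.  A spectrally broad
femtosecond pump pulse coherently populates every level under its spectral
envelope, preparing a vibrational wavepacket.  This module holds the stick
spectrum containers and the rule that turns sticks plus a pump profile into
wavepacket amplitudes.

Conventions
-----------
* Level energies are in cm^-1 relative to the S1 origin.
* Stick intensities are relative fluorescence-excitation intensities and
  therefore proportional to the square of a transition moment; by default
  they enter the wavepacket amplitude through their square root.
* ``PumpPulse.fwhm_cm1`` is the FWHM of the measured *spectral intensity*
  profile.  The weight applied to the transition amplitude is the field
  envelope, i.e. the square root of the intensity profile, so populations
  follow the intensity profile directly: ``a_n^2 ∝ I_n g(E_n)`` with ``g``
  the unit-peak Gaussian intensity envelope.

Mode labels
-----------
Levels may carry an assignment label of the form ``"179(2)"`` (two quanta
of the 179 cm^-1 mode), ``"179(1)+421(1)"`` (combination band) or any free
string for unassigned satellites.  :func:`label_components` parses the
structured form; per-mode phase manipulation matches on the mode name part.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import wavelength_to_relative_energy

__all__ = [
    "VibronicLevel",
    "StickSpectrum",
    "PumpPulse",
    "build_wavepacket",
    "label_components",
    "label_matches",
    "PumpOverlapError",
]


class PumpOverlapError(ValueError):
    """Raised when the pump envelope gives negligible weight to every level."""


@dataclass(frozen=True)
class VibronicLevel:
    """One stick of the excitation spectrum.

    Attributes
    ----------
    energy_cm1
        Level energy relative to the S1 origin (>= 0).
    intensity
        Relative excitation intensity (>= 0).
    mode_label
        Optional assignment, e.g. ``"179(1)"`` or ``"179(1)+421(1)"``.
    phase_rad
        Initial phase offset carried into the wavepacket (radians).
    """

    energy_cm1: float
    intensity: float
    mode_label: str | None = None
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy_cm1) or self.energy_cm1 < 0:
            raise ValueError(f"level energy must be finite and >= 0, got {self.energy_cm1}")
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"level intensity must be finite and >= 0, got {self.intensity}")
        if not math.isfinite(self.phase_rad):
            raise ValueError("level phase must be finite")


_LABEL_PART = re.compile(r"^\s*([^()+\s]+)\s*(?:\((\d+)\))?\s*$")


def label_components(label: str | None) -> list[tuple[str, int]]:
    """Parse an assignment label into ``(mode_name, quanta)`` pairs.

    ``"179(2)"`` -> ``[("179", 2)]``; ``"179(1)+421(1)"`` -> both modes;
    a bare name implies one quantum.  Unparseable labels yield the whole
    string as a single component with one quantum.
    """
    if not label:
        return []
    parts = []
    for chunk in label.split("+"):
        m = _LABEL_PART.match(chunk)
        if m:
            parts.append((m.group(1), int(m.group(2)) if m.group(2) else 1))
        else:
            parts.append((chunk.strip(), 1))
    return parts


def label_matches(label: str | None, mode_name: str) -> bool:
    """True if ``mode_name`` appears among the mode components of ``label``."""
    return any(name == mode_name for name, _ in label_components(label))


@dataclass(frozen=True)
class StickSpectrum:
    """Ordered vibronic stick spectrum relative to the electronic origin.

    Levels closer in energy than ``merge_tol_cm1`` are merged on
    construction: intensities are summed, the merged energy is the
    intensity-weighted mean, and the first non-empty label wins (digitised
    spectra routinely contain near-duplicate sticks).
    """

    levels: tuple[VibronicLevel, ...]
    origin_cm1: float
    merge_tol_cm1: float = field(default=0.5, compare=False)

    def __post_init__(self) -> None:
        merged = _merge_levels(self.levels, self.merge_tol_cm1)
        object.__setattr__(self, "levels", merged)
        energies = [lv.energy_cm1 for lv in merged]
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("level energies must be strictly increasing after merging")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def energies_cm1(self) -> np.ndarray:
        return np.array([lv.energy_cm1 for lv in self.levels])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([lv.intensity for lv in self.levels])

    @property
    def phases_rad(self) -> np.ndarray:
        return np.array([lv.phase_rad for lv in self.levels])

    def with_phase_on_mode(self, mode_name: str, phase_rad: float) -> "StickSpectrum":
        """Copy with ``phase_rad`` added to every level assigned to ``mode_name``."""
        new = tuple(
            replace(lv, phase_rad=lv.phase_rad + phase_rad)
            if label_matches(lv.mode_label, mode_name)
            else lv
            for lv in self.levels
        )
        return replace(self, levels=new)

    @classmethod
    def from_arrays(
        cls,
        energies_cm1: Sequence[float],
        intensities: Sequence[float],
        origin_cm1: float,
        mode_labels: Sequence[str | None] | None = None,
        phases_rad: Sequence[float] | None = None,
        merge_tol_cm1: float = 0.5,
    ) -> "StickSpectrum":
        n = len(energies_cm1)
        labels = mode_labels if mode_labels is not None else [None] * n
        phases = phases_rad if phases_rad is not None else [0.0] * n
        if not (len(intensities) == len(labels) == len(phases) == n):
            raise ValueError("all stick-spectrum arrays must have equal length")
        levels = tuple(
            VibronicLevel(float(e), float(i), lb, float(p))
            for e, i, lb, p in zip(energies_cm1, intensities, labels, phases)
        )
        return cls(levels=levels, origin_cm1=origin_cm1, merge_tol_cm1=merge_tol_cm1)


def _merge_levels(
    levels: Iterable[VibronicLevel], tol_cm1: float
) -> tuple[VibronicLevel, ...]:
    ordered = sorted(levels, key=lambda lv: lv.energy_cm1)
    merged: list[VibronicLevel] = []
    for lv in ordered:
        if merged and lv.energy_cm1 - merged[-1].energy_cm1 < tol_cm1:
            prev = merged[-1]
            w = prev.intensity + lv.intensity
            if w > 0:
                e = (prev.energy_cm1 * prev.intensity + lv.energy_cm1 * lv.intensity) / w
            else:
                e = 0.5 * (prev.energy_cm1 + lv.energy_cm1)
            merged[-1] = VibronicLevel(
                energy_cm1=e,
                intensity=w,
                mode_label=prev.mode_label or lv.mode_label,
                phase_rad=prev.phase_rad,
            )
        else:
            merged.append(lv)
    return tuple(merged)


@dataclass(frozen=True)
class PumpPulse:
    """Spectral profile of the pump pulse, relative to the S1 origin.

    ``fwhm_cm1`` is the FWHM of the spectral *intensity* profile (the
    quantity read off a spectrometer, ~500 cm^-1 for the femtosecond
    pulses modelled here).
    """

    center_cm1: float
    fwhm_cm1: float

    def __post_init__(self) -> None:
        if not (self.fwhm_cm1 > 0):
            raise ValueError(f"pump FWHM must be positive, got {self.fwhm_cm1}")

    @classmethod
    def from_wavelength(
        cls, lambda_nm: float, origin_cm1: float, fwhm_cm1: float
    ) -> "PumpPulse":
        return cls(
            center_cm1=wavelength_to_relative_energy(lambda_nm, origin_cm1),
            fwhm_cm1=fwhm_cm1,
        )

    def intensity_envelope(self, energy_cm1: np.ndarray) -> np.ndarray:
        """Unit-peak Gaussian spectral intensity profile evaluated at ``energy_cm1``."""
        x = (np.asarray(energy_cm1, dtype=float) - self.center_cm1) / self.fwhm_cm1
        return np.exp(-4.0 * math.log(2.0) * x * x)


def build_wavepacket(
    spectrum: StickSpectrum,
    pump: PumpPulse,
    *,
    amplitude_weighting: str = "sqrt",
    population_floor: float = 1e-6,
):
    """Construct the coherent wavepacket prepared by a broadband pump pulse.

    Amplitudes are ``a_n ∝ w(I_n) * sqrt(g(E_n))`` where ``g`` is the
    unit-peak Gaussian pump intensity envelope and ``w`` is ``sqrt`` (the
    default, appropriate when stick intensities scale as squared transition
    moments) or ``linear``.  Amplitudes are normalised so that
    ``sum(a_n^2) == 1``; levels whose normalised population falls below
    ``population_floor`` are dropped (and the rest renormalised).  Phases
    are copied from the levels.

    Raises
    ------
    PumpOverlapError
        If every level receives (numerically) zero pump weight.
    """
    from .dynamics import Wavepacket  # local import to avoid a cycle

    if len(spectrum) == 0:
        raise ValueError("stick spectrum is empty")
    if amplitude_weighting not in ("sqrt", "linear"):
        raise ValueError(f"unknown amplitude weighting {amplitude_weighting!r}")

    energies = spectrum.energies_cm1
    intensities = spectrum.intensities
    g = pump.intensity_envelope(energies)
    base = np.sqrt(intensities) if amplitude_weighting == "sqrt" else intensities
    w = base * np.sqrt(g)  # field envelope = sqrt of intensity profile
    norm2 = float(np.sum(w * w))
    if norm2 <= 0.0:
        raise PumpOverlapError(
            "pump does not overlap spectrum: all level weights are zero "
            f"(pump center {pump.center_cm1} cm^-1, FWHM {pump.fwhm_cm1} cm^-1)"
        )
    a = w / math.sqrt(norm2)
    keep = a * a >= population_floor
    if not np.any(keep):
        raise PumpOverlapError("pump does not overlap spectrum above the population floor")
    a = a[keep]
    a = a / math.sqrt(float(np.sum(a * a)))
    return Wavepacket(
        energies_cm1=energies[keep],
        amplitudes=a,
        phases_rad=spectrum.phases_rad[keep],
    )
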
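"""Harmonic vibrational state counting by Beyer-Swinehart direct count.

The Beyer-Swinehart algorithm folds one harmonic mode at a time into an
energy-binned count array: starting from a single state (the vibrationless
level) in bin 0, each mode of frequency ``nu`` adds ``counts[i - r]`` to
``counts[i]`` in place (``r = nu`` in bins), which enumerates every
quantum-number combination exactly.  The cumulative sum gives the total
count N(E); a windowed average of the per-bin counts gives the density of
states rho(E), the quantity that controls the onset of statistical
intramolecular vibrational energy redistribution.

No anharmonicity is modelled; degenerate modes are represented by listing
a frequency multiple times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModeSet",
    "beyer_swinehart_counts",
    "cumulative_counts",
    "density_of_states",
]


@dataclass(frozen=True)
class ModeSet:
    """A list of harmonic vibrational frequencies (cm^-1, all > 0).

    May be empty (a bare origin with no vibrations).  ``label`` records
    provenance, e.g. which electronic state / geometry the frequencies
    belong to.
    """

    frequencies_cm1: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_cm1)
        if any(f <= 0 for f in freqs):
            raise ValueError("all mode frequencies must be positive")
        object.__setattr__(self, "frequencies_cm1", freqs)

    def __len__(self) -> int:
        return len(self.frequencies_cm1)

    @classmethod
    def from_file(cls, path, label: str = "") -> "ModeSet":
        """Read one frequency per line from a text file ('#' comments allowed)."""
        freqs = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    freqs.append(float(line))
        return cls(frequencies_cm1=tuple(freqs), label=label or str(path))


def beyer_swinehart_counts(
    modes: ModeSet, e_max_cm1: float, bin_cm1: float = 1.0
) -> np.ndarray:
    """Number of vibrational states in each energy bin up to ``e_max_cm1``.

    ``counts[i]`` counts states with energy in bin ``i`` (bin 0 holds the
    vibrationless level, always exactly 1).  Frequencies are rounded to
    the nearest bin; a frequency that rounds below one bin is rejected
    because the fold would miscount it as zero energy.
    """
    if not (e_max_cm1 > 0):
        raise ValueError("e_max_cm1 must be positive")
    if not (bin_cm1 >= 1):
        raise ValueError("bin width must be >= 1 cm^-1")
    n_bins = int(np.floor(e_max_cm1 / bin_cm1)) + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    counts[0] = 1
    for f in modes.frequencies_cm1:
        r = int(round(f / bin_cm1))
        if r < 1:
            raise ValueError(
                f"mode at {f} cm^-1 is smaller than the bin width {bin_cm1} cm^-1; "
                "use a finer grid"
            )
        for i in range(r, n_bins):
            counts[i] += counts[i - r]
    return counts


def cumulative_counts(counts: np.ndarray) -> np.ndarray:
    """Total number of states at or below each bin energy, N(E)."""
    return np.cumsum(counts)


def density_of_states(
    counts: np.ndarray,
    at_energy_cm1: float,
    smooth_window_cm1: float = 100.0,
    bin_cm1: float = 1.0,
) -> float:
    """Windowed average density of states (states per cm^-1).

    Averages the binned counts over ``smooth_window_cm1`` centred on
    ``at_energy_cm1``.  A window reaching past the counted range is
    truncated with a warning.
    """
    n_bins = counts.size
    e_max = (n_bins - 1) * bin_cm1
    if not (0.0 <= at_energy_cm1 <= e_max):
        raise ValueError(
            f"energy {at_energy_cm1} cm^-1 outside counted range [0, {e_max}]"
        )
    half = smooth_window_cm1 / 2.0
    i_lo = int(np.ceil((at_energy_cm1 - half) / bin_cm1))
    i_hi = int(np.floor((at_energy_cm1 + half) / bin_cm1))
    if i_lo < 0 or i_hi > n_bins - 1:
        warnings.warn(
            "smoothing window extends outside the counted range; truncating",
            stacklevel=2,
        )
        i_lo = max(i_lo, 0)
        i_hi = min(i_hi, n_bins - 1)
    width_cm1 = (i_hi - i_lo + 1) * bin_cm1
    return float(np.sum(counts[i_lo : i_hi + 1])) / width_cm1
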
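"""Synthetic stand-in for the S1 harmonic frequency list of methyl anthranilate.

The real S1 equilibrium frequencies come from excited-state electronic
structure calculations and are consumed as *input* by this package; this
module ships a synthetic, chemically plausible surrogate so that state
counting can be exercised without that input.  The list is constructed
from group-frequency reasoning for a 20-atom aromatic amino-ester
(54 normal modes = 45 skeletal/bending modes below 1700 cm^-1, including
the two experimentally observed LIF-active modes at 179 and 421 cm^-1,
plus 9 C-H/N-H stretches): it is structurally faithful (mode count,
low-frequency torsional cluster, ring-mode region, stretch region) but the
individual values are NOT computed frequencies and must not be quoted as
such.  Supply a real frequency file for quantitative work.
"""

from __future__ import annotations

from .states import ModeSet

#: Synthetic S1-state frequencies (cm^-1) for a methyl-anthranilate-like
#: molecule; see the module docstring for provenance and caveats.
MA_S1_FREQUENCIES_SYNTHETIC: tuple[float, ...] = (
    # torsions and substituent bends
    55.0, 85.0, 120.0, 160.0, 179.0, 215.0, 255.0, 300.0, 345.0, 365.0,
    # skeletal bends / ring deformations
    421.0, 445.0, 490.0, 530.0, 560.0, 590.0, 630.0, 670.0, 700.0, 730.0,
    760.0, 790.0, 820.0, 850.0, 880.0, 910.0, 940.0, 965.0, 990.0, 1020.0,
    # C-C/C-N/C-O stretches and in-plane CH bends
    1050.0, 1080.0, 1110.0, 1140.0, 1170.0, 1200.0, 1230.0, 1260.0, 1290.0,
    1330.0, 1370.0, 1410.0, 1450.0, 1500.0, 1600.0,
    # C-H stretches (methyl + aromatic) and N-H stretches
    2950.0, 2995.0, 3040.0, 3060.0, 3075.0, 3090.0, 3105.0, 3420.0, 3540.0,
)


def ma_s1_modes_synthetic() -> ModeSet:
    """The synthetic MA-like S1 mode set as a :class:`~beatmap.states.ModeSet`."""
    return ModeSet(
        frequencies_cm1=MA_S1_FREQUENCIES_SYNTHETIC,
        label="MA S1,eq (synthetic surrogate)",
    )
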
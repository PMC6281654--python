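"""Synthetic stick spectra and 2-D TR-PES maps with realistic beat structure.

The generator realises the physical mechanism behind quantum beats in
time-resolved photoelectron spectroscopy: the probe projects each
wavepacket eigenstate ``n`` onto cation vibrational levels ``v+`` with
Franck-Condon amplitudes, each (n, v+) ionisation channel producing
photoelectrons at its energy-conserving kinetic energy
``eKE = eke_offset + E_n - E(v+)``.  Two eigenstates interfere — beat —
only in eKE regions where they share a final state, so the beat pattern
shifts across the eKE axis exactly as observed experimentally.

Beat dampening (IVR) is applied per interference term: each off-diagonal
(n, m) cross term decays with its pair lifetime, while the diagonal
(population) terms follow the overall electronic decay only.

Everything is deterministic under a fixed seed, and the noiseless core is
independent of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .units import C_CM_PS
from .vibronic import PumpPulse, StickSpectrum, VibronicLevel, build_wavepacket
from .dynamics import Transient, gaussian_smooth
from .beats import TRPESMap

__all__ = [
    "IonizationModel",
    "SyntheticSpec",
    "generate_trpes",
    "generate_lif_spectrum",
    "ma_lif_default",
    "scenario",
    "SCENARIO_NAMES",
    "make_fixture_suite",
]


_LN16 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class IonizationModel:
    """Projection of the excited-state levels onto the cation manifold.

    ``fc[n, q]`` is the probability that excited level ``n`` ionises into
    cation level ``q`` (rows sum to 1).  ``eke_offset_cm1`` is the
    electron kinetic energy of the origin -> origin channel, and each
    photoelectron feature is Gaussian in eKE with intensity FWHM
    ``eke_bandwidth_cm1``.
    """

    cation_levels_cm1: tuple[float, ...]
    fc: np.ndarray
    eke_offset_cm1: float
    eke_bandwidth_cm1: float = 250.0

    def __post_init__(self) -> None:
        cat = tuple(float(e) for e in self.cation_levels_cm1)
        if any(e < 0 for e in cat):
            raise ValueError("cation level energies must be >= 0")
        fc = np.asarray(self.fc, dtype=float)
        if fc.ndim != 2 or fc.shape[1] != len(cat):
            raise ValueError("FC matrix shape must be (n_levels, n_cation_levels)")
        if np.any(fc < 0):
            raise ValueError("FC factors must be non-negative")
        rows = fc.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("FC matrix rows must sum to 1 (row-stochastic)")
        if not (self.eke_bandwidth_cm1 > 0):
            raise ValueError("eKE bandwidth must be positive")
        object.__setattr__(self, "cation_levels_cm1", cat)
        object.__setattr__(self, "fc", fc)

    def channel_eke(self, e_s1_cm1: float, q: int) -> float:
        """Energy-conserving eKE of the (level, cation-level) channel."""
        return self.eke_offset_cm1 + e_s1_cm1 - self.cation_levels_cm1[q]

    # ---- canonical constructions -----------------------------------------

    @classmethod
    def single_channel(
        cls, n_levels: int, eke_offset_cm1: float, eke_bandwidth_cm1: float = 250.0
    ) -> "IonizationModel":
        """Every level projects onto the single cation origin (maximal interference)."""
        return cls(
            cation_levels_cm1=(0.0,),
            fc=np.ones((n_levels, 1)),
            eke_offset_cm1=eke_offset_cm1,
            eke_bandwidth_cm1=eke_bandwidth_cm1,
        )

    @classmethod
    def diagonal(
        cls,
        s1_energies_cm1: Sequence[float],
        eke_offset_cm1: float,
        eke_bandwidth_cm1: float = 250.0,
    ) -> "IonizationModel":
        """Each level ionises into its own distinct cation level: no shared
        final state, hence no beats anywhere (the null control)."""
        n = len(s1_energies_cm1)
        return cls(
            cation_levels_cm1=tuple(float(e) for e in s1_energies_cm1),
            fc=np.eye(n),
            eke_offset_cm1=eke_offset_cm1,
            eke_bandwidth_cm1=eke_bandwidth_cm1,
        )

    @classmethod
    def delta_v_ladder(
        cls,
        s1_energies_cm1: Sequence[float],
        mode_cm1: float = 179.0,
        leak: float = 0.2,
        eke_offset_cm1: float = 2000.0,
        eke_bandwidth_cm1: float = 250.0,
    ) -> "IonizationModel":
        """Quantum-number-preserving ionisation in one progression mode.

        Level ``n`` with ``v_n = round(E_n / mode_cm1)`` quanta keeps its
        excitation upon ionisation (weight ``1 - leak`` into cation level
        ``v_n`` of a ``mode_cm1``-spaced ladder) with probability ``leak``
        of collapsing to the cation origin — the common final state through
        which all levels can interfere.
        """
        if not (0.0 <= leak <= 1.0):
            raise ValueError("leak must be in [0, 1]")
        e = [float(x) for x in s1_energies_cm1]
        v = [int(round(x / mode_cm1)) for x in e]
        n_cat = max(v) + 1
        fc = np.zeros((len(e), n_cat))
        for n, vn in enumerate(v):
            if vn == 0:
                fc[n, 0] = 1.0
            else:
                fc[n, vn] += 1.0 - leak
                fc[n, 0] += leak
        return cls(
            cation_levels_cm1=tuple(mode_cm1 * q for q in range(n_cat)),
            fc=fc,
            eke_offset_cm1=eke_offset_cm1,
            eke_bandwidth_cm1=eke_bandwidth_cm1,
        )


def _default_t() -> np.ndarray:
    return np.arange(0.0, 12.5 + 2.5e-3, 5e-3)


def _default_eke() -> np.ndarray:
    return np.arange(0.0, 3000.0 + 12.5, 25.0)


@dataclass
class SyntheticSpec:
    """Complete recipe for one synthetic TR-PES measurement.

    ``beat_damp_ps`` sets the IVR dampening of the interference terms:
    ``None`` (undamped), a global lifetime in ps, or a dict mapping level
    pairs ``(E_low, E_high)`` (cm^-1, rounded to 0.1) to lifetimes with an
    optional ``"default"`` key.
    """

    spectrum: StickSpectrum
    pump: PumpPulse
    ionization: IonizationModel
    decay_lifetime_ps: float = 1200.0
    beat_damp_ps: float | dict | None = None
    irf_fwhm_ps: float = 0.1
    t_ps: np.ndarray = field(default_factory=_default_t)
    eke_cm1: np.ndarray = field(default_factory=_default_eke)
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    rng_seed: int = 0
    amplitude_weighting: str = "sqrt"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not (self.decay_lifetime_ps > 0):
            raise ValueError("decay lifetime must be positive")
        self.t_ps = np.asarray(self.t_ps, dtype=float)
        self.eke_cm1 = np.asarray(self.eke_cm1, dtype=float)

    def pair_damp_ps(self, e_lo: float, e_hi: float) -> float:
        """Dampening lifetime for the (e_lo, e_hi) interference term."""
        if self.beat_damp_ps is None:
            return math.inf
        if isinstance(self.beat_damp_ps, dict):
            key = (round(min(e_lo, e_hi), 1), round(max(e_lo, e_hi), 1))
            if key in self.beat_damp_ps:
                return float(self.beat_damp_ps[key])
            return float(self.beat_damp_ps.get("default", math.inf))
        return float(self.beat_damp_ps)

    def describe(self) -> dict:
        """Parameter record for manifests and provenance headers."""
        return {
            "origin_cm1": float(self.spectrum.origin_cm1),
            "levels": [
                {
                    "energy_cm1": float(lv.energy_cm1),
                    "intensity": float(lv.intensity),
                    "mode_label": lv.mode_label,
                    "phase_rad": float(lv.phase_rad),
                }
                for lv in self.spectrum.levels
            ],
            "pump_center_cm1": float(self.pump.center_cm1),
            "pump_fwhm_cm1": float(self.pump.fwhm_cm1),
            "cation_levels_cm1": list(self.ionization.cation_levels_cm1),
            "fc": self.ionization.fc.tolist(),
            "eke_offset_cm1": float(self.ionization.eke_offset_cm1),
            "eke_bandwidth_cm1": float(self.ionization.eke_bandwidth_cm1),
            "decay_lifetime_ps": float(self.decay_lifetime_ps),
            "beat_damp_ps": (
                self.beat_damp_ps
                if not isinstance(self.beat_damp_ps, dict)
                else {str(k): float(v) for k, v in self.beat_damp_ps.items()}
            ),
            "irf_fwhm_ps": float(self.irf_fwhm_ps),
            "t_ps": [float(self.t_ps[0]), float(self.t_ps[-1]), float(self.t_ps[1] - self.t_ps[0])],
            "eke_cm1": [
                float(self.eke_cm1[0]),
                float(self.eke_cm1[-1]),
                float(self.eke_cm1[1] - self.eke_cm1[0]),
            ],
            "noise_sigma": float(self.noise_sigma),
            "noise_model": self.noise_model,
            "rng_seed": int(self.rng_seed),
            "amplitude_weighting": self.amplitude_weighting,
        }


def generate_trpes(spec: SyntheticSpec) -> TRPESMap:
    """Render the synthetic 2-D TR-PES map described by ``spec``.

    For each cation level ``q`` the coherent photoelectron amplitude is
    ``sum_n a_n sqrt(FC[n, q]) g(eKE - eke_nq) exp(-i theta_n(t))`` with
    ``g`` the amplitude eKE envelope of the channel and
    ``theta_n = 2 pi c E_n t + phi_n``; its modulus squared (with per-pair
    IVR damping of the cross terms) is summed incoherently over ``q``,
    multiplied by the step-gated electronic decay, blurred by the IRF in
    time, and Gaussian noise is added.
    """
    wp = build_wavepacket(
        spec.spectrum, spec.pump, amplitude_weighting=spec.amplitude_weighting
    )
    ion = spec.ionization
    # map wavepacket levels (possibly a subset after the population floor)
    # back onto spectrum rows of the FC matrix
    spec_e = spec.spectrum.energies_cm1
    rows = [int(np.argmin(np.abs(spec_e - e))) for e in wp.energies_cm1]
    if ion.fc.shape[0] != spec_e.size:
        raise ValueError(
            f"FC matrix has {ion.fc.shape[0]} rows but the stick spectrum has "
            f"{spec_e.size} levels"
        )
    fc = ion.fc[rows]

    t_out = spec.t_ps
    # pad the grid below its start so the IRF convolution sees the true
    # step-function onset instead of a reflected edge
    if spec.irf_fwhm_ps > 0.0:
        dt = float(t_out[1] - t_out[0])
        if dt >= spec.irf_fwhm_ps / 3.0:
            raise ValueError(
                f"delay step {dt} ps too coarse for IRF FWHM {spec.irf_fwhm_ps} ps"
            )
        n_pad = int(math.ceil(5.0 * spec.irf_fwhm_ps / dt))
        t = np.concatenate([t_out[0] + dt * np.arange(-n_pad, 0), t_out])
    else:
        n_pad = 0
        t = t_out
    eke = spec.eke_cm1
    n_lvl = len(wp)
    e_n, a_n, phi_n = wp.energies_cm1, wp.amplitudes, wp.phases_rad

    # amplitude eKE envelope: square has FWHM = eke_bandwidth_cm1
    bw = ion.eke_bandwidth_cm1

    def g_amp(center: float) -> np.ndarray:
        x = (eke - center) / bw
        return np.exp(-0.5 * _LN16 * x * x)

    core = np.zeros((t.size, eke.size))
    tpos = np.clip(t, 0.0, None)
    for q in range(len(ion.cation_levels_cm1)):
        c = a_n * np.sqrt(fc[:, q])
        active = np.nonzero(c > 0.0)[0]
        if active.size == 0:
            continue
        g = {int(n): g_amp(ion.channel_eke(e_n[n], q)) for n in active}
        # diagonal (population) terms: time-independent before decay
        diag = np.zeros(eke.size)
        for n in active:
            diag += (c[n] * c[n]) * g[n] ** 2
        core += diag[None, :]
        # cross (beat) terms with per-pair IVR damping
        for ii, n in enumerate(active):
            for m in active[ii + 1 :]:
                gap = e_n[m] - e_n[n]
                tau = spec.pair_damp_ps(e_n[n], e_n[m])
                envelope = (
                    np.exp(-tpos / tau) if math.isfinite(tau) else 1.0
                )
                timefac = (
                    2.0
                    * c[n]
                    * c[m]
                    * np.cos(2.0 * math.pi * C_CM_PS * gap * t + (phi_n[m] - phi_n[n]))
                    * envelope
                )
                core += np.outer(timefac, g[n] * g[m])

    if spec.irf_fwhm_ps > 0.0:
        dt = float(t[1] - t[0])
        # area-weighted step: the sample cell containing t=0 contributes
        # its covered fraction, avoiding a half-sample onset bias
        gate = np.clip(t / dt + 0.5, 0.0, 1.0)
    else:
        gate = (t >= 0.0).astype(float)
    core *= (gate * np.exp(-tpos / spec.decay_lifetime_ps))[:, None]

    if spec.irf_fwhm_ps > 0.0:
        core = gaussian_smooth(core, dt, spec.irf_fwhm_ps, axis=0)
    if n_pad:
        core = core[n_pad:]
        t = t_out

    intensity = core
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.rng_seed)
        peak = float(np.max(np.abs(core))) or 1.0
        if spec.noise_model == "gaussian":
            intensity = core + spec.noise_sigma * peak * rng.standard_normal(core.shape)
        else:  # Poisson-like: sigma proportional to sqrt(local intensity)
            local = np.sqrt(np.clip(core, 0.0, None) / peak)
            intensity = core + spec.noise_sigma * peak * local * rng.standard_normal(
                core.shape
            )

    return TRPESMap(t_ps=t, eke_cm1=eke, intensity=intensity, meta=spec.describe())


# --------------------------------------------------------------------------
# stick-spectrum generator


def generate_lif_spectrum(
    progressions: Sequence[tuple[float, int, float]],
    satellites: Sequence[tuple[float, float, str]] = (),
    *,
    combinations: bool = True,
    intensity_jitter: float = 0.0,
    rng_seed: int | None = None,
    origin_cm1: float = 28851.0,
) -> StickSpectrum:
    """Build a vibronic stick spectrum from harmonic progressions.

    Each progression ``(freq_cm1, max_v, decay_ratio)`` contributes levels
    at ``v * freq`` with intensities ``decay_ratio ** v`` relative to the
    origin; with ``combinations=True`` every cross product of quanta is
    included with multiplicative intensities.  ``satellites`` are extra
    sticks ``(energy_cm1, intensity, label)`` for unassigned bands.
    ``intensity_jitter`` applies seeded multiplicative Gaussian scatter.
    """
    import itertools

    for f, vmax, ratio in progressions:
        if f <= 0:
            raise ValueError("progression frequencies must be positive")
        if vmax < 0 or ratio <= 0:
            raise ValueError("progression max_v must be >= 0 and ratio > 0")

    levels: list[VibronicLevel] = []
    ranges = [range(vmax + 1) for _, vmax, _ in progressions]
    for quanta in itertools.product(*ranges):
        if not combinations and sum(1 for v in quanta if v > 0) > 1:
            continue
        energy = sum(v * f for v, (f, _, _) in zip(quanta, progressions))
        inten = math.prod(
            ratio**v for v, (_, _, ratio) in zip(quanta, progressions)
        )
        parts = [
            f"{int(round(f))}({v})"
            for v, (f, _, _) in zip(quanta, progressions)
            if v > 0
        ]
        label = "+".join(parts) if parts else "origin"
        levels.append(VibronicLevel(energy, inten, label))
    for energy, inten, label in satellites:
        levels.append(VibronicLevel(float(energy), float(inten), label))

    if intensity_jitter > 0.0:
        rng = np.random.default_rng(rng_seed)
        levels = [
            VibronicLevel(
                lv.energy_cm1,
                max(lv.intensity * (1.0 + intensity_jitter * rng.standard_normal()), 0.0),
                lv.mode_label,
                lv.phase_rad,
            )
            for lv in levels
        ]
    return StickSpectrum(levels=tuple(levels), origin_cm1=origin_cm1)


def ma_lif_default() -> StickSpectrum:
    """Approximate methyl-anthranilate-like excitation spectrum.

    Two progressions (179 and 421 cm^-1) with combination bands plus the
    prominent unassigned satellite at 366 cm^-1.  The level list is a
    best-effort reconstruction from the dominant reported band positions
    (0, 179, 358, 366, 421, 537, ~600 cm^-1); it is approximate — the
    quantitative line list of the measured spectrum is an external input.
    """
    return generate_lif_spectrum(
        progressions=[(179.0, 3, 0.6), (421.0, 1, 0.35)],
        satellites=[(366.0, 0.25, "sat366")],
        combinations=True,
    )


# --------------------------------------------------------------------------
# fixture scenarios

SCENARIO_NAMES = ("348like", "344like", "330like", "330like_mena", "beatfree")


def scenario(name: str, seed: int = 0) -> SyntheticSpec:
    """Canonical synthetic measurement scenarios.

    ``348like``
        Pump red of the origin (348 nm analogue) populating the low levels
        of the 179 cm^-1 progression; undamped beats.
    ``344like``
        Pump ~220 cm^-1 above the origin (344 nm analogue) spanning both
        progressions; undamped — dephasing/rephasing comes entirely from
        the level structure.
    ``330like`` / ``330like_mena``
        Pump high in the level structure with rapid IVR dampening of every
        beat (1.4 ps / 1.0 ps analogues of the two molecules).  Only the
        three dominant upper sticks (358, 421, 537 cm^-1) are kept so each
        beat band is a single gap (63, 116, 179 cm^-1) and the fitted
        dampening lifetime is cleanly defined.
    ``beatfree``
        Diagonal ionisation control: no shared final state, no beats.
    """
    sticks = ma_lif_default()
    origin = sticks.origin_cm1
    e = sticks.energies_cm1
    ladder = lambda: IonizationModel.delta_v_ladder(  # noqa: E731
        e, mode_cm1=179.0, leak=0.2, eke_offset_cm1=2000.0, eke_bandwidth_cm1=250.0
    )
    t_10 = np.arange(0.0, 10.0 + 5e-3, 1e-2)
    t_125 = np.arange(0.0, 12.5 + 5e-3, 1e-2)
    eke = np.arange(0.0, 3000.0 + 25.0, 50.0)
    common = dict(
        decay_lifetime_ps=1200.0,
        irf_fwhm_ps=0.1,
        eke_cm1=eke,
        noise_sigma=0.01,
        rng_seed=seed,
    )
    if name == "348like":
        return SyntheticSpec(
            spectrum=sticks,
            pump=PumpPulse.from_wavelength(348.0, origin, 500.0),
            ionization=ladder(),
            beat_damp_ps=None,
            t_ps=t_10,
            **common,
        )
    if name == "344like":
        return SyntheticSpec(
            spectrum=sticks,
            pump=PumpPulse.from_wavelength(344.0, origin, 500.0),
            ionization=ladder(),
            beat_damp_ps=None,
            t_ps=t_125,
            **common,
        )
    if name in ("330like", "330like_mena"):
        upper = StickSpectrum.from_arrays(
            [358.0, 421.0, 537.0],
            [0.36, 0.35, 0.216],
            origin_cm1=origin,
            mode_labels=["179(2)", "421(1)", "179(3)"],
        )
        return SyntheticSpec(
            spectrum=upper,
            pump=PumpPulse(center_cm1=450.0, fwhm_cm1=500.0),
            ionization=IonizationModel.delta_v_ladder(
                upper.energies_cm1,
                mode_cm1=179.0,
                leak=0.2,
                eke_offset_cm1=2000.0,
                eke_bandwidth_cm1=250.0,
            ),
            beat_damp_ps=1.4 if name == "330like" else 1.0,
            t_ps=t_10,
            **common,
        )
    if name == "beatfree":
        return SyntheticSpec(
            spectrum=sticks,
            pump=PumpPulse.from_wavelength(348.0, origin, 500.0),
            ionization=IonizationModel.diagonal(e, eke_offset_cm1=2000.0),
            beat_damp_ps=None,
            t_ps=t_10,
            **common,
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the canonical fixture files for every scenario.

    For each scenario this writes the 2-D map (long-format text), the
    eKE-integrated 1-D transient, and the stick spectrum, plus a single
    manifest recording every generator parameter and seed.  Output is
    byte-reproducible for a fixed seed.  Returns the manifest dict.
    """
    from . import io as bio  # deferred: io imports containers from here

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "scenarios": {}}
    for i, name in enumerate(SCENARIO_NAMES):
        spec = scenario(name, seed=seed + i)
        map_ = generate_trpes(spec)
        tr = map_.integrate_eke()
        files = {
            "trpes": f"{name}_trpes.csv",
            "transient": f"{name}_transient.csv",
            "sticks": f"{name}_sticks.csv",
        }
        bio.write_trpes(map_, out / files["trpes"])
        bio.write_transient(tr, out / files["transient"])
        bio.write_stick_spectrum(spec.spectrum, out / files["sticks"])
        manifest["scenarios"][name] = {"files": files, "params": spec.describe()}
    bio.save_config(manifest, out / "manifest.yaml")
    return manifest
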
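"""Synthetic stick spectra and TR-PES maps: structure, determinism, oracles."""

import hashlib

import numpy as np
import pytest

from beatmap import (
    C_CM_PS,
    IonizationModel,
    PumpPulse,
    StickSpectrum,
    SyntheticSpec,
    Transient,
    build_wavepacket,
    fft_spectrum,
    fft_vs_eke,
    find_beat_peaks,
    generate_lif_spectrum,
    generate_trpes,
    isolate_beats,
    ma_lif_default,
    make_fixture_suite,
    scenario,
    survival_probability,
)
from beatmap.dynamics import gaussian_smooth


class TestGenerateLIFSpectrum:
    def test_single_progression_geometric_intensities(self):
        sp = generate_lif_spectrum([(179.0, 3, 0.7)])
        assert list(sp.energies_cm1) == [0.0, 179.0, 358.0, 537.0]
        assert sp.intensities == pytest.approx([1.0, 0.7, 0.49, 0.343])

    def test_combination_band_present(self):
        sp = generate_lif_spectrum([(179.0, 1, 0.7), (421.0, 1, 0.4)])
        assert 600.0 in sp.energies_cm1
        idx = list(sp.energies_cm1).index(600.0)
        assert sp.intensities[idx] == pytest.approx(0.7 * 0.4)
        assert sp.levels[idx].mode_label == "179(1)+421(1)"

    def test_no_combinations_flag(self):
        sp = generate_lif_spectrum(
            [(179.0, 1, 0.7), (421.0, 1, 0.4)], combinations=False
        )
        assert 600.0 not in sp.energies_cm1

    def test_ma_default_contains_assigned_beat_gaps(self):
        """The observed beat frequencies (55, 63, 116, 179 cm^-1) all occur
        among the pairwise level differences of the default spectrum."""
        sp = ma_lif_default()
        e = sp.energies_cm1
        gaps = np.abs(e[:, None] - e[None, :])[np.triu_indices(e.size, 1)]
        for gap in (55.0, 63.0, 116.0, 179.0):
            assert np.min(np.abs(gaps - gap)) < 0.5, gap

    def test_intensity_jitter_is_seeded(self):
        a = generate_lif_spectrum([(179.0, 3, 0.7)], intensity_jitter=0.1, rng_seed=1)
        b = generate_lif_spectrum([(179.0, 3, 0.7)], intensity_jitter=0.1, rng_seed=1)
        c = generate_lif_spectrum([(179.0, 3, 0.7)], intensity_jitter=0.1, rng_seed=2)
        assert a.intensities == pytest.approx(b.intensities)
        assert not np.allclose(a.intensities, c.intensities)


class TestIonizationModel:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            IonizationModel((0.0,), np.array([[0.5]]), 2000.0)

    def test_energy_bookkeeping_constant_offset(self):
        """eKE + cation internal energy - excited level energy is the same
        constant for every ionisation channel (energy conservation)."""
        ion = IonizationModel.delta_v_ladder([0.0, 179.0, 358.0, 421.0])
        for n, e_s1 in enumerate([0.0, 179.0, 358.0, 421.0]):
            for q in range(len(ion.cation_levels_cm1)):
                eke = ion.channel_eke(e_s1, q)
                assert eke + ion.cation_levels_cm1[q] - e_s1 == pytest.approx(
                    ion.eke_offset_cm1
                )

    def test_delta_v_ladder_leak_shares_cation_origin(self):
        ion = IonizationModel.delta_v_ladder([0.0, 179.0, 358.0], leak=0.2)
        fc = ion.fc
        assert fc[0] == pytest.approx([1.0, 0.0, 0.0])
        assert fc[1] == pytest.approx([0.2, 0.8, 0.0])
        assert fc[2] == pytest.approx([0.2, 0.0, 0.8])


def _noiseless_spec(ionization, levels=(0.0, 179.0, 358.0), irf=0.0, **kw):
    sticks = StickSpectrum.from_arrays(levels, [1.0] * len(levels), 28851.0)
    defaults = dict(
        spectrum=sticks,
        pump=PumpPulse(100.0, 1e9),
        ionization=ionization,
        decay_lifetime_ps=5.0,
        beat_damp_ps=None,
        irf_fwhm_ps=irf,
        t_ps=np.arange(0.0, 5.0 + 5e-3, 1e-2),
        eke_cm1=np.arange(0.0, 3000.0 + 25.0, 25.0),
        noise_sigma=0.0,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


class TestGenerateTRPES:
    def test_diagonal_fc_produces_no_beats(self):
        """Interference requires a common final state: with one distinct
        cation level per excited level the map is beat-free everywhere."""
        ion = IonizationModel.diagonal([0.0, 179.0, 358.0], eke_offset_cm1=2000.0)
        m = generate_trpes(_noiseless_spec(ion))
        tr = m.integrate_eke()
        spec = fft_spectrum(isolate_beats(tr, "exponential"))
        sel = spec.freq_cm1 > 3 * spec.resolution_cm1
        assert np.max(spec.magnitude[sel]) < 1e-6

    def test_single_final_state_beats_at_every_gap(self):
        """All levels projecting onto the cation origin beat at every
        pairwise gap, and only around the high-eKE channel cluster."""
        ion = IonizationModel.single_channel(3, eke_offset_cm1=2000.0)
        m = generate_trpes(_noiseless_spec(ion))
        tr = m.integrate_eke()
        spec = fft_spectrum(isolate_beats(tr, "exponential"))
        freqs = sorted(f for f, _ in find_beat_peaks(spec, prominence_frac=0.05))
        assert freqs == pytest.approx([179.0, 358.0], abs=spec.resolution_cm1)
        # beats live where the channel envelopes sit (2000-2400 cm^-1),
        # not at low eKE
        fe = fft_vs_eke(m, None, eke_bin_cm1=None, intensity_floor_frac=0.0)
        i179 = np.argmin(np.abs(fe.freq_cm1 - 179.0))
        lo = fe.eke_cm1 < 1000.0
        hi = (fe.eke_cm1 > 1900.0) & (fe.eke_cm1 < 2500.0)
        assert np.max(fe.magnitude[lo, i179]) < 1e-3 * np.max(
            fe.magnitude[hi, i179]
        )

    def test_ma_like_179_beat_at_multiple_eke_features(self):
        """Quantum-number preservation plus leakage puts the 179 cm^-1 beat
        at more than one photoelectron feature."""
        spec = scenario("348like", seed=1)
        fe = fft_vs_eke(generate_trpes(spec), "exponential")
        i179 = np.argmin(np.abs(fe.freq_cm1 - 179.0))
        active = (fe.magnitude[:, i179] > 0.03) & fe.mask
        assert active.sum() >= 2

    def test_integrated_map_equals_correlator_times_decay(self):
        """With a single common final state, a broadband pump (equal
        amplitudes) and no damping or noise, the eKE-integrated map is the
        survival probability times the decay envelope to 1e-6."""
        ion = IonizationModel.single_channel(
            3, eke_offset_cm1=1500.0, eke_bandwidth_cm1=1e8
        )
        spec = _noiseless_spec(ion)
        tr = generate_trpes(spec).integrate_eke()
        wp = build_wavepacket(spec.spectrum, spec.pump)
        oracle = survival_probability(wp, spec.t_ps).y * np.exp(-spec.t_ps / 5.0)
        assert np.max(np.abs(tr.y / tr.y[0] - oracle / oracle[0])) < 1e-6

    def test_integrated_map_equals_smoothed_correlator_with_irf(self):
        """The same equivalence holds with the instrument response applied
        to both routes on a padded grid."""
        ion = IonizationModel.single_channel(
            3, eke_offset_cm1=1500.0, eke_bandwidth_cm1=1e8
        )
        spec = _noiseless_spec(ion, irf=0.1)
        tr = generate_trpes(spec).integrate_eke()
        wp = build_wavepacket(spec.spectrum, spec.pump)
        dt = 1e-2
        pad = int(np.ceil(5 * 0.1 / dt))
        t_ext = np.concatenate([spec.t_ps[0] + dt * np.arange(-pad, 0), spec.t_ps])
        gate = np.clip(t_ext / dt + 0.5, 0.0, 1.0)  # same onset convention
        core = survival_probability(wp, t_ext).y * gate * np.exp(
            -np.clip(t_ext, 0, None) / 5.0
        )
        oracle = gaussian_smooth(core, dt, 0.1)[pad:]
        assert np.max(np.abs(tr.y / tr.y[0] - oracle / oracle[0])) < 1e-6

    def test_beat_damping_shortens_interference_terms_only(self):
        """Pair damping kills the oscillation but not the population
        (diagonal) signal."""
        ion = IonizationModel.single_channel(2, eke_offset_cm1=2000.0)
        spec = _noiseless_spec(ion, levels=(0.0, 179.0), beat_damp_ps=0.5)
        tr = generate_trpes(spec).integrate_eke()
        envelope = np.exp(-tr.t_ps / 5.0)
        ratio = tr.y / envelope
        early = tr.t_ps < 1.0
        late = tr.t_ps > 4.0
        # strong modulation early, none late; population signal survives
        assert np.ptp(ratio[early]) / ratio[early].mean() > 0.5
        assert np.ptp(ratio[late]) / ratio[late].mean() < 0.01
        assert tr.y[late].mean() > 0.1 * tr.y[0]

    def test_noise_reproducible_and_core_seed_independent(self):
        ion = IonizationModel.single_channel(3, eke_offset_cm1=2000.0)
        noisy1 = generate_trpes(_noiseless_spec(ion, noise_sigma=0.02, rng_seed=1))
        noisy1b = generate_trpes(_noiseless_spec(ion, noise_sigma=0.02, rng_seed=1))
        noisy2 = generate_trpes(_noiseless_spec(ion, noise_sigma=0.02, rng_seed=2))
        core1 = generate_trpes(_noiseless_spec(ion, rng_seed=1))
        core2 = generate_trpes(_noiseless_spec(ion, rng_seed=2))
        assert np.array_equal(noisy1.intensity, noisy1b.intensity)
        assert not np.array_equal(noisy1.intensity, noisy2.intensity)
        assert np.array_equal(core1.intensity, core2.intensity)

    def test_poisson_like_noise_scales_with_intensity(self):
        ion = IonizationModel.single_channel(2, eke_offset_cm1=2000.0)
        spec = _noiseless_spec(
            ion, levels=(0.0, 179.0), noise_sigma=0.05, noise_model="poisson",
            rng_seed=3,
        )
        core = generate_trpes(_noiseless_spec(ion, levels=(0.0, 179.0)))
        noisy = generate_trpes(spec)
        resid = noisy.intensity - core.intensity
        bright = core.intensity > 0.5 * core.intensity.max()
        dark = core.intensity < 0.01 * core.intensity.max()
        assert resid[bright].std() > 3.0 * resid[dark].std()


class TestFixtureSuite:
    def test_same_seed_byte_identical(self, tmp_path):
        m1 = make_fixture_suite(tmp_path / "a", seed=42)
        m2 = make_fixture_suite(tmp_path / "b", seed=42)
        assert m1 == m2
        for p in sorted((tmp_path / "a").iterdir()):
            h1 = hashlib.sha256(p.read_bytes()).hexdigest()
            h2 = hashlib.sha256((tmp_path / "b" / p.name).read_bytes()).hexdigest()
            assert h1 == h2, p.name

    def test_manifest_records_all_scenarios_and_seeds(self, tmp_path):
        from beatmap import SCENARIO_NAMES

        m = make_fixture_suite(tmp_path / "fix", seed=7)
        assert set(m["scenarios"]) == set(SCENARIO_NAMES)
        for name, entry in m["scenarios"].items():
            assert "rng_seed" in entry["params"]
            for f in entry["files"].values():
                assert (tmp_path / "fix" / f).exists()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("331like")
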
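# beatmap

Quantum-beat analysis and vibronic wavepacket simulation for time-resolved
photoelectron spectroscopy (TR-PES).

## The problem

A spectrally broad femtosecond pump pulse does not excite a molecule into a
single vibronic eigenstate: every level of the excited electronic state
under the pulse envelope is populated coherently, forming a vibrational
wavepacket

```
|Psi(dt)> = sum_n a_n |psi_n> exp(-i 2 pi c E_n dt)
```

with level energies `E_n` in cm⁻¹ and `c` the speed of light in cm/ps.
When a probe pulse ionises this wavepacket, eigenstates `n` and `m` that
reach the *same* cation final state interfere, modulating the photoelectron
signal at the gap frequency `|E_n − E_m|` — quantum beats.  Watching where
(in electron kinetic energy, eKE) and how long (dampening, revivals) these
beats live reveals Franck–Condon structure and intramolecular vibrational
energy redistribution (IVR) on the excited state.  The motivating system is
methyl anthranilate (MA), the precursor of the sunscreen filter Meradimate,
whose S₁ state carries prominent 179 cm⁻¹ (ester in-plane bend) and
421 cm⁻¹ progressions above the origin at 28 851 cm⁻¹; IVR among these
levels is what traps its excited-state population and makes it a poor
photoprotector.

The package provides, as composable library modules plus a CLI:

* **`vibronic`** — stick spectra, pump envelopes, wavepacket construction
  (`a_n² ∝ I_n g(E_n)` with `g` the Gaussian pump intensity profile);
* **`dynamics`** — the phase-augmented survival probability
  `P(dt) = |Σ_n a_n² exp(−i(2π c E_n dt + φ_n))|²` with per-mode phase
  offsets and Gaussian instrument-response smoothing;
* **`beats`** — decay isolation, tapered/zero-padded FFT spectra,
  column-wise FFT(eKE) maps, sliding-window FFT(Δt) spectrograms, peak and
  revival detection;
* **`fitting`** — IRF-convolved kinetic models with multiplicative damped
  sinusoids, FFT-seeded, with shared "overall beat dampening lifetime" and
  standard errors from the fit covariance;
* **`states`** — Beyer–Swinehart direct counting of harmonic vibrational
  states and windowed densities of states;
* **`synthetic`** — a TR-PES generator that realises the common-final-state
  interference mechanism (Franck–Condon projection matrix, energy-conserving
  eKE channels, per-pair IVR damping, seeded noise), so the whole pipeline
  is testable end to end without any measured data.

## Worked example

Excite the v = 0, 1, 2 levels of the 179 cm⁻¹ progression with a 500 cm⁻¹
FWHM pump centred 100 cm⁻¹ above the origin, propagate, blur with a 0.1 ps
instrument response, and read off the beats:

```python
import numpy as np
import beatmap as bm

sticks = bm.StickSpectrum.from_arrays(
    [0.0, 179.0, 358.0], [1.0, 1.0, 1.0], origin_cm1=28851.0
)
wp = bm.build_wavepacket(sticks, bm.PumpPulse(center_cm1=100.0, fwhm_cm1=500.0))
print("level populations:", np.round(wp.populations, 3))

t = np.arange(0.0, 7.5, 0.005)                      # ps
tr = bm.smooth_with_irf(bm.survival_probability(wp, t), 0.1)
spec = bm.fft_spectrum(tr)
print(f"FFT resolution: {spec.resolution_cm1:.1f} cm^-1")
for f, m in bm.find_beat_peaks(spec, prominence_frac=0.01):
    print(f"beat at {f:6.1f} cm^-1   magnitude {m:.3f}")
```

prints

```
level populations: [0.388 0.405 0.207]
FFT resolution: 4.5 cm^-1
beat at  179.0 cm^-1   magnitude 0.173
beat at  168.5 cm^-1   magnitude 0.005
beat at  189.5 cm^-1   magnitude 0.005
beat at  358.0 cm^-1   magnitude 0.003
```

The pump populates the three levels 0.39 : 0.40 : 0.21, and the survival
probability beats dominantly at the one-quantum gap of 179 cm⁻¹ (the two
small satellites are Hann-window sidelobes).  The two-quantum beat at
358 cm⁻¹ is almost gone: the 0.1 ps instrument response attenuates a
cosine at ν̃ by `exp(−(π c ν̃)² w² / (4 ln 2))`, which is the reason
measured transients show no beats much above ~250 cm⁻¹.

The same stages run from the shell:

```sh
beatmap synth --scenario 330like --out fixtures --seed 1
beatmap analyze --config analyze.yaml --out results
beatmap fit --config fit.yaml --out results --seed 1
beatmap dos --modes s1_modes.txt --at 1400 --window 100
```

## Scope notes

Electronic-structure calculations are out of scope: harmonic frequencies
and stick intensities are *inputs*.  The shipped MA-like line list and S₁
frequency list are labelled approximations/synthetic surrogates for
development and testing — substitute measured or computed lists for
quantitative work.  See `docs/methods.md` for the model assumptions,
parameter defaults and known limitations.
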
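# Methods

This note records the model, the numerical conventions, and the design
choices behind `beatmap`, in enough detail to reproduce or challenge any
number the package computes.

## Units and constants

Energies are wavenumbers (cm⁻¹), times picoseconds, wavelengths vacuum
nanometres.  The only physical constant is the speed of light,
`c = 2.99792458 × 10⁻² cm/ps`; a level gap ΔE beats with period
`1/(c ΔE)` (179 cm⁻¹ → 0.1864 ps) and an FFT frequency axis in cycles/ps
divides by `c` to give cm⁻¹.  Photon energies convert as `10⁷/λ[nm]`,
reported relative to the electronic origin unless flagged absolute.

## Wavepacket preparation

A stick spectrum (energy, relative excitation intensity, optional mode
label, optional initial phase) describes the excited-state level
structure.  Sticks closer than 0.5 cm⁻¹ merge (summed intensity,
intensity-weighted energy) — hygiene for digitised spectra.

The pump pulse is characterised by its measured spectral *intensity*
profile: a unit-peak Gaussian `g(E)` of given FWHM (default 500 cm⁻¹,
typical of a ~40 fs UV pulse).  Amplitudes are

    a_n ∝ sqrt(I_n) · sqrt(g(E_n)),   i.e.   a_n² ∝ I_n · g(E_n),

so populations follow the stick intensities weighted by the pump intensity
envelope.  The square root on `I_n` reflects that excitation intensities
scale as squared transition moments while the wavepacket coefficient
carries the moment itself; the square root on `g` is the field envelope of
the intensity profile.  A `linear` weighting switch exists for sensitivity
checks.  Amplitudes are normalised to `Σ a_n² = 1`; levels below a
population floor (default 10⁻⁶) are dropped and the rest renormalised.  A
pump that overlaps nothing raises rather than returning an empty packet.

## Survival probability and per-mode phases

The observable is the phase-augmented time-autocorrelation

    C(dt) = Σ_n a_n² exp(−i (2π c E_n dt + φ_n)),    P(dt) = |C(dt)|².

The textbook autocorrelation (all φ_n = 0) is insensitive to phases; the
augmented form shifts individual beat components in time, which is how a
vibrational-mode-dependent ionisation window appears in measured
transients.  Adding π/2 to the levels of one progression (matched through
the mode labels, combinations included) delays the beats that involve
those levels by a quarter period without touching the others — this is an
interpretation layer, exposed as `apply_mode_phase`, not a claim about the
exact supplementary formulation used elsewhere.  Properties guaranteed and
tested: P(0) = 1 at zero phases, 0 ≤ P ≤ 1, evenness in dt, invariance
under a global phase, and full revival with period `1/(c g)` when all gaps
are multiples of g.

FFT peaks of P sit exactly at the pairwise gaps `|E_n − E_m|` with
amplitude `2 a_n² a_m²` per gap; the test suite checks this against a
brute-force pair enumeration.

## Instrument response

Finite pump/probe durations are modelled as convolution with a unit-area
Gaussian of FWHM `w` (default 0.10 ps; the cross-correlation of two
~40 fs pulses stretched by dispersion is of this order).  A cosine at ν̃
is attenuated by `exp(−(π c ν̃)² w² / (4 ln 2))` with phase preserved —
at w = 0.1 ps this passes 64% of a 180 cm⁻¹ beat but only 1.7% of a
358 cm⁻¹ beat, which is why fast beats vanish from measured transients.
The discrete filter uses a reflected-edge Gaussian (`truncate = 8`);
`w = 0` is a bit-identical no-op, and a grid coarser than w/3 is rejected.

## Beat extraction

**Decay isolation.**  The slowly varying population signal is fitted with
a constant, an IRF-blurred single exponential, or a bi-exponential
(`auto` fits both exponential forms and keeps the lower corrected AIC).
The blurred exponential is evaluated analytically as
`½ erfcx(z) exp(−t²/2σ²)`, switching to the pure-exponential branch where
`erfcx` would overflow.  Ratio mode (default) returns `y/baseline − 1`,
the beats as fractional modulation; subtract mode returns `y − baseline`.
A baseline touching zero makes the ratio undefined and raises.

**FFT spectra.**  Records are restricted to dt > 0 (beats only exist at
positive delays), the taper-weighted mean is removed (exact DC
suppression), a Hann taper applied, and the transform zero-padded 8×
for peak interpolation.  Magnitude is normalised so a unit cosine filling
the record gives a unit peak; the nominal resolution is `1/(c T)` for
record length T (4.4 cm⁻¹ at 7.5 ps).  Peaks are refined by three-point
parabolic interpolation and reported above a prominence threshold, DC
excluded.  Note that a Hann mainlobe spans ~4 resolution elements: two
gaps must be separated by about `4/(c T)` to appear as two peaks.

**FFT(eKE).**  eKE columns are binned to ≥ 50 cm⁻¹, isolated and
transformed independently.  Columns below 5% of the map's peak intensity
are masked as "no information" rather than zero-filled; a column whose
ratio-mode baseline is undefined falls back to subtract mode.

**FFT(Δt).**  A Gaussian window (FWHM 2.5 ps, step 0.1 ps by default —
resolving ~13 cm⁻¹ while localising few-ps dampening) slides across the
record; each window is mean-removed, transformed, and normalised like the
static FFT, so a stationary tone gives a flat band ("global" mode).
"per-window-max" rescaling emphasises weak late-time structure.  Revivals
are local maxima of a band-integrated magnitude trace occurring after its
first local minimum, at a prominence threshold; monotone bands yield none.

## Kinetic fitting

The fit model is

    S(t) = G(t; w) ⊛ [ H(t) (Σ_j A_j e^(−t/τ_j))
                       (1 + Σ_k B_k e^(−t/τ_k^d) cos(2π c ν̃_k t + φ_k)) ] + y₀.

Beats modulate the decay multiplicatively (an oscillating fraction of the
excited-state ionisation signal); an additive variant is available.  All
beats share one dampening lifetime by default — the "overall beat decay
lifetime" that quantifies IVR — with per-beat lifetimes optional.
Convolution is numerical: the step-gated signal is built on an oversampled
grid (≤ min(dt, σ/4, beat period/20)) padded by 5 IRF widths, filtered,
and interpolated back.  The sample cell containing t = 0 carries its
fractional area (an area-weighted step) — without this the discrete
convolution acquires a half-sample onset bias of a few percent.

Frequencies are seeded from FFT peaks of the envelope-normalised signal
(the standard cross-check between the Fourier and kinetic analyses) and
bounded within ±max(8%, 5 cm⁻¹) of their seeds during optimisation: the
least-squares landscape of a sum of sinusoids is riddled with distant
local minima, and the FFT already localises each frequency.  Candidate
beats must modulate the signal by ≥ 0.5% to be seeded.  Optimisation is
trust-region least squares (lmfit) with a numerical Jacobian; an optional
multistart (default 8 in the CLI) perturbs seeds by 20% with a recorded
RNG seed.  Standard errors come from the scaled covariance at the
optimum; non-convergence is reported in the result flag, never masked.
On 50 synthetic replicates at 1–5% noise the median frequency error is
well under the FFT resolution, the median dampening-lifetime error under
20%, and the ±1 SE interval covers the truth for roughly two thirds of
replicates — consistent with a mildly misspecification-free error model.

## State counting

Beyer–Swinehart direct counting on a 1 cm⁻¹ grid (default): `counts[0] = 1`,
then each harmonic mode of frequency ν folds in place,
`counts[i] += counts[i − round(ν/bin)]`.  This enumerates every
quantum-number combination exactly (verified against brute force).  A
frequency below one bin is rejected as a binning artifact.  The density of
states is a windowed average of the binned counts (default window
100 cm⁻¹), truncated with a warning at the range edges.  No anharmonicity;
degeneracy by listing a frequency twice.

The shipped `example_modes` list is a **synthetic surrogate** for an
MA-like molecule (54 modes from group-frequency reasoning, containing the
two observed LIF-active modes); it gives ~4 × 10² states/cm⁻¹ at
1400 cm⁻¹ and ~0.16 at 200 cm⁻¹ — the right orders for the statistical
and sparse IVR regimes — but its individual values are not computed
frequencies.

## Synthetic TR-PES generator

Each excited level n ionises into cation level v⁺ with probability
FC[n, v⁺] (rows sum to 1) at the energy-conserving
`eKE = eke_offset + E_n − E(v⁺)`; each channel is Gaussian in eKE
(intensity FWHM 250 cm⁻¹ by default).  The coherent amplitude at one final
state is `Σ_n a_n √FC[n,v⁺] g_n(eKE) e^(−iθ_n)`; its modulus squared is
summed incoherently over v⁺, multiplied by the step-gated electronic
decay, blurred by the IRF on a padded grid (same onset convention as the
fit model), and seeded Gaussian (or Poisson-like) noise is added.  Cross
terms damp per level pair (global lifetime or a pair-keyed table) —
IVR empties the prepared levels, killing interference before population.

Consequences realised and tested: a diagonal FC matrix (no shared final
state) produces no beats anywhere; a single common final state beats at
every pairwise gap, localised at the high-eKE channel cluster; the default
"Δv-preserving ladder + leakage to v⁺ = 0" matrix puts the 179 cm⁻¹ beat
at several photoelectron features.  In the limit of one common final
state, a flat pump, no damping and no noise, the eKE-integrated map equals
the survival probability times the decay envelope to 10⁻⁶ (for equal
amplitudes the `a_n` vs `a_n²` weighting of the two routes coincides after
normalisation).  The FC matrices are structurally faithful but
quantitatively arbitrary — the real ionisation matrix elements of MA are
unknown here.

Scenario presets (`348like`, `344like`, `330like`, `330like_mena`,
`beatfree`) encode the studied regimes: near-origin excitation of the
179 cm⁻¹ ladder (undamped beats), excitation ~220 cm⁻¹ above the origin
spanning both progressions (dephasing/rephasing from the level structure
alone), and the IVR regime with 1.4 ps (MA-like) and 1.0 ps (MenA-like)
beat dampening.  The IVR scenarios keep only the three dominant upper
sticks (358/421/537 cm⁻¹) so each band is a single gap and the fitted
shared lifetime is cleanly defined; with the full line list each nominal
band is a cluster of near-degenerate gaps whose dephasing masquerades as
extra damping.  The overall electronic decay is 1.2 ns (effectively flat
over the 10–12.5 ps records, as for a trapped S₁ population).  Fixture
grids are 10–12.5 ps at 10 fs and 0–3000 cm⁻¹ at 50 cm⁻¹ with 1% noise;
simulation-quality grids default to 5 fs (Nyquist ≈ 3300 cm⁻¹).  The
noiseless core is seed-independent; everything else is byte-reproducible
under a fixed seed.

What the generator does **not** emulate: photoelectron angular
distributions, spectrometer lineshape asymmetries, pump-probe artifacts
around t = 0, scattered-light backgrounds, and any quantitative
Franck–Condon structure.  Green tests therefore demonstrate that the
analysis chain recovers what the interference model puts in — not that the
model captures every feature of a measured map.

## Default line list

The built-in MA-like stick spectrum is reconstructed from the prominent
reported band positions: the 179 cm⁻¹ progression (v ≤ 3, intensity ratio
0.6), the 421 cm⁻¹ mode (v ≤ 1, ratio 0.35), their combinations, and the
unassigned satellite at 366 cm⁻¹ (intensity 0.25).  Its pairwise gaps
contain the assigned beat frequencies (55, 63, 116, 179 cm⁻¹).  It is
approximate: the measured spectrum's fine structure (anharmonic shifts,
Fermi resonances, exact satellite intensities) is not shipped, and
quantities that depend on that fine structure — notably late revival
times of individual bands — shift accordingly.  With π/2 on the
ester-bend levels the phase-augmented correlator dephases its 60 and
115 cm⁻¹ bands within ~2–3 ps and revives the 60 cm⁻¹ band at ~5.2 ps
and the 180 cm⁻¹ band at ~5.8 ps; the surrogate's 110–120 cm⁻¹ band
contains a single gap and therefore cannot rephase at all.

## Numerical and interface choices

* Delimited text everywhere, full `%.17g` precision: write→read round
  trips are bit-identical; metadata rides in a `# meta: {json}` header.
* All analysis parameters echo into output headers/manifests; CLI runs
  drop a `run.yaml` (config, seed, version) and are byte-reproducible.
* Unknown config keys fail fast by name; file parse errors name the line.
* Degenerate inputs: empty wavepackets, non-uniform grids, zero-crossing
  baselines, windows longer than records, bands outside ranges and
  sub-bin frequencies all raise with specific messages rather than
  propagating NaNs.

## Known limitations

* The per-mode phase is an interpretation of how an eKE-dependent
  ionisation window enters a 1-D correlator, not a derivation from the
  ionisation dynamics; no explicit cation-surface projection is performed.
* The kinetic model's shared-dampening convention is one of the two
  defensible readings of an "overall beat decay lifetime"; per-beat
  lifetimes are available but not default.
* Beyer–Swinehart is harmonic and exact only on its grid; 1 cm⁻¹ bins
  make rounding exact for integer frequencies.
* The Zenodo-deposited measured data are not bundled; a defensive loader
  is not provided because the deposition's internal layout is not
  specified here — readers ingest the package's own text formats instead.
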
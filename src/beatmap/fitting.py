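"""Kinetic fitting of beat-modulated pump-probe transients.

The model is an instrument-response-convolved population decay modulated by
damped sinusoids:

    S(t) = G(t; irf) * [ H(t) (sum_j A_j e^(-t/tau_j))
                         (1 + sum_k B_k e^(-t/tau_k^d) cos(2 pi c nu_k t + phi_k)) ]
           + offset

with ``H`` the unit step and ``G`` a unit-area Gaussian of the given FWHM.
Beats modulate the decay multiplicatively by default (the oscillation rides
on the excited-state ionisation signal); an additive variant is available.
The beat dampening lifetime ``tau^d`` is the IVR observable: in the shared
(default) configuration every beat draws one common "overall beat decay
lifetime", whose standard error comes from the fit covariance.

Convolution is carried out numerically on an oversampled, padded grid and
interpolated back, so arbitrary modulation products are handled exactly
enough (the analytic route only exists for pure exponentials).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import lmfit

from .units import C_CM_PS, fwhm_to_sigma
from .dynamics import Transient, gaussian_smooth
from .beats import fft_spectrum, find_beat_peaks

__all__ = [
    "DecayComponent",
    "BeatComponent",
    "BeatFitModel",
    "FitResult",
    "model_eval",
    "init_from_fft",
    "fit_transient",
]


@dataclass(frozen=True)
class DecayComponent:
    amplitude: float
    lifetime_ps: float

    def __post_init__(self) -> None:
        if not (self.lifetime_ps > 0):
            raise ValueError("decay lifetime must be positive")


@dataclass(frozen=True)
class BeatComponent:
    """One damped sinusoid.

    ``damp_lifetime_ps = inf`` means undamped.  Beats sharing a ``group``
    id are constrained to a single dampening lifetime during fitting.
    """

    amplitude: float
    freq_cm1: float
    phase_rad: float = 0.0
    damp_lifetime_ps: float = math.inf
    group: str | None = "shared"

    def __post_init__(self) -> None:
        if not (self.freq_cm1 > 0):
            raise ValueError("beat frequency must be positive")
        if not (self.damp_lifetime_ps > 0):
            raise ValueError("beat dampening lifetime must be positive")


@dataclass(frozen=True)
class BeatFitModel:
    decays: tuple[DecayComponent, ...]
    beats: tuple[BeatComponent, ...] = ()
    irf_fwhm_ps: float = 0.0
    offset: float = 0.0
    modulation: str = "multiplicative"

    def __post_init__(self) -> None:
        if not self.decays:
            raise ValueError("model needs at least one decay component")
        if self.modulation not in ("multiplicative", "additive"):
            raise ValueError(f"unknown modulation {self.modulation!r}")
        if self.irf_fwhm_ps < 0:
            raise ValueError("IRF FWHM must be >= 0")
        object.__setattr__(self, "decays", tuple(self.decays))
        object.__setattr__(self, "beats", tuple(self.beats))


@dataclass
class FitResult:
    """Best-fit parameters with standard errors and goodness metrics.

    ``params`` maps parameter name to ``(value, stderr)``; ``stderr`` is
    the standard error from the scaled covariance at the optimum (NaN when
    the covariance could not be estimated).  ``success`` is the honest
    convergence flag of the underlying trust-region solver.
    """

    model: BeatFitModel
    params: dict[str, tuple[float, float]]
    redchi: float
    aicc: float
    residual: np.ndarray
    success: bool
    nfev: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def value(self, name: str) -> float:
        return self.params[name][0]

    def stderr(self, name: str) -> float:
        return self.params[name][1]


# --------------------------------------------------------------------------
# model evaluation


def _raw_signal(
    model: BeatFitModel, t: np.ndarray, step_weights: np.ndarray | None = None
) -> np.ndarray:
    """Step-gated model signal.

    ``step_weights`` replaces the hard unit step with per-sample weights
    (used on oversampled grids before convolution, where the sample
    containing the discontinuity carries its fractional area to avoid a
    half-sample bias).
    """
    decay = np.zeros_like(t)
    for d in model.decays:
        decay += d.amplitude * np.exp(-np.clip(t, 0.0, None) / d.lifetime_ps)
    osc = np.zeros_like(t)
    for b in model.beats:
        damp = (
            np.exp(-np.clip(t, 0.0, None) / b.damp_lifetime_ps)
            if np.isfinite(b.damp_lifetime_ps)
            else 1.0
        )
        osc += b.amplitude * damp * np.cos(
            2.0 * math.pi * C_CM_PS * b.freq_cm1 * t + b.phase_rad
        )
    if model.modulation == "multiplicative":
        y = decay * (1.0 + osc)
    else:
        y = decay + osc
    if step_weights is None:
        return np.where(t >= 0.0, y, 0.0)
    return y * step_weights


def step_weights(t: np.ndarray, dt: float) -> np.ndarray:
    """Fractional coverage of each sample cell by t > 0 (area-weighted step)."""
    return np.clip(t / dt + 0.5, 0.0, 1.0)


def model_eval(model: BeatFitModel, t_ps: np.ndarray) -> Transient:
    """Evaluate the kinetic model on a delay grid.

    With a nonzero IRF the step-gated signal is built on an oversampled
    grid padded by 5 IRF widths on both sides, convolved with the Gaussian
    and linearly interpolated back to ``t_ps``; without an IRF the model is
    evaluated directly.
    """
    t = np.asarray(t_ps, dtype=float)
    if model.irf_fwhm_ps == 0.0:
        y = _raw_signal(model, t) + model.offset
        return Transient(t_ps=t, y=y, meta={"kind": "model_eval"})

    sigma = fwhm_to_sigma(model.irf_fwhm_ps)
    dt = float(t[1] - t[0]) if t.size > 1 else sigma / 4.0
    fine_dt = min(dt, sigma / 4.0)
    # resolve the fastest oscillation as well as the IRF
    if model.beats:
        fmax = max(b.freq_cm1 for b in model.beats)
        fine_dt = min(fine_dt, 1.0 / (20.0 * C_CM_PS * fmax))
    pad = 5.0 * model.irf_fwhm_ps
    fine_t = np.arange(t[0] - pad, t[-1] + pad + fine_dt, fine_dt)
    fine_y = gaussian_smooth(
        _raw_signal(model, fine_t, step_weights(fine_t, fine_dt)),
        fine_dt,
        model.irf_fwhm_ps,
    )
    y = np.interp(t, fine_t, fine_y) + model.offset
    return Transient(t_ps=t, y=y, meta={"kind": "model_eval"})


# --------------------------------------------------------------------------
# seeding


def init_from_fft(
    tr: Transient,
    *,
    max_beats: int = 4,
    prominence_frac: float = 0.15,
    min_modulation: float = 0.005,
    max_freq_cm1: float | None = None,
    irf_fwhm_ps: float = 0.0,
    shared_damping: bool = True,
) -> BeatFitModel:
    """Seed a fit model from the transient itself.

    The slowly varying envelope (Gaussian-smoothed over a tenth of the
    record) provides the decay amplitude and a log-linear lifetime guess;
    dividing it out isolates the oscillation, whose FFT peak positions
    seed the beat frequencies (the standard consistency anchor between the
    Fourier and kinetic analyses) and magnitudes seed the modulation
    depths.  Phases start at 0.
    """
    from .dynamics import gaussian_smooth

    sel = tr.t_ps >= 0.0
    t, y = tr.t_ps[sel], tr.y[sel]
    span = float(t[-1] - t[0])
    dt = tr.dt_ps
    envelope = gaussian_smooth(y, dt, max(span / 10.0, 3.0 * dt))
    a0 = float(np.max(envelope))
    # log-linear decay estimate on the well-determined part of the envelope
    ok = envelope > 0.05 * a0
    tau = 10.0 * span
    if np.count_nonzero(ok) > 2 and a0 > 0:
        slope = np.polyfit(t[ok], np.log(envelope[ok]), 1)[0]
        if slope < -1.0 / (100.0 * span):
            tau = min(-1.0 / slope, 100.0 * span)
    tau = max(tau, 5.0 * dt)

    peaks: list[tuple[float, float]] = []
    if a0 > 0 and np.all(envelope > 0.02 * a0):
        osc = Transient(t_ps=t, y=y / envelope - 1.0)
        spec = fft_spectrum(osc)
        # absolute floor: a candidate beat must modulate the signal by at
        # least min_modulation, otherwise numerical envelope ripple and
        # noise would seed spurious components
        peaks = [
            p
            for p in find_beat_peaks(spec, prominence_frac=prominence_frac)
            if p[1] >= min_modulation
        ]
        if max_freq_cm1 is not None:
            peaks = [p for p in peaks if p[0] <= max_freq_cm1]
        peaks = peaks[:max_beats]

    beats = tuple(
        BeatComponent(
            amplitude=max(min(mag, 1.0), 0.01),
            freq_cm1=f,
            phase_rad=0.0,
            damp_lifetime_ps=span / 3.0,
            group="shared" if shared_damping else f"b{k}",
        )
        for k, (f, mag) in enumerate(peaks)
    )
    return BeatFitModel(
        decays=(DecayComponent(amplitude=a0 if a0 > 0 else 1.0, lifetime_ps=tau),),
        beats=beats,
        irf_fwhm_ps=irf_fwhm_ps,
        offset=0.0,
    )


# --------------------------------------------------------------------------
# fitting


def _model_to_params(
    model: BeatFitModel, vary_irf: bool, freq_halfwidth_cm1: float | None = None
) -> lmfit.Parameters:
    p = lmfit.Parameters()
    for j, d in enumerate(model.decays):
        p.add(f"A{j}", value=d.amplitude, min=0.0)
        p.add(f"tau{j}", value=d.lifetime_ps, min=1e-4, max=1e6)
    p.add("offset", value=model.offset)
    groups: dict[str, str] = {}
    for k, b in enumerate(model.beats):
        p.add(f"B{k}", value=b.amplitude, min=0.0, max=2.0)
        # keep each frequency near its FFT seed: the oscillatory landscape
        # is riddled with local minima at unrelated frequencies
        dv = (
            freq_halfwidth_cm1
            if freq_halfwidth_cm1 is not None
            else max(0.08 * b.freq_cm1, 5.0)
        )
        p.add(f"nu{k}", value=b.freq_cm1, min=max(b.freq_cm1 - dv, 0.1), max=b.freq_cm1 + dv)
        p.add(f"phi{k}", value=b.phase_rad, min=-2.0 * math.pi, max=2.0 * math.pi)
        tau_d = b.damp_lifetime_ps if np.isfinite(b.damp_lifetime_ps) else 1e6
        if b.group is None:
            p.add(f"taud{k}", value=tau_d, min=5e-2, max=1e7)
        elif b.group in groups:
            p.add(f"taud{k}", expr=groups[b.group])
        else:
            gname = f"taud{k}"
            p.add(gname, value=tau_d, min=5e-2, max=1e7)
            groups[b.group] = gname
    p.add(
        "irf_fwhm",
        value=model.irf_fwhm_ps,
        vary=vary_irf,
        min=0.0 if model.irf_fwhm_ps == 0.0 else model.irf_fwhm_ps / 3.0,
        max=max(3.0 * model.irf_fwhm_ps, 1e-6),
    )
    return p


def _params_to_model(params: lmfit.Parameters, template: BeatFitModel) -> BeatFitModel:
    decays = tuple(
        DecayComponent(params[f"A{j}"].value, params[f"tau{j}"].value)
        for j in range(len(template.decays))
    )
    beats = tuple(
        replace(
            b,
            amplitude=params[f"B{k}"].value,
            freq_cm1=max(params[f"nu{k}"].value, 1e-9),
            phase_rad=params[f"phi{k}"].value,
            damp_lifetime_ps=params[f"taud{k}"].value,
        )
        for k, b in enumerate(template.beats)
    )
    return replace(
        template,
        decays=decays,
        beats=beats,
        offset=params["offset"].value,
        irf_fwhm_ps=params["irf_fwhm"].value,
    )


def fit_transient(
    tr: Transient,
    model: BeatFitModel,
    *,
    weights: np.ndarray | None = None,
    vary_irf: bool = False,
    multistart: int = 1,
    seed: int = 0,
    perturb_frac: float = 0.2,
    freq_halfwidth_cm1: float | None = None,
) -> FitResult:
    """Weighted trust-region least-squares fit of the kinetic model.

    ``multistart > 1`` repeats the fit from randomly perturbed seeds
    (relative perturbation ``perturb_frac``, RNG seeded by ``seed``) and
    keeps the lowest-chi^2 solution — cheap insurance against local minima
    in the oscillatory landscape.  ``freq_halfwidth_cm1`` overrides the
    default bound (the larger of 8% and 5 cm^-1) tying each beat frequency
    to its seed.  Non-convergence is reported through
    ``FitResult.success``, never silently ignored.
    """
    n_free = sum(
        1
        for _ in _model_to_params(model, vary_irf, freq_halfwidth_cm1).values()
        if _.vary
    )
    if tr.t_ps.size < 5 * n_free:
        raise ValueError(
            f"need at least 5 data points per free parameter "
            f"({tr.t_ps.size} points, {n_free} free)"
        )
    w = np.ones_like(tr.y) if weights is None else np.asarray(weights, dtype=float)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        m = _params_to_model(params, model)
        return (model_eval(m, tr.t_ps).y - tr.y) * w

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, multistart)):
        params = _model_to_params(model, vary_irf, freq_halfwidth_cm1)
        if trial > 0:
            for par in params.values():
                if par.vary and par.expr is None:
                    par.value = par.value * (
                        1.0 + perturb_frac * rng.standard_normal()
                    )
                    if par.min is not None and np.isfinite(par.min):
                        par.value = max(par.value, par.min + 1e-12)
                    if par.max is not None and np.isfinite(par.max):
                        par.value = min(par.value, par.max - 1e-12)
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:  # singular start etc.: try the next restart
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise ValueError("kinetic fit failed on every restart")

    n, k = best.ndata, best.nvarys
    denom = n - k - 1
    aicc = best.aic + (2.0 * k * (k + 1) / denom if denom > 0 else np.inf)
    params_out = {
        name: (
            float(par.value),
            float(par.stderr) if par.stderr is not None else float("nan"),
        )
        for name, par in best.params.items()
    }
    return FitResult(
        model=_params_to_model(best.params, model),
        params=params_out,
        redchi=float(best.redchi),
        aicc=float(aicc),
        residual=np.asarray(best.residual, dtype=float),
        success=bool(best.success),
        nfev=int(best.nfev),
        seed=seed,
        meta={"multistart": multistart, "weighted": weights is not None},
    )
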
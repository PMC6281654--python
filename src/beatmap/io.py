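"""Delimited-text readers and writers for every container in the package.

All numeric payloads are written at full double precision (``%.17g``) so a
write/read round trip is bit-identical.  Metadata travels in ``#``-prefixed
header lines as a single JSON object (``# meta: {...}``), keeping files
self-describing while trivially parseable.  Comma and tab delimiters are
auto-detected on read; writes use commas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import Transient
from .beats import FFTSpectrum, FFTvsEKE, Spectrogram, TRPESMap
from .fitting import FitResult
from .vibronic import StickSpectrum, VibronicLevel

__all__ = [
    "read_stick_spectrum",
    "write_stick_spectrum",
    "read_transient",
    "write_transient",
    "read_trpes",
    "write_trpes",
    "write_fft_spectrum",
    "write_fft_vs_eke",
    "write_spectrogram",
    "write_fit_result",
    "load_config",
    "save_config",
]

_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FMT % x


def _write_meta(fh, meta: dict) -> None:
    if meta:
        fh.write("# meta: " + json.dumps(_jsonable(meta)) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def _read_meta_and_frame(path) -> tuple[dict, pd.DataFrame]:
    meta: dict = {}
    sep = ","
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                # sniff the delimiter from the first non-comment line
                sep = "\t" if ("\t" in line and "," not in line) else ","
                break
            body = line[1:].strip()
            if body.startswith("meta:"):
                meta = json.loads(body[len("meta:") :])
    try:
        frame = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse delimited data ({exc})") from exc
    return meta, frame


# -------------------------------------------------------------- sticks


def write_stick_spectrum(spectrum: StickSpectrum, path) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, {"origin_cm1": spectrum.origin_cm1})
        fh.write("energy_cm1,intensity,mode_label,phase_rad\n")
        for lv in spectrum.levels:
            label = "" if lv.mode_label is None else lv.mode_label
            fh.write(
                f"{_fmt(lv.energy_cm1)},{_fmt(lv.intensity)},{label},{_fmt(lv.phase_rad)}\n"
            )


def read_stick_spectrum(path, origin_cm1: float | None = None) -> StickSpectrum:
    """Read a stick spectrum; ``origin_cm1`` overrides the file header."""
    meta, frame = _read_meta_and_frame(path)
    required = {"energy_cm1", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: stick spectrum needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    origin = origin_cm1 if origin_cm1 is not None else meta.get("origin_cm1")
    if origin is None:
        raise ValueError(f"{path}: no origin_cm1 in header and none supplied")
    labels = (
        [None if pd.isna(x) or x == "" else str(x) for x in frame["mode_label"]]
        if "mode_label" in frame.columns
        else None
    )
    phases = frame["phase_rad"].to_numpy() if "phase_rad" in frame.columns else None
    return StickSpectrum.from_arrays(
        frame["energy_cm1"].to_numpy(),
        frame["intensity"].to_numpy(),
        origin_cm1=float(origin),
        mode_labels=labels,
        phases_rad=phases,
    )


# -------------------------------------------------------------- transients


def write_transient(tr: Transient, path) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, tr.meta)
        fh.write("t_ps,y\n")
        for t, y in zip(tr.t_ps, tr.y):
            fh.write(f"{_fmt(t)},{_fmt(y)}\n")


def read_transient(path) -> Transient:
    """Read a two-column transient; parse errors name the offending line."""
    meta: dict = {}
    t_list: list[float] = []
    y_list: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("meta:"):
                    meta = json.loads(body[len("meta:") :])
                continue
            fields = line.replace("\t", ",").split(",")
            if fields and fields[0].strip().lower() in ("t_ps", "t"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns: {line!r}")
            try:
                t_list.append(float(fields[0]))
                y_list.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse numbers: {line!r}"
                ) from exc
    if not t_list:
        raise ValueError(f"{path}: no data rows")
    return Transient(t_ps=np.array(t_list), y=np.array(y_list), meta=meta)


# -------------------------------------------------------------- 2-D maps


def write_trpes(map_: TRPESMap, path) -> None:
    """Long-format text: one (t_ps, eke_cm1, intensity) row per map cell."""
    t = np.repeat(map_.t_ps, map_.eke_cm1.size)
    e = np.tile(map_.eke_cm1, map_.t_ps.size)
    z = map_.intensity.ravel()
    with open(path, "w") as fh:
        _write_meta(fh, map_.meta)
        fh.write("t_ps,eke_cm1,intensity\n")
        np.savetxt(fh, np.column_stack([t, e, z]), fmt=_FMT, delimiter=",")


def read_trpes(path) -> TRPESMap:
    meta, frame = _read_meta_and_frame(path)
    required = {"t_ps", "eke_cm1", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: TR-PES map needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    t = np.unique(frame["t_ps"].to_numpy())
    e = np.unique(frame["eke_cm1"].to_numpy())
    if t.size * e.size != len(frame):
        raise ValueError(f"{path}: map is not a complete (t, eKE) grid")
    pivot = frame.pivot(index="t_ps", columns="eke_cm1", values="intensity")
    return TRPESMap(t_ps=t, eke_cm1=e, intensity=pivot.to_numpy(), meta=meta)


# -------------------------------------------------------------- spectra


def write_fft_spectrum(spec: FFTSpectrum, path) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, dict(spec.meta, resolution_cm1=spec.resolution_cm1))
        fh.write("freq_cm1,magnitude\n")
        np.savetxt(
            fh, np.column_stack([spec.freq_cm1, spec.magnitude]), fmt=_FMT, delimiter=","
        )


def write_fft_vs_eke(fe: FFTvsEKE, path) -> None:
    """Long format: (eke_cm1, freq_cm1, magnitude, valid) rows."""
    with open(path, "w") as fh:
        _write_meta(fh, dict(fe.meta, resolution_cm1=fe.resolution_cm1))
        fh.write("eke_cm1,freq_cm1,magnitude,valid\n")
        for i, eke in enumerate(fe.eke_cm1):
            v = int(fe.mask[i])
            for f, m in zip(fe.freq_cm1, fe.magnitude[i]):
                fh.write(f"{_fmt(eke)},{_fmt(f)},{_fmt(m)},{v}\n")


def write_spectrogram(sg: Spectrogram, path) -> None:
    """Long format: (window_center_ps, freq_cm1, magnitude) rows."""
    with open(path, "w") as fh:
        _write_meta(
            fh,
            dict(
                sg.meta,
                window_fwhm_ps=sg.window_fwhm_ps,
                step_ps=sg.step_ps,
                normalization=sg.normalization,
            ),
        )
        fh.write("window_center_ps,freq_cm1,magnitude\n")
        for i, tc in enumerate(sg.window_center_ps):
            for f, m in zip(sg.freq_cm1, sg.magnitude[i]):
                fh.write(f"{_fmt(tc)},{_fmt(f)},{_fmt(m)}\n")


# -------------------------------------------------------------- fit results


def write_fit_result(fr: FitResult, path) -> None:
    """Structured-text (YAML) summary of a kinetic fit."""
    doc = {
        "success": bool(fr.success),
        "redchi": float(fr.redchi),
        "aicc": float(fr.aicc),
        "nfev": int(fr.nfev),
        "seed": fr.seed,
        "parameters": {
            name: {"value": v, "stderr": (None if np.isnan(s) else s)}
            for name, (v, s) in fr.params.items()
        },
        "model": {
            "modulation": fr.model.modulation,
            "irf_fwhm_ps": fr.model.irf_fwhm_ps,
            "n_decays": len(fr.model.decays),
            "n_beats": len(fr.model.beats),
        },
        "meta": _jsonable(fr.meta),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -------------------------------------------------------------- config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(cfg), fh, sort_keys=False)
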
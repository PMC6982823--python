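"""File exchange: extraction-curve CSV, JSON results, atomic writes."""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .bic import ExtractionCurve, ExtractionSystem
from .constants import (LAB_SOLID_DENSITY, LAB_TEMPERATURE,
                        LAB_VOID_FRACTION)

__all__ = ["read_curve_csv", "write_curve_csv", "atomic_write_text",
           "write_json"]

#: metadata comment keys <-> ExtractionSystem fields
_META_FIELDS = {
    "N_kg": "N", "x0": "x0", "ys": "ys", "Q_kg_s": "Q", "eps": "eps",
    "rho_s": "rho_s", "rho_f": "rho_f", "dp_um": "d_p",
    "pressure_bar": "P", "temp_C": "T", "mu_f": "mu_f",
}


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file + rename so readers never see a
    partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path, obj) -> None:
    """Atomically write a JSON document (sorted keys, 2-space indent)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True,
                                       default=default) + "\n")


def write_curve_csv(path, curve: ExtractionCurve) -> None:
    """Curve CSV: '# key: value' metadata comments, then
    time_s,extract_kg rows (UTF-8, dot decimal)."""
    s = curve.system
    lines = []
    for key, attr in _META_FIELDS.items():
        val = getattr(s, attr)
        if key == "dp_um":
            val = val * 1e6
        elif key == "pressure_bar":
            val = val / 1e5
        elif key == "temp_C":
            val = val - 273.15
        lines.append(f"# {key}: {val:.10g}")
    lines.append(f"# provenance: {curve.provenance}")
    lines.append("time_s,extract_kg")
    for t, m in zip(curve.times, curve.masses):
        lines.append(f"{t:.10g},{m:.12g}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_curve_csv(path) -> ExtractionCurve:
    """Read a curve CSV written by :func:`write_curve_csv` (or by hand
    with the same header and metadata comments)."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                break
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "extract_kg"} <= set(df.columns):
        raise ValueError("curve CSV needs time_s and extract_kg columns")

    kwargs = {}
    for key, attr in _META_FIELDS.items():
        if key in meta:
            val = float(meta[key])
            if key == "dp_um":
                val = val * 1e-6
            elif key == "pressure_bar":
                val = val * 1e5
            elif key == "temp_C":
                val = val + 273.15
            kwargs[attr] = val
    masses = df["extract_kg"].to_numpy(dtype=float)
    kwargs.setdefault("eps", LAB_VOID_FRACTION)
    kwargs.setdefault("rho_s", LAB_SOLID_DENSITY)
    kwargs.setdefault("T", LAB_TEMPERATURE)
    if "x0" not in kwargs and "N" in kwargs:
        # asymptotic-extraction convention when x0 is not recorded
        kwargs["x0"] = float(masses.max()) / kwargs["N"]
    system = ExtractionSystem(**kwargs)
    return ExtractionCurve(times=df["time_s"].to_numpy(dtype=float),
                           masses=masses, system=system,
                           provenance=meta.get("provenance", "measured"))
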
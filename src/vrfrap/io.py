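"""Curve and report readers/writers.

Curves travel as comma-separated text: ``# key=value`` metadata comment
lines, a ``time,intensity`` header, then the data — bit-exact round trip.
Reports are JSON with a schema version and deterministic key order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from .curve import RecoveryCurve

SCHEMA_VERSION = "1.0"
_FLOAT_META = {"R", "w", "K", "noise_sd"}
_INT_META = {"seed", "n_replicates"}


def write_curve(curve: RecoveryCurve, path) -> None:
    path = Path(path)
    lines = []
    meta: dict[str, Any] = {
        "provenance": curve.provenance,
        "n_replicates": curve.n_replicates,
    }
    if curve.bleach_radius is not None:
        meta["R"] = curve.bleach_radius
    if curve.waist is not None:
        meta["w"] = curve.waist
    if curve.noise_sd is not None:
        meta["noise_sd"] = curve.noise_sd
    for key in ("K", "seed", "mode", "length_unit", "time_unit"):
        if key in curve.meta:
            meta[key] = curve.meta[key]
    for k in sorted(meta):
        v = meta[k]
        if isinstance(v, (float, np.floating)):
            v = repr(float(v))
        lines.append(f"# {k}={v}")
    lines.append("time,intensity")
    for t, i in zip(curve.times, curve.intensities):
        lines.append(f"{float(t)!r},{float(i)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_curve(path) -> RecoveryCurve:
    """Parse a curve file; errors name the offending line number."""
    path = Path(path)
    meta: dict[str, Any] = {}
    times: list[float] = []
    intens: list[float] = []
    line_numbers: list[int] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: metadata line without '='")
            k, v = body.split("=", 1)
            k, v = k.strip(), v.strip()
            if k in _FLOAT_META:
                try:
                    meta[k] = float(v)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable value for {k!r}") from exc
            elif k in _INT_META:
                meta[k] = int(v)
            else:
                meta[k] = v
            continue
        if not header_seen:
            cols = [c.strip().lower() for c in line.split(",")]
            if cols[:2] != ["time", "intensity"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header 'time,intensity', got {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two comma-separated values")
        try:
            times.append(float(parts[0]))
            intens.append(float(parts[1]))
            line_numbers.append(lineno)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable number") from exc
    if not header_seen:
        raise ValueError(f"{path}: missing 'time,intensity' header")
    t = np.array(times)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise ValueError(
            f"{path}:{line_numbers[bad + 1]}: times not strictly increasing")
    extra = {k: v for k, v in meta.items()
             if k not in ("R", "w", "noise_sd", "provenance", "n_replicates")}
    return RecoveryCurve(
        times=t, intensities=np.array(intens),
        bleach_radius=meta.get("R"), waist=meta.get("w"),
        n_replicates=int(meta.get("n_replicates", 1)),
        noise_sd=meta.get("noise_sd"),
        provenance=str(meta.get("provenance", "file")),
        meta=extra,
    )


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(results: dict[str, Any], path,
                 input_paths: list | None = None,
                 seed: int | None = None) -> None:
    """Versioned JSON report with input checksums and deterministic key
    order; ``results`` must already be JSON-serializable."""
    from . import __version__

    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": seed,
        "inputs": {str(p): _checksum(p) for p in (input_paths or [])},
        "results": results,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     allow_nan=False, default=_jsonify) + "\n",
                          encoding="utf-8")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report(path) -> dict:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if "schema_version" not in doc:
        raise ValueError(f"{path}: not a report file (no schema_version)")
    return doc
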
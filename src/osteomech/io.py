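"""CSV/JSON I/O for curves, tables and reports.

Curves are plain CSV with a header row whose column names carry the
units (depth_nm, force_nN, displacement_mm, force_N); per-curve metadata
(probe radius, Poisson ratio, span, ...) lives in a JSON sidecar next to
the CSV, mirroring how instrument exports usually separate the two.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bending import LoadDisplacementCurve
from .nanoindent import ForceIndentationCurve


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_indentation_csv(curve: ForceIndentationCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"depth_nm": curve.depth_nm, "force_nN": curve.force_nN}).to_csv(
        path, index=False
    )
    meta = {
        "probe_radius_nm": curve.probe_radius_nm,
        "poisson_ratio": curve.poisson_ratio,
        "frequency_hz": curve.frequency_hz,
        "orientation": curve.orientation,
        "compartment": curve.compartment,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_indentation_csv(path: str | Path) -> ForceIndentationCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return ForceIndentationCurve(
        depth_nm=df["depth_nm"].to_numpy(),
        force_nN=df["force_nN"].to_numpy(),
        probe_radius_nm=float(meta.get("probe_radius_nm", 300.0)),
        poisson_ratio=float(meta.get("poisson_ratio", 0.3)),
        frequency_hz=meta.get("frequency_hz"),
        orientation=meta.get("orientation", "longitudinal"),
        compartment=meta.get("compartment", "cortical"),
        meta=meta,
    )


def write_bending_csv(curve: LoadDisplacementCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"displacement_mm": curve.displacement_mm, "force_N": curve.force_N}
    ).to_csv(path, index=False)
    meta = {"span_mm": curve.span_mm, "rate_mm_per_s": curve.loading_rate_mm_s}
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_bending_csv(path: str | Path, span_mm: float | None = None) -> LoadDisplacementCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return LoadDisplacementCurve(
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
        span_mm=float(span_mm if span_mm is not None else meta.get("span_mm", 7.0)),
        loading_rate_mm_s=float(meta.get("rate_mm_per_s", 0.05)),
        meta=meta,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report_json(report, path: str | Path) -> Path:
    """Serialize any dataclass/dict report (numpy-safe) as indented JSON."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2))
    return path
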
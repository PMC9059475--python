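"""Labeled voxel volume container and MetaImage / TIFF-stack I/O.

The volume stands in for a reconstructed, pre-segmented micro-CT scan.
Voxel labels: 0 background, 1 cortical bone, 2 trabecular bone, 3 marrow.
The shaft axis is the last array axis (z); arrays are indexed (x, y, z).
All physical coordinates are millimetres; voxel spacing is stored in
micrometres to match scanner conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError

LABEL_BACKGROUND = 0
LABEL_CORTICAL = 1
LABEL_TRABECULAR = 2
LABEL_MARROW = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_CORTICAL: "cortical",
    LABEL_TRABECULAR: "trabecular",
    LABEL_MARROW: "marrow",
}


@dataclass
class VoxelVolume:
    """Isotropic labeled 3D grid.

    Parameters
    ----------
    labels
        Integer array of shape (nx, ny, nz) with values in {0, 1, 2, 3}.
    spacing_um
        Isotropic voxel edge length in micrometres.
    origin_mm
        Physical position of the center of voxel (0, 0, 0).
    growth_plate_z_mm
        Axial coordinate of the growth-plate plane, if the volume has one.
        Stored as metadata; the plane is not a voxel label.
    """

    labels: np.ndarray
    spacing_um: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    growth_plate_z_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.shape[2] < 1:
            raise ParameterError("labels must be a 3D array with at least one z-slice")
        if self.spacing_um <= 0:
            raise ParameterError("voxel spacing must be positive")
        bad = np.setdiff1d(np.unique(self.labels), [0, 1, 2, 3])
        if bad.size:
            raise ParameterError(f"unknown label codes: {bad.tolist()}")

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def z_coords_mm(self) -> np.ndarray:
        """Physical z coordinate of each slice's voxel centers."""
        return self.origin_mm[2] + np.arange(self.shape[2]) * self.spacing_mm

    def mask(self, which: int | set[int]) -> np.ndarray:
        labels = {which} if isinstance(which, int) else set(which)
        return np.isin(self.labels, sorted(labels))


def write_metaimage(volume: VoxelVolume, path: str | Path) -> Path:
    """Write the volume as MetaImage (.mha), growth-plate z in a JSON sidecar."""
    import SimpleITK as sitk

    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.labels.T.astype(np.uint8)))
    s = volume.spacing_mm
    img.SetSpacing((s, s, s))
    img.SetOrigin(tuple(volume.origin_mm))
    sitk.WriteImage(img, str(path), useCompression=False)
    _write_sidecar(volume, path.with_suffix(".json"))
    return path


def read_metaimage(path: str | Path) -> VoxelVolume:
    import SimpleITK as sitk

    path = Path(path)
    img = sitk.ReadImage(str(path))
    labels = sitk.GetArrayFromImage(img).T  # back to (x, y, z)
    spacing = img.GetSpacing()
    meta = _read_sidecar(path.with_suffix(".json"))
    return VoxelVolume(
        labels=labels,
        spacing_um=spacing[0] * 1000.0,
        origin_mm=tuple(img.GetOrigin()),
        growth_plate_z_mm=meta.get("growth_plate_z_mm"),
        meta=meta,
    )


def write_tiff_stack(volume: VoxelVolume, path: str | Path) -> Path:
    """Write the volume as a multipage TIFF (pages along z) plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    # tifffile pages index the first axis; store as (z, y, x)
    tifffile.imwrite(str(path), np.ascontiguousarray(volume.labels.T.astype(np.uint8)))
    _write_sidecar(volume, path.with_suffix(".json"))
    return path


def read_tiff_stack(path: str | Path) -> VoxelVolume:
    import tifffile

    path = Path(path)
    labels = tifffile.imread(str(path)).T
    meta = _read_sidecar(path.with_suffix(".json"))
    if "spacing_um" not in meta:
        raise ParameterError(f"TIFF sidecar {path.with_suffix('.json')} missing spacing_um")
    return VoxelVolume(
        labels=labels,
        spacing_um=float(meta["spacing_um"]),
        origin_mm=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        growth_plate_z_mm=meta.get("growth_plate_z_mm"),
        meta=meta,
    )


def read_volume(path: str | Path) -> VoxelVolume:
    """Dispatch on extension: .mha/.mhd via MetaImage, .tif/.tiff via TIFF stack."""
    path = Path(path)
    if path.suffix.lower() in {".mha", ".mhd"}:
        return read_metaimage(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_tiff_stack(path)
    raise ParameterError(f"unsupported volume format: {path.suffix}")


def _write_sidecar(volume: VoxelVolume, path: Path) -> None:
    meta = dict(volume.meta)
    meta.update(
        {
            "spacing_um": volume.spacing_um,
            "origin_mm": list(volume.origin_mm),
            "growth_plate_z_mm": volume.growth_plate_z_mm,
            "label_map": {str(k): v for k, v in LABEL_NAMES.items()},
            "axis_convention": "z is the shaft axis",
        }
    )
    path.write_text(json.dumps(meta, indent=2))


def _read_sidecar(path: Path) -> dict:
    if path.exists():
        return json.loads(path.read_text())
    return {}
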
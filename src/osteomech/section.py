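"""Cross-sectional geometry along the shaft: area, principal second
moments, and the geometric bending coefficients Imax/C1 and Imin/C2.

Each voxel is treated as a solid unit square contributing its own
second moment (h^4/12) plus the parallel-axis term about the section
centroid; this removes the thin-wall bias a point-mass model would
introduce.  Principal values come from the eigen-decomposition of the
2x2 second-moment tensor; C1 and C2 are the farthest voxel-center
distances from the Imax and Imin principal axes respectively, so
Imax/C1 and Imin/C2 are the section moduli about the two principal
bending axes.  Flexural rigidity is E*I for a supplied modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .volume import LABEL_CORTICAL, LABEL_TRABECULAR, VoxelVolume


@dataclass
class SectionProperties:
    area_mm2: float
    centroid_mm: tuple[float, float]
    ixx_mm4: float
    iyy_mm4: float
    ixy_mm4: float
    imax_mm4: float
    imin_mm4: float
    theta_rad: float
    c1_mm: float
    c2_mm: float

    @property
    def imax_over_c1_mm3(self) -> float:
        return self.imax_mm4 / self.c1_mm

    @property
    def imin_over_c2_mm3(self) -> float:
        return self.imin_mm4 / self.c2_mm


@dataclass
class RigidityProfile:
    z_mm: np.ndarray
    properties: list[SectionProperties]
    flexural_rigidity_N_mm2: np.ndarray | None = None

    def as_arrays(self) -> dict[str, np.ndarray]:
        cols = {
            "z_mm": self.z_mm,
            "area_mm2": np.array([p.area_mm2 for p in self.properties]),
            "imax_mm4": np.array([p.imax_mm4 for p in self.properties]),
            "imin_mm4": np.array([p.imin_mm4 for p in self.properties]),
            "imax_over_c1_mm3": np.array([p.imax_over_c1_mm3 for p in self.properties]),
            "imin_over_c2_mm3": np.array([p.imin_over_c2_mm3 for p in self.properties]),
        }
        if self.flexural_rigidity_N_mm2 is not None:
            cols["flexural_rigidity_N_mm2"] = self.flexural_rigidity_N_mm2
        return cols


def section_properties(slice_mask: np.ndarray, spacing_um: float) -> SectionProperties:
    """Section properties of one 2D binary cross-section.

    Moments are about the area centroid.  Ties in the eigen-problem
    (ixx = iyy, ixy = 0) resolve to theta = 0.
    """
    mask = np.asarray(slice_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise UndefinedMetricError("empty or non-2D slice")
    h = spacing_um / 1000.0
    ix, iy = np.nonzero(mask)
    x = ix * h
    y = iy * h
    n = x.size
    area = n * h * h
    cx, cy = float(x.mean()), float(y.mean())
    dx, dy = x - cx, y - cy
    self_term = n * h**4 / 12.0
    # Ixx: second moment about the x-axis (integral of y^2 dA)
    ixx = float(np.dot(dy, dy)) * h * h + self_term
    iyy = float(np.dot(dx, dx)) * h * h + self_term
    ixy = float(np.dot(dx, dy)) * h * h

    if abs(ixy) < 1e-300 and abs(ixx - iyy) < 1e-300:
        imax, imin, theta = ixx, iyy, 0.0
        v1 = np.array([1.0, 0.0])
        v2 = np.array([0.0, 1.0])
    else:
        tensor = np.array([[ixx, -ixy], [-ixy, iyy]])
        vals, vecs = np.linalg.eigh(tensor)  # ascending
        imin, imax = float(vals[0]), float(vals[1])
        v1 = vecs[:, 1]  # axis direction of Imax... see below
        v2 = vecs[:, 0]
        # The tensor acts on axis directions (u) giving I about that axis.
        # eigenvector of the larger eigenvalue is the direction of the axis
        # about which I is maximal.
        theta = float(np.arctan2(v1[1], v1[0]))
        if theta <= -np.pi / 2:
            theta += np.pi
        elif theta > np.pi / 2:
            theta -= np.pi

    # farthest voxel-center distance from each principal axis (axis through
    # the centroid along v1 for Imax, v2 for Imin); distance is the
    # perpendicular component
    pts = np.stack([dx, dy], axis=1)
    c1 = float(np.max(np.abs(pts @ np.array([-v1[1], v1[0]]))))
    c2 = float(np.max(np.abs(pts @ np.array([-v2[1], v2[0]]))))
    c1 = max(c1, h / 2)
    c2 = max(c2, h / 2)
    return SectionProperties(
        area_mm2=area,
        centroid_mm=(cx, cy),
        ixx_mm4=ixx,
        iyy_mm4=iyy,
        ixy_mm4=ixy,
        imax_mm4=imax,
        imin_mm4=imin,
        theta_rad=theta,
        c1_mm=c1,
        c2_mm=c2,
    )


def rigidity_profile(
    volume: VoxelVolume,
    bone_labels: set[int] = frozenset({LABEL_CORTICAL, LABEL_TRABECULAR}),
    modulus_gpa: float | None = None,
) -> RigidityProfile:
    """Per-slice section properties along z for the mineralized section.

    By default the whole mineralized section (cortical + trabecular) is
    profiled.  When a modulus is supplied, flexural rigidity E*Imin is
    reported per slice (Imin governs the weakest bending direction);
    units: GPa * mm^4 = kN*mm^2, converted to N*mm^2.
    """
    mask3 = volume.mask(set(bone_labels))
    occupied = np.nonzero(mask3.any(axis=(0, 1)))[0]
    if occupied.size < 2:
        raise UndefinedMetricError("need >= 2 nonempty slices for a profile")
    z = volume.z_coords_mm()
    props = []
    zs = []
    for k in occupied:
        props.append(section_properties(mask3[:, :, k], volume.spacing_um))
        zs.append(z[k])
    rigidity = None
    if modulus_gpa is not None:
        rigidity = np.array([modulus_gpa * 1000.0 * p.imin_mm4 for p in props])
    return RigidityProfile(
        z_mm=np.asarray(zs), properties=props, flexural_rigidity_N_mm2=rigidity
    )
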
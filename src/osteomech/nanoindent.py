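"""Hertzian spherical-contact analysis of AFM force-indentation curves.

A rigid sphere of radius R indenting an elastic half-space obeys

    F = (4/3) * [E / (1 - nu^2)] * sqrt(R) * delta^(3/2)

with F the load, delta the indentation depth, E the sample's elastic
modulus and nu its Poisson ratio.  Equivalently E = 3 F (1 - nu^2) /
(4 sqrt(R delta^3)).  Units are chosen so that nm and nN give E directly
in GPa (1 nN/nm^2 = 1 GPa).

The half-space assumption requires small strains; a depth cap (default
50 nm, well below the probe radius of 300 nm) restricts the fit window
to the regime where the model holds and substrate effects are absent.

Longitudinal (El) and transverse (Et) moduli are summarized per
compartment and genotype; their ratio El/Et is the anisotropy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    FitFailureError,
    InsufficientDataError,
    NoContactError,
    ParameterError,
    UndefinedMetricError,
)

#: Poisson ratio assumed for bone when curve metadata omits it.
DEFAULT_POISSON_RATIO = 0.3

#: Default indentation-depth cap in nm for Hertz fits.
DEFAULT_DEPTH_CAP_NM = 50.0


@dataclass
class ForceIndentationCurve:
    """One AFM indentation record: depth (nm) vs force (nN).

    ``depth`` is the raw piezo-derived indentation coordinate; the true
    contact point may sit at a positive offset within the record.
    """

    depth_nm: np.ndarray
    force_nN: np.ndarray
    probe_radius_nm: float
    poisson_ratio: float = DEFAULT_POISSON_RATIO
    frequency_hz: float | None = None
    orientation: Literal["longitudinal", "transverse"] = "longitudinal"
    compartment: Literal["cortical", "trabecular"] = "cortical"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth_nm = np.asarray(self.depth_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.depth_nm.shape != self.force_nN.shape or self.depth_nm.size < 10:
            raise ParameterError("depth and force must be equal-length arrays of >= 10 samples")
        if self.probe_radius_nm <= 0:
            raise ParameterError("probe radius must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ParameterError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class HertzFit:
    modulus_gpa: float
    contact_offset_nm: float
    residual_rms_nN: float
    depth_cap_nm: float
    n_points: int


@dataclass
class FrequencyFit:
    """Empirical log-frequency stiffening law E(f) = a + b ln f."""

    intercept_a_gpa: float
    slope_b_gpa: float
    r_squared: float


@dataclass
class ModulusSummary:
    mean_el_gpa: float
    mean_et_gpa: float
    sd_el_gpa: float
    sd_et_gpa: float
    n_el: int
    n_et: int

    @property
    def anisotropy_ratio(self) -> float:
        """Mean El over mean Et."""
        return self.mean_el_gpa / self.mean_et_gpa


def hertz_force(depth_nm, modulus_gpa: float, poisson_ratio: float, probe_radius_nm: float):
    """Forward Hertz model: force (nN) at the given depths (nm)."""
    delta = np.clip(np.asarray(depth_nm, dtype=float), 0.0, None)
    reduced = modulus_gpa / (1.0 - poisson_ratio**2)
    return (4.0 / 3.0) * reduced * np.sqrt(probe_radius_nm) * delta**1.5


def detect_contact_point(curve: ForceIndentationCurve, force_threshold_sd: float = 5.0) -> float:
    """Locate the depth at which the probe first touches the surface.

    The first crossing of (baseline mean + threshold * baseline SD) gives a
    coarse offset; back-extrapolating the linearized Hertz relation
    F^(2/3) = k^(2/3) * (delta - delta0) over the post-contact samples then
    refines delta0 as the x-intercept.
    """
    depth, force = curve.depth_nm, curve.force_nN
    n_base = max(5, int(0.1 * depth.size))
    baseline = force[:n_base]
    mu, sd = float(np.mean(baseline)), float(np.std(baseline))
    threshold = mu + force_threshold_sd * max(sd, 1e-12)
    above = np.nonzero(force > threshold)[0]
    if above.size == 0:
        raise NoContactError("force never exceeds the baseline threshold")
    coarse = float(depth[above[0]])

    # refine on samples clearly past contact: F^(2/3) is linear in depth
    # with x-intercept at the contact point (exact for the Hertz model)
    post = force > max(threshold, 1e-12)
    if np.count_nonzero(post) >= 3:
        x = depth[post]
        y = np.maximum(force[post], 0.0) ** (2.0 / 3.0)
        slope, intercept = np.polyfit(x, y, 1)
        if slope > 0:
            refined = -intercept / slope
            if refined <= depth[-1]:
                # noise can push the intercept slightly before the record
                # start; contact cannot precede the first sample
                return float(np.clip(refined, depth[0], depth[-1]))
    return coarse


def fit_hertz(
    curve: ForceIndentationCurve,
    depth_cap_nm: float = DEFAULT_DEPTH_CAP_NM,
    contact_offset_nm: float | None = None,
    force_threshold_sd: float = 5.0,
) -> HertzFit:
    """Fit E by linear least squares of F on delta^(3/2) through the origin.

    The linearization is exact for the Hertz model and needs no
    initialization; the fitted slope maps to the modulus via
    E = slope * (3/4) * (1 - nu^2) / sqrt(R).

    Parameters
    ----------
    depth_cap_nm
        Hard upper bound on post-contact depth included in the fit; points
        beyond it are discarded (small-strain / substrate-free window).
    contact_offset_nm
        Known contact offset; detected automatically when omitted.
    """
    if contact_offset_nm is None:
        try:
            contact_offset_nm = detect_contact_point(curve, force_threshold_sd)
        except NoContactError:
            raise
    delta = curve.depth_nm - contact_offset_nm
    window = (delta > 0) & (delta <= depth_cap_nm)
    if np.count_nonzero(window) < 10:
        raise InsufficientDataError(
            f"only {np.count_nonzero(window)} usable points below the {depth_cap_nm} nm cap"
        )
    d32 = delta[window] ** 1.5
    f = curve.force_nN[window]
    slope = float(np.dot(d32, f) / np.dot(d32, d32))
    if slope <= 0:
        raise FitFailureError("nonpositive Hertz slope: curve is not an indentation loading branch")
    modulus = slope * 0.75 * (1.0 - curve.poisson_ratio**2) / np.sqrt(curve.probe_radius_nm)
    residual = f - slope * d32
    return HertzFit(
        modulus_gpa=modulus,
        contact_offset_nm=float(contact_offset_nm),
        residual_rms_nN=float(np.sqrt(np.mean(residual**2))),
        depth_cap_nm=depth_cap_nm,
        n_points=int(np.count_nonzero(window)),
    )


def modulus_summary(
    longitudinal_gpa: Sequence[float], transverse_gpa: Sequence[float]
) -> ModulusSummary:
    """Group means, SDs and the El/Et anisotropy ratio for one cell
    (compartment x genotype) of the experimental design."""
    el = np.asarray(list(longitudinal_gpa), dtype=float)
    et = np.asarray(list(transverse_gpa), dtype=float)
    if el.size == 0 or et.size == 0:
        raise UndefinedMetricError("empty orientation group")
    return ModulusSummary(
        mean_el_gpa=float(np.mean(el)),
        mean_et_gpa=float(np.mean(et)),
        sd_el_gpa=float(np.std(el, ddof=1)) if el.size > 1 else 0.0,
        sd_et_gpa=float(np.std(et, ddof=1)) if et.size > 1 else 0.0,
        n_el=int(el.size),
        n_et=int(et.size),
    )


def fit_log_frequency(points: Iterable[tuple[float, float]]) -> FrequencyFit:
    """Least-squares fit of modulus on ln(frequency): E(f) = a + b ln f.

    Captures the rate stiffening seen in dynamic indentation sweeps
    (1-100 Hz); b > 0 reflects the viscoelastic nature of bone.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be (frequency_hz, modulus_gpa) pairs")
    freqs, moduli = pts[:, 0], pts[:, 1]
    if np.any(freqs <= 0):
        raise ParameterError("frequencies must be positive")
    if np.unique(freqs).size < 3:
        raise InsufficientDataError("need >= 3 distinct frequencies for a log fit")
    x = np.log(freqs)
    b, a = np.polyfit(x, moduli, 1)
    pred = a + b * x
    ss_res = float(np.sum((moduli - pred) ** 2))
    ss_tot = float(np.sum((moduli - np.mean(moduli)) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return FrequencyFit(intercept_a_gpa=float(a), slope_b_gpa=float(b), r_squared=min(r2, 1.0))
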
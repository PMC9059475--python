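"""Three-point-bending load-displacement analysis.

Extracts whole-bone mechanical metrics from a single monotonic loading
record: stiffness (the maximum sustained slope of the elastic portion,
with the instrument/settling toe excluded), yield load (offset-line
construction), maximum load, ultimate load/displacement at fracture, and
work to fracture (area under the curve).

Stiffness here is a whole-bone structural property in N/mm, not a tissue
modulus; converting it to a material modulus requires the section
geometry and is deliberately out of scope of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisFailureError, DataError, InsufficientDataError, ParameterError


@dataclass
class LoadDisplacementCurve:
    """Whole-bone three-point-bending record (displacement mm, force N)."""

    displacement_mm: np.ndarray
    force_N: np.ndarray
    loading_rate_mm_s: float = 0.05
    span_mm: float = 7.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.displacement_mm.shape != self.force_N.shape or self.displacement_mm.size < 20:
            raise ParameterError("displacement and force must be equal-length arrays of >= 20 samples")
        if abs(self.displacement_mm[0]) > 1e-12:
            raise ParameterError("displacement must start at 0")
        if np.any(np.diff(self.displacement_mm) < 0):
            raise DataError("displacement must be non-decreasing")


@dataclass
class BendingMetrics:
    stiffness_N_mm: float
    yield_load_N: float
    ultimate_load_N: float
    ultimate_displacement_mm: float
    max_load_N: float
    work_to_fracture_N_mm: float
    elastic_window: tuple[int, int]  # half-open index interval
    fracture_detected: bool = True


def _moving_slopes(d: np.ndarray, f: np.ndarray, width: int) -> np.ndarray:
    """Least-squares slope of each length-`width` window; slopes[i] covers [i, i+width)."""
    n = d.size - width + 1
    slopes = np.empty(n)
    for i in range(n):
        x = d[i : i + width]
        y = f[i : i + width]
        dx = x - x.mean()
        denom = float(np.dot(dx, dx))
        slopes[i] = np.dot(dx, y - y.mean()) / denom if denom > 0 else 0.0
    return slopes


def identify_elastic_region(
    curve: LoadDisplacementCurve,
    toe_fraction: float = 0.5,
    window_width: int | None = None,
    linearity_tol: float = 0.15,
) -> tuple[int, int]:
    """Locate the linear elastic segment as a half-open index interval.

    The toe (low-slope settling at the start of the record) is excluded by
    dropping leading windows whose local slope is below
    ``toe_fraction * running-max slope``; the segment ends at the first
    sustained drop of the local slope below ``(1 - linearity_tol)`` of the
    elastic slope (onset of yielding) or at the force peak.
    """
    d, f = curve.displacement_mm, curve.force_N
    peak = int(np.argmax(f))
    if f[peak] <= 0:
        raise AnalysisFailureError("curve carries no load")
    d, f = d[: peak + 1], f[: peak + 1]
    if window_width is None:
        window_width = max(3, d.size // 20)
    if d.size <= window_width:
        raise AnalysisFailureError("curve too short for the slope window")
    slopes = _moving_slopes(d, f, window_width)
    # robust reference slope: a high percentile resists single noisy
    # window spikes that the plain maximum would lock onto
    k_ref = float(np.percentile(slopes, 90))
    if k_ref <= 0:
        raise AnalysisFailureError("no rising segment found")

    start = None
    running = 0.0
    for i, s in enumerate(slopes):
        running = max(running, s)
        if s >= toe_fraction * running and s >= 0.9 * k_ref:
            start = i
            break
    if start is None:
        raise AnalysisFailureError("no linear segment found")

    # anchor an elastic line just past the toe, then end the window at the
    # first sustained drop of the curve below that line (yield onset);
    # testing the curve, not windowed slopes, is far less noise-sensitive
    i1 = min(start + 2 * window_width, d.size)
    k0 = float(np.median(slopes[start : max(start + window_width, start + 3)]))
    b0 = float(np.median(f[start:i1] - k0 * d[start:i1]))
    resid = f - (k0 * d + b0)
    sigma = float(np.std(resid[start:i1]))
    tol = max(3.0 * sigma, linearity_tol * 0.1 * float(f.max()))
    end = d.size
    run = 0
    for i in range(i1, d.size):
        if resid[i] < -tol:
            run += 1
            if run >= 3:
                end = i - run + 1
                break
        else:
            run = 0
    return (start, end)


def extract_metrics(
    curve: LoadDisplacementCurve,
    toe_fraction: float = 0.5,
    window_width: int | None = None,
    yield_offset_fraction: float = 0.002,
    fracture_drop_fraction: float = 0.5,
) -> BendingMetrics:
    """Compute the full metric set from one load-displacement record.

    Notes
    -----
    * Stiffness is the maximum moving-window slope inside the elastic
      window (the mean of the top windows is not used: the max-slope
      definition matches how testing-machine software reports it).
    * Yield is the intersection of the curve with the elastic-slope line
      offset by ``yield_offset_fraction * span`` along displacement
      (0.2%-offset construction, the reproducible standard when no yield
      definition is given).
    * Fracture is the first inter-sample force drop exceeding
      ``fracture_drop_fraction`` of the peak; ultimate load/displacement
      are taken at the last point before that drop.  If no such drop
      exists the record end is used and the result is flagged.
    """
    d, f = curve.displacement_mm, curve.force_N
    start, end = identify_elastic_region(curve, toe_fraction, window_width)
    seg_d, seg_f = d[start:end], f[start:end]
    # slope windows: a quarter of the elastic segment. Narrow windows make
    # the max-slope statistic a maximum over many noisy estimates and bias
    # stiffness upward; wide windows are exact on the (linear) segment.
    width = window_width if window_width is not None else max(3, seg_d.size // 4)
    if seg_d.size <= width:
        width = max(2, seg_d.size - 1)
    slopes = _moving_slopes(seg_d, seg_f, width)
    stiffness = float(np.max(slopes))

    max_idx = int(np.argmax(f))
    max_load = float(f[max_idx])

    drops = f[:-1] - f[1:]
    frac_idx = np.nonzero(drops > fracture_drop_fraction * max_load)[0]
    if frac_idx.size:
        ult_idx = int(frac_idx[0])
        fracture_detected = True
    else:
        ult_idx = f.size - 1
        fracture_detected = False

    # 0.2%-of-span offset line anchored on the elastic fit
    i_anchor = start + int(np.argmax(slopes))
    d0 = d[i_anchor] - f[i_anchor] / stiffness  # elastic line x-intercept
    offset = yield_offset_fraction * curve.span_mm
    line = stiffness * (d - d0 - offset)
    diff = f - line
    yield_load = max_load
    crossing = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    crossing = crossing[crossing >= start]
    if crossing.size:
        i = int(crossing[0])
        # linear interpolation of the crossing
        t = diff[i] / (diff[i] - diff[i + 1])
        yield_load = float(f[i] + t * (f[i + 1] - f[i]))

    work = float(np.trapezoid(f[: ult_idx + 1], d[: ult_idx + 1]))

    return BendingMetrics(
        stiffness_N_mm=stiffness,
        yield_load_N=min(yield_load, max_load),
        ultimate_load_N=float(f[ult_idx]),
        ultimate_displacement_mm=float(d[ult_idx]),
        max_load_N=max_load,
        work_to_fracture_N_mm=work,
        elastic_window=(start, end),
        fracture_detected=fracture_detected,
    )


def group_contrast(metrics_a, metrics_b, labels=("WT", "KO")) -> dict:
    """Per-metric group means, SDs, percent difference (A vs B) and
    unpaired two-tailed t-test p-values for two cohorts of BendingMetrics."""
    from .stats import percent_difference, ttest_unpaired

    if len(metrics_a) < 2 or len(metrics_b) < 2:
        raise InsufficientDataError("need >= 2 specimens per group")
    fields = [
        "stiffness_N_mm",
        "yield_load_N",
        "ultimate_load_N",
        "ultimate_displacement_mm",
        "max_load_N",
        "work_to_fracture_N_mm",
    ]
    out: dict = {"groups": labels, "metrics": {}}
    for name in fields:
        a = np.array([getattr(m, name) for m in metrics_a], dtype=float)
        b = np.array([getattr(m, name) for m in metrics_b], dtype=float)
        t, p = ttest_unpaired(a, b)
        out["metrics"][name] = {
            f"mean_{labels[0]}": float(a.mean()),
            f"mean_{labels[1]}": float(b.mean()),
            f"sd_{labels[0]}": float(a.std(ddof=1)),
            f"sd_{labels[1]}": float(b.std(ddof=1)),
            "percent_difference": percent_difference(float(a.mean()), float(b.mean())),
            "t": t,
            "p": p,
        }
    return out
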
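"""Group statistics, expression fold-changes, and report assembly.

Implements the study-level statistical toolkit: percent-difference
contrasts, unpaired two-tailed Student's t-tests (pooled variance, as in
the classical formulation; Welch available by flag), one-way ANOVA,
the delta-delta-Ct relative-expression method for qPCR, ratio-of-means
metrics with bootstrap confidence intervals (RANKL/OPG style), and a
cross-module phenotype report builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    DataError,
    InsufficientDataError,
    UndefinedMetricError,
)


@dataclass
class GroupSample:
    label: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1 or not np.all(np.isfinite(self.values)):
            raise DataError("group needs >= 1 finite value")


@dataclass
class CtRecord:
    """One qPCR well: threshold cycles for the target and reference gene."""

    sample_id: str
    ct_target: float
    ct_reference: float
    group: Literal["calibrator", "test"] = "test"

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not (0 < ct < 45):
                raise DataError(f"Ct value {ct} outside the plausible (0, 45) range")


def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / b: by how many percent a exceeds the reference b."""
    if b == 0:
        raise UndefinedMetricError("percent difference undefined for zero reference")
    return 100.0 * (a - b) / b


def ttest_unpaired(
    x: Sequence[float] | GroupSample,
    y: Sequence[float] | GroupSample,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test; pooled-variance Student form by default.

    Degenerate case (zero pooled variance): p = 1 for equal means,
    p -> 0 otherwise (t is +/- inf).
    """
    xv = x.values if isinstance(x, GroupSample) else np.asarray(list(x), dtype=float)
    yv = y.values if isinstance(y, GroupSample) else np.asarray(list(y), dtype=float)
    if xv.size < 2 or yv.size < 2:
        raise InsufficientDataError("need >= 2 values per group")
    if np.var(xv, ddof=1) == 0 and np.var(yv, ddof=1) == 0:
        if np.mean(xv) == np.mean(yv):
            return 0.0, 1.0
        return float(np.sign(np.mean(xv) - np.mean(yv)) * np.inf), 0.0
    res = sps.ttest_ind(xv, yv, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups: Sequence[GroupSample | Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA (F, p) across >= 2 groups."""
    arrays = [
        g.values if isinstance(g, GroupSample) else np.asarray(list(g), dtype=float)
        for g in groups
    ]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise DataError("need >= 2 groups with >= 2 values each")
    if all(np.var(a, ddof=1) == 0 for a in arrays):
        means = [float(a.mean()) for a in arrays]
        if len(set(means)) == 1:
            return 0.0, 1.0
        return float("inf"), 0.0
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def ddct_fold_change(records: Sequence[CtRecord]) -> dict[str, float]:
    """Relative expression per test sample by the delta-delta-Ct method.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the mean
    calibrator dCt; fold change = 2^(-ddCt).  Calibrator samples are
    reported too (their mean fold is 1 by construction on average).
    """
    cal = [r for r in records if r.group == "calibrator"]
    if not cal:
        raise ConfigurationError("no calibrator records")
    cal_dct = float(np.mean([r.ct_target - r.ct_reference for r in cal]))
    out = {}
    for r in records:
        ddct = (r.ct_target - r.ct_reference) - cal_dct
        out[r.sample_id] = float(2.0 ** (-ddct))
    return out


def ratio_metric(
    numerator: GroupSample,
    denominator: GroupSample,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict[str, float]:
    """Ratio of group means (e.g. RANKL/OPG) with a seeded bootstrap CI."""
    den_mean = float(np.mean(denominator.values))
    if den_mean == 0:
        raise UndefinedMetricError("zero denominator mean")
    num_mean = float(np.mean(numerator.values))
    ratio = num_mean / den_mean
    rng = np.random.default_rng(seed)
    nv, dv = numerator.values, denominator.values
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bn = rng.choice(nv, size=nv.size, replace=True).mean()
        bd = rng.choice(dv, size=dv.size, replace=True).mean()
        boots[i] = bn / bd if bd != 0 else np.nan
    alpha = (1 - ci) / 2
    lo, hi = np.nanpercentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return {"ratio": ratio, "ci_low": float(lo), "ci_high": float(hi)}


@dataclass
class MetricContrast:
    metric: str
    units: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    percent_difference: float
    t: float | None = None
    p: float | None = None


def contrast(name: str, a: GroupSample, b: GroupSample) -> MetricContrast:
    """Mean/SD/percent-difference/t-test summary for one metric, A vs B."""
    t = p = None
    if a.values.size >= 2 and b.values.size >= 2:
        t, p = ttest_unpaired(a, b)
    return MetricContrast(
        metric=name,
        units=a.units,
        mean_a=float(a.values.mean()),
        mean_b=float(b.values.mean()),
        sd_a=float(a.values.std(ddof=1)) if a.values.size > 1 else 0.0,
        sd_b=float(b.values.std(ddof=1)) if b.values.size > 1 else 0.0,
        n_a=int(a.values.size),
        n_b=int(b.values.size),
        percent_difference=percent_difference(
            float(a.values.mean()), float(b.values.mean())
        ),
        t=t,
        p=p,
    )


def build_report(
    stage_outputs: dict[str, dict[str, tuple[Sequence[float], Sequence[float]]]],
    labels: tuple[str, str] = ("WT", "KO"),
    units: dict[str, str] | None = None,
    provenance: dict | None = None,
) -> dict:
    """Assemble the cross-module phenotype report.

    ``stage_outputs`` maps stage name -> {metric name -> (values_A, values_B)}.
    Produces one contrast row per metric with means, SDs, percent
    difference and t-test p, plus embedded provenance.
    """
    if not stage_outputs:
        raise DataError("no stage outputs supplied")
    units = units or {}
    rows = []
    for stage, metrics in stage_outputs.items():
        for metric, (va, vb) in metrics.items():
            unit = units.get(metric, "")
            c = contrast(
                metric,
                GroupSample(labels[0], np.asarray(list(va), dtype=float), unit),
                GroupSample(labels[1], np.asarray(list(vb), dtype=float), unit),
            )
            row = {"stage": stage, **c.__dict__}
            rows.append(row)
    return {
        "groups": labels,
        "contrasts": rows,
        "provenance": provenance or {},
    }
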
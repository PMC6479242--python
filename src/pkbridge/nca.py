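"""Noncompartmental analysis (NCA) of single-dose concentration-time profiles.

Exposure metrics follow the standard clinical-PK definitions: Cmax/Tmax are
the observed maximum and its (earliest) time; AUC0-t uses the linear
trapezoidal rule up to the last quantifiable concentration; AUC0-inf adds the
extrapolated tail Clast/lambda_z; lambda_z is the negative slope of a
log-linear least-squares fit to the terminal points, with the terminal window
chosen by the best-adjusted-R^2 rule (the WinNonlin-equivalent "best fit"
convention, since window selection is rarely reported explicitly).

Interior zero concentrations are kept in the trapezoids (the piecewise-linear
interpolant is well defined there) but excluded from the log-linear
regression, whose model is only defined for positive concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np

from .study_data import ConcTimeProfile

__all__ = [
    "UndefinedMetricError",
    "NCAResult",
    "ArmSummary",
    "LambdaZSelection",
    "cmax_tmax",
    "auc_trapezoid",
    "estimate_lambda_z",
    "t_half",
    "auc_to_infinity",
    "dose_normalize",
    "early_exposure_fraction",
    "run_nca",
    "summarize_arm",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for this profile (e.g. all-zero concentrations)."""


@dataclass(frozen=True)
class LambdaZSelection:
    """Terminal-window selection policy for the lambda_z regression.

    ``n_points`` forces a manual window (the last ``n_points`` usable
    points); otherwise all suffix windows of >= ``min_points`` consecutive
    usable points strictly after Tmax are scored by adjusted R^2 and the best
    wins; ties within ``r2_tol`` go to the window with more points.
    """

    min_points: int = 3
    n_points: int | None = None
    r2_tol: float = 1e-4


@dataclass
class NCAResult:
    """Per-profile exposure metrics; undefined metrics are ``None``."""

    subject_id: str | None = None
    treatment: str | None = None
    period: int | None = None
    cmax: float | None = None
    tmax: float | None = None
    auc_last: float | None = None
    auc_inf: float | None = None
    clast: float | None = None
    tlast: float | None = None
    lambda_z: float | None = None
    t_half: float | None = None
    n_lambda_points: int | None = None
    r2_adj: float | None = None
    dn_cmax: float | None = None
    dn_auc_last: float | None = None
    early_fraction: float | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ArmSummary:
    """Arm-level descriptive statistics for one metric (Table-style row)."""

    metric: str
    n: int
    mean: float | None = None
    cv_pct: float | None = None
    median: float | None = None
    min: float | None = None
    max: float | None = None
    geo_mean: float | None = None


def cmax_tmax(profile: ConcTimeProfile) -> tuple[float, float]:
    """Maximum observed concentration and the earliest time attaining it."""
    conc = profile.conc_array
    if not np.any(conc > 0):
        raise UndefinedMetricError("all concentrations are zero")
    i = int(np.argmax(conc))  # argmax returns the first maximal index
    return float(conc[i]), float(profile.times[i])


def auc_trapezoid(profile: ConcTimeProfile, t_start: float, t_end: float) -> float:
    """Linear-trapezoidal AUC over [t_start, t_end] (ng.h/mL).

    Boundary values at non-sampling times are obtained by linear
    interpolation; the window must lie within the observed time range.
    """
    t = profile.times_array
    c = profile.conc_array
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise ValueError(
            f"window [{t_start}, {t_end}] outside observed range [{t[0]}, {t[-1]}]"
        )
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    cc = np.concatenate(([np.interp(t_start, t, c)], c[inside], [np.interp(t_end, t, c)]))
    return float(np.trapezoid(cc, tt))


def _tlast_clast(profile: ConcTimeProfile) -> tuple[float, float]:
    """Time and value of the last quantifiable (positive) concentration."""
    c = profile.conc_array
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        raise UndefinedMetricError("no quantifiable concentration")
    i = int(pos[-1])
    return float(profile.times[i]), float(c[i])


def _adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def estimate_lambda_z(
    profile: ConcTimeProfile,
    selection: LambdaZSelection | None = None,
) -> tuple[float, int, float]:
    """Terminal elimination rate constant lambda_z (1/h).

    Returns ``(lambda_z, n_points, r2_adj)``.  lambda_z is minus the slope of
    the least-squares regression of ln(concentration) on time over the
    selected terminal window; only positive concentrations strictly after
    Tmax are usable.  Raises :class:`UndefinedMetricError` when no candidate
    window of >= 3 points yields a positive lambda_z.
    """
    sel = selection or LambdaZSelection()
    _, tmax = cmax_tmax(profile)
    t = profile.times_array
    c = profile.conc_array
    usable = (t > tmax) & (c > 0)
    tu, cu = t[usable], np.log(c[usable])

    if tu.size < sel.min_points:
        raise UndefinedMetricError(
            f"only {tu.size} positive post-Tmax points; need >= {sel.min_points}"
        )

    if sel.n_points is not None:
        if sel.n_points < sel.min_points or sel.n_points > tu.size:
            raise UndefinedMetricError(f"cannot use manual window of {sel.n_points} points")
        starts: Iterable[int] = [tu.size - sel.n_points]
    else:
        starts = range(tu.size - sel.min_points + 1)

    best: tuple[float, int, float] | None = None  # (r2_adj, n, lambda_z)
    for s in starts:
        x, y = tu[s:], cu[s:]
        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        r2a = _adjusted_r2(r2, n)
        if best is None or r2a > best[0] + sel.r2_tol or (
            abs(r2a - best[0]) <= sel.r2_tol and n > best[1]
        ):
            best = (r2a, n, float(-slope))
    if best is None:
        raise UndefinedMetricError("no terminal window with a negative slope")
    r2a, n, lz = best
    return lz, n, r2a


def t_half(lambda_z: float) -> float:
    """Terminal half-life ln(2)/lambda_z (h)."""
    if lambda_z <= 0:
        raise ValueError("lambda_z must be > 0")
    return math.log(2.0) / lambda_z


def auc_to_infinity(auc_last: float, clast: float, lambda_z: float) -> float:
    """AUC extrapolated to infinity: AUC0-t + Clast/lambda_z."""
    if clast <= 0:
        raise UndefinedMetricError("Clast must be > 0 to extrapolate")
    if lambda_z <= 0:
        raise UndefinedMetricError("lambda_z must be > 0 to extrapolate")
    return auc_last + clast / lambda_z


def dose_normalize(value: float, dose_mg: float) -> float:
    """Divide an exposure metric by the administered dose (per-mg metric)."""
    if dose_mg <= 0:
        raise ValueError("dose_mg must be > 0")
    return value / dose_mg


def early_exposure_fraction(profile: ConcTimeProfile, window_end: float = 10.0) -> float:
    """Percent of AUC0-t accrued in the first ``window_end`` hours.

    For an evening-dosed delayed-release formulation this quantifies
    overnight drug exposure (the 0-10 h window after a 8-9 PM dose spans the
    night).  Denominator is AUC0-t.
    """
    tlast, _ = _tlast_clast(profile)
    auc_last = auc_trapezoid(profile, profile.times[0], tlast)
    if auc_last <= 0:
        raise UndefinedMetricError("AUC0-t is zero")
    early = auc_trapezoid(profile, profile.times[0], min(window_end, tlast))
    return 100.0 * min(early / auc_last, 1.0)


def run_nca(
    profile: ConcTimeProfile,
    dose_mg: float | None = None,
    early_window: float | None = 10.0,
    selection: LambdaZSelection | None = None,
) -> NCAResult:
    """Full NCA for one profile; metrics that cannot be computed are None."""
    res = NCAResult(
        subject_id=profile.subject_id, treatment=profile.treatment, period=profile.period
    )
    try:
        res.cmax, res.tmax = cmax_tmax(profile)
    except UndefinedMetricError:
        return res
    res.tlast, res.clast = _tlast_clast(profile)
    res.auc_last = auc_trapezoid(profile, profile.times[0], res.tlast)
    try:
        res.lambda_z, res.n_lambda_points, res.r2_adj = estimate_lambda_z(profile, selection)
        res.t_half = t_half(res.lambda_z)
        res.auc_inf = auc_to_infinity(res.auc_last, res.clast, res.lambda_z)
    except UndefinedMetricError:
        pass
    if dose_mg is not None:
        res.dn_cmax = dose_normalize(res.cmax, dose_mg)
        res.dn_auc_last = dose_normalize(res.auc_last, dose_mg)
    if early_window is not None and res.tlast > early_window:
        res.early_fraction = early_exposure_fraction(profile, early_window)
    return res


def summarize_arm(results: Sequence[NCAResult] | Sequence[float], metric: str) -> ArmSummary:
    """Descriptive statistics of one metric across an arm's subjects.

    ``results`` may be NCAResult objects (the named metric is extracted) or a
    bare sequence of values.  Missing (None/NaN) values are dropped; an
    all-missing arm yields an empty summary with n = 0.  CV% is
    100 * sample SD / mean; the geometric mean requires all values positive.
    """
    if results and isinstance(results[0], NCAResult):
        values = [getattr(r, metric) for r in results]  # type: ignore[union-attr]
    else:
        values = list(results)  # type: ignore[arg-type]
    vals = np.array([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return ArmSummary(metric=metric, n=0)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ArmSummary(
        metric=metric,
        n=int(vals.size),
        mean=mean,
        cv_pct=100.0 * sd / mean if mean != 0 else None,
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        geo_mean=float(np.exp(np.mean(np.log(vals)))) if np.all(vals > 0) else None,
    )
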
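"""Per-feature oscillator fitting and significance machinery.

Fitting is multi-start nonlinear least squares. The start grid scans
candidate periods at a fixed step; at each candidate period the phase,
amplitude and baseline are profiled out by linear least squares (the model
is linear in ``A*cos``, ``A*sin`` and ``y0`` once the period is fixed and
the AC coefficient is pinned at zero), which replaces an explicit phase
grid with its exact optimum. The best screened periods seed full 5-parameter
refinements via trust-region least squares; extra starts with nonzero AC
coefficient guard against strongly damped or forced envelopes. The whole
procedure is deterministic: no randomness enters the fit.

Significance is a nested F-test of the fitted trend against the
intercept-only model, followed by Benjamini–Hochberg adjustment across
features. The free-run fit places no prior restriction on the period;
circadian calls are made *after* fitting by restricting to a period window
and a q-value cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats import multitest

from .models import (
    AcCategory,
    CIRCADIAN_CATEGORIES,
    EchoLinearParams,
    EchoParams,
    ExponentialParams,
    LinearParams,
    TrendParams,
    classify_ac,
    evaluate_trend,
    peak_time,
)
from .preprocess import Design

__all__ = [
    "FitResult",
    "fit_echo",
    "significance",
    "bh_adjust",
    "postrun_restrict",
    "rmse_of",
    "results_frame",
    "free_run_bounds",
    "n_free_params",
]

_TWO_PI = 2.0 * math.pi

#: Nonlinear-refinement bounds on the AC coefficient (1/h); wide enough to
#: reach well into the extreme (overexpressed/repressed) bands.
DEFAULT_GAMMA_BOUNDS = (-3.0, 3.0)
#: Additional AC-coefficient start values tried at the best screened period.
DEFAULT_GAMMA_STARTS = (0.4, -0.4)


@dataclass
class FitResult:
    """One feature's model fit.

    ``bh_q`` is NaN until :func:`bh_adjust` has been applied across the
    result set. ``ac_category`` is populated only for oscillatory models.
    """

    feature_id: str
    model: str  # "echo", "echo_linear", "linear", "exponential"
    params: TrendParams
    rss: float
    n_obs: int
    p_value: float
    bh_q: float
    converged: bool
    ac_category: Optional[AcCategory] = None

    @property
    def rmse(self) -> float:
        return math.sqrt(self.rss / self.n_obs)

    @property
    def period(self) -> Optional[float]:
        if isinstance(self.params, EchoParams):
            return self.params.period
        if isinstance(self.params, EchoLinearParams):
            return self.params.echo.period
        return None

    @property
    def is_oscillatory(self) -> bool:
        return isinstance(self.params, (EchoParams, EchoLinearParams))


def n_free_params(model: str) -> int:
    """Free-parameter count per trend-library member."""
    return {"linear": 2, "exponential": 3, "echo": 5, "echo_linear": 6}[model]


def free_run_bounds(design: Design) -> Tuple[float, float]:
    """Default free-run period bounds: [2 * sampling interval, time span].

    A "no period restriction" fit still needs numeric limits; twice the
    sampling interval is the shortest resolvable period and the time span
    the longest observable one.
    """
    tp = design.timepoints
    if tp.size < 3:
        raise ValueError("need at least 3 timepoints for a free-run fit")
    dt = float(np.min(np.diff(tp)))
    span = float(tp[-1] - tp[0])
    return (2.0 * dt, span)


def _screen_periods(
    t: np.ndarray, y: np.ndarray, periods: np.ndarray, slope_term: bool = False
) -> np.ndarray:
    """RSS of the zero-AC harmonic regression at each candidate period.

    Returns an array of shape (len(periods), 4 or 5): rss, a, b, y0[, m]
    where the fitted curve is a*cos(w t) + b*sin(w t) + y0 [+ m*t].
    """
    n_extra = 2 if slope_term else 1
    out = np.empty((periods.size, 3 + n_extra))
    ones = np.ones_like(t)
    for j, tau in enumerate(periods):
        w = _TWO_PI / tau
        cols = [np.cos(w * t), np.sin(w * t), ones]
        if slope_term:
            cols.append(t)
        X = np.column_stack(cols)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        out[j, 0] = resid @ resid
        out[j, 1:] = coef
    return out


def _ab_to_amp_phase(a: float, b: float) -> Tuple[float, float]:
    """Convert a*cos + b*sin to A*cos(. + phi): A=hypot(a,b), phi=atan2(-b,a)."""
    return math.hypot(a, b), math.atan2(-b, a)


def _echo_residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray, slope_term: bool):
    amp, gamma, tau, phi, y0 = theta[:5]
    pred = amp * np.exp(-gamma * t / 2.0) * np.cos(_TWO_PI * t / tau + phi) + y0
    if slope_term:
        pred = pred + theta[5] * t
    return pred - y


def _refine(
    start: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    period_bounds: Tuple[float, float],
    gamma_bounds: Tuple[float, float],
    slope_term: bool,
):
    lo = [0.0, gamma_bounds[0], period_bounds[0], -_TWO_PI, -np.inf]
    hi = [np.inf, gamma_bounds[1], period_bounds[1], 2 * _TWO_PI, np.inf]
    if slope_term:
        lo.append(-np.inf)
        hi.append(np.inf)
    start = np.clip(start, lo, hi)
    return optimize.least_squares(
        _echo_residuals,
        start,
        bounds=(lo, hi),
        args=(t, y, slope_term),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=400,
    )


def fit_echo(
    series: Sequence[float],
    design: Design,
    feature_id: str = "",
    period_bounds: Optional[Tuple[float, float]] = None,
    period_step: float = 2.0,
    n_starts: int = 3,
    gamma_bounds: Tuple[float, float] = DEFAULT_GAMMA_BOUNDS,
    gamma_starts: Sequence[float] = DEFAULT_GAMMA_STARTS,
    slope_term: bool = False,
    harmonic_cutoff: float = 0.15,
    extreme_cutoff: float = 1.0,
) -> FitResult:
    """Fit the damped oscillator to one feature's series (all replicates).

    Parameters
    ----------
    series
        Complete (post-preprocessing) values, one per design sample.
    period_bounds
        (lo, hi) hours; defaults to the free-run bounds for the design.
    period_step
        Spacing of the period screening grid, hours.
    n_starts
        Number of best-screened periods carried into nonlinear refinement.
    slope_term
        Fit the oscillator-plus-linear-trend variant instead.

    Returns the lowest-RSS converged refinement, with a nested F-test
    p-value against the intercept-only model. If no start converges the
    best screened evaluation is returned with ``converged=False``.
    """
    t = design.times
    y = np.asarray(series, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series length must match the design")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains missing values; preprocess first")
    if period_bounds is None:
        period_bounds = free_run_bounds(design)
    lo_p, hi_p = period_bounds
    if not (0 < lo_p < hi_p):
        raise ValueError(f"invalid period bounds {period_bounds}")

    periods = np.arange(lo_p, hi_p + 1e-9, period_step)
    if periods.size == 0 or periods[-1] < hi_p - 1e-9:
        periods = np.append(periods, hi_p)
    screen = _screen_periods(t, y, periods, slope_term=slope_term)
    order = np.argsort(screen[:, 0], kind="stable")

    starts = []
    for rank, j in enumerate(order[: max(1, n_starts)]):
        amp, phi = _ab_to_amp_phase(screen[j, 1], screen[j, 2])
        base = [amp, 0.0, periods[j], phi % _TWO_PI, screen[j, 3]]
        if slope_term:
            base.append(screen[j, 4])
        starts.append(np.array(base))
        if rank == 0:
            for g in gamma_starts:
                s = np.array(base)
                s[1] = g
                starts.append(s)

    best = None
    for s in starts:
        try:
            res = _refine(s, t, y, period_bounds, gamma_bounds, slope_term)
        except Exception:  # numerical failure of one start is not fatal
            continue
        if not res.success:
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res.x)

    converged = best is not None
    if converged:
        rss, theta = best
    else:
        j = order[0]
        amp, phi = _ab_to_amp_phase(screen[j, 1], screen[j, 2])
        theta = np.array(
            [amp, 0.0, periods[j], phi % _TWO_PI, screen[j, 3]]
            + ([screen[j, 4]] if slope_term else [])
        )
        rss = float(screen[j, 0])

    echo = EchoParams(
        amplitude=float(theta[0]),
        ac_coefficient=float(theta[1]),
        period=float(theta[2]),
        phase=float(theta[3]),
        baseline=float(theta[4]),
    )
    params: TrendParams
    model = "echo_linear" if slope_term else "echo"
    if slope_term:
        params = EchoLinearParams(echo=echo, slope=float(theta[5]))
    else:
        params = echo

    n = y.size
    k = n_free_params(model)
    p = significance(rss, _null_rss(y), n, k)
    return FitResult(
        feature_id=feature_id,
        model=model,
        params=params,
        rss=rss,
        n_obs=n,
        p_value=p,
        bh_q=float("nan"),
        converged=converged,
        ac_category=classify_ac(echo.ac_coefficient, harmonic_cutoff, extreme_cutoff),
    )


def _null_rss(y: np.ndarray) -> float:
    resid = y - y.mean()
    return float(resid @ resid)


def significance(rss1: float, rss0: float, n: int, k: int) -> float:
    """Nested F-test of a k-parameter trend against the intercept-only model.

    ``F = ((rss0 - rss1)/(k - 1)) / (rss1/(n - k))`` with p from the upper
    tail of F(k-1, n-k). A perfect fit (rss1 = 0) gives p = 0; a fit no
    better than the mean gives p = 1.
    """
    if n <= k:
        raise ValueError(f"F-test undefined: n={n} <= k={k}")
    if rss1 < 0 or rss0 < 0:
        raise ValueError("residual sums of squares must be non-negative")
    if rss1 == 0:
        return 0.0
    f = ((rss0 - rss1) / (k - 1)) / (rss1 / (n - k))
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, k - 1, n - k))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multitest.multipletests(p, method="fdr_bh")[1]


def attach_bh_q(results: Sequence[FitResult]) -> list[FitResult]:
    """Return results with BH q-values computed across the whole set."""
    q = bh_adjust([r.p_value for r in results])
    return [replace(r, bh_q=float(qi)) for r, qi in zip(results, q)]


def postrun_restrict(
    results: Sequence[FitResult],
    period_window: Tuple[float, float],
    q_cutoff: float = 0.05,
) -> list[FitResult]:
    """Post-fit circadian call: period window, q-value and AC category.

    Keeps exactly the oscillatory fits with ``lo <= period <= hi``
    (inclusive bounds), ``bh_q < q_cutoff`` (strict) and an AC category in
    the circadian set (damped/harmonic/forced). Applied after a free-run
    fit, this is what turns "rhythmic" into "circadian".
    """
    lo, hi = period_window
    if lo > hi:
        raise ValueError(f"invalid period window ({lo}, {hi})")
    kept = []
    for r in results:
        if not r.is_oscillatory:
            continue
        tau = r.period
        if tau is None or not (lo <= tau <= hi):
            continue
        if not (r.bh_q < q_cutoff):
            continue
        if r.ac_category not in CIRCADIAN_CATEGORIES:
            continue
        kept.append(r)
    return kept


def rmse_of(fit: FitResult, series: Sequence[float], design: Design) -> float:
    """Root mean squared residual of a fit over all fitted points."""
    y = np.asarray(series, dtype=float)
    resid = evaluate_trend(fit.params, design.times) - y
    return float(np.sqrt(np.mean(resid**2)))


def results_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Tabulate fit results, one row per feature (per channel upstream)."""
    rows = []
    for r in results:
        row = {
            "feature_id": r.feature_id,
            "model": r.model,
            "period_h": r.period,
            "phase_rad": None,
            "peak_time_h": None,
            "amplitude": None,
            "ac_coefficient": None,
            "ac_category": r.ac_category.value if r.ac_category else None,
            "baseline": None,
            "slope": None,
            "rss": r.rss,
            "rmse": r.rmse,
            "p_value": r.p_value,
            "bh_q": r.bh_q,
            "converged": r.converged,
        }
        p = r.params
        echo = None
        if isinstance(p, EchoParams):
            echo = p
        elif isinstance(p, EchoLinearParams):
            echo = p.echo
            row["slope"] = p.slope
        elif isinstance(p, LinearParams):
            row["slope"] = p.slope
            row["baseline"] = p.intercept
        elif isinstance(p, ExponentialParams):
            row["amplitude"] = p.scale
            row["slope"] = p.rate
            row["baseline"] = p.offset
        if echo is not None:
            row.update(
                phase_rad=echo.phase,
                amplitude=echo.amplitude,
                ac_coefficient=echo.ac_coefficient,
                baseline=echo.baseline,
                peak_time_h=peak_time(echo) if echo.amplitude > 0 else None,
            )
        rows.append(row)
    return pd.DataFrame(rows)
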
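"""Trend-model library and joint modeling of paired omics channels.

Beyond the plain oscillator, each feature can follow a non-oscillatory
trend (linear, exponential) or an oscillator superimposed on a linear
trend. The library is fitted per feature and the winner chosen by BIC.

Joint modeling addresses a noisy channel (typically protein) paired with a
cleaner one (typically RNA) for the same gene: both channels are fitted in
a single weighted least-squares problem that shares the period and phase
while keeping per-channel amplitude, AC coefficient, baseline (and slope,
for the linear variants). Channels are weighted by inverse residual
variance from their independent fits, with one reweighting iteration. An
oscillation that only reaches significance under this coupling is labeled
"ECHO Joint" (or "ECHO Linear Joint") — the rhythm is real but drowned in
channel noise when the channel is fitted alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .fitting import (
    FitResult,
    _null_rss,
    fit_echo,
    free_run_bounds,
    n_free_params,
    significance,
)
from .models import (
    AcCategory,
    CIRCADIAN_CATEGORIES,
    EchoLinearParams,
    EchoParams,
    ExponentialParams,
    LinearParams,
    classify_ac,
    evaluate_trend,
)
from .preprocess import Design

__all__ = [
    "TREND_LABELS",
    "JointFitResult",
    "fit_trend_library",
    "fit_joint",
    "assign_trend_label",
    "trend_distribution",
    "bic",
]

_TWO_PI = 2.0 * math.pi

#: The six trend categories assigned to significant features.
TREND_LABELS = (
    "Linear",
    "Exponential",
    "ECHO",
    "ECHO Joint",
    "ECHO Linear",
    "ECHO Linear Joint",
)

#: Bound on the exponential rate (1/h) to keep exp(k*t) finite over a
#: multi-day time course.
EXP_RATE_BOUND = 1.0

# RSS floor used inside BIC: below ~machine precision per point, fits are
# numerically tied and the parameter-count penalty should decide.
_BIC_RSS_FLOOR = 1e-18


def bic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood BIC: n*ln(rss/n) + k*ln(n), with an RSS floor
    so numerically-zero residuals compare by parameter count."""
    mean_sq = max(rss / n, _BIC_RSS_FLOOR)
    return n * math.log(mean_sq) + k * math.log(n)


def _fit_linear(t: np.ndarray, y: np.ndarray, feature_id: str) -> FitResult:
    X = np.column_stack([t, np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n, k = y.size, n_free_params("linear")
    return FitResult(
        feature_id=feature_id,
        model="linear",
        params=LinearParams(slope=float(coef[0]), intercept=float(coef[1])),
        rss=rss,
        n_obs=n,
        p_value=significance(rss, _null_rss(y), n, k),
        bh_q=float("nan"),
        converged=True,
    )


def _exp_residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, k, c = theta
    return a * np.exp(k * t) + c - y


def _fit_exponential(t: np.ndarray, y: np.ndarray, feature_id: str) -> FitResult:
    # Profile the rate: for fixed k the model is linear in (a, c).
    k_grid = np.array([-0.5, -0.2, -0.05, -0.01, 0.01, 0.05, 0.2, 0.5])
    best_start = None
    for k in k_grid:
        X = np.column_stack([np.exp(k * t), np.ones_like(t)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        if best_start is None or rss < best_start[0]:
            best_start = (rss, np.array([coef[0], k, coef[1]]))
    converged = False
    theta = best_start[1]
    rss = best_start[0]
    try:
        res = optimize.least_squares(
            _exp_residuals,
            best_start[1],
            bounds=([-np.inf, -EXP_RATE_BOUND, -np.inf], [np.inf, EXP_RATE_BOUND, np.inf]),
            args=(t, y),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=200,
        )
        if res.success and np.all(np.isfinite(res.x)):
            converged = True
            theta = res.x
            rss = float(res.fun @ res.fun)
    except Exception:
        pass
    n, k = y.size, n_free_params("exponential")
    return FitResult(
        feature_id=feature_id,
        model="exponential",
        params=ExponentialParams(scale=float(theta[0]), rate=float(theta[1]), offset=float(theta[2])),
        rss=rss,
        n_obs=n,
        p_value=significance(rss, _null_rss(y), n, k),
        bh_q=float("nan"),
        converged=converged,
    )


def fit_trend_library(
    series: Sequence[float],
    design: Design,
    feature_id: str = "",
    period_bounds: Optional[Tuple[float, float]] = None,
    **echo_kwargs,
) -> Tuple[FitResult, Dict[str, FitResult]]:
    """Fit every trend-library member and select the best by BIC.

    Returns ``(best, candidates)`` where ``candidates`` maps model tags to
    their fits for audit. Non-converged candidates are kept in the
    dictionary but excluded from selection (unless nothing converged, in
    which case the lowest-BIC candidate is returned regardless).
    """
    t = design.times
    y = np.asarray(series, dtype=float)
    candidates = {
        "linear": _fit_linear(t, y, feature_id),
        "exponential": _fit_exponential(t, y, feature_id),
        "echo": fit_echo(y, design, feature_id, period_bounds=period_bounds, **echo_kwargs),
        "echo_linear": fit_echo(
            y, design, feature_id, period_bounds=period_bounds, slope_term=True, **echo_kwargs
        ),
    }
    pool = [c for c in candidates.values() if c.converged] or list(candidates.values())
    best = min(pool, key=lambda c: bic(c.rss, c.n_obs, n_free_params(c.model)))
    return best, candidates


@dataclass
class JointFitResult:
    """Joint fit of one feature across two channels sharing period and phase.

    ``channel_fits`` holds per-channel :class:`FitResult` objects whose
    oscillator parameters embed the shared period/phase; ``weights`` are
    the inverse-residual-variance channel weights of the final iteration.
    """

    feature_id: str
    period: float
    phase: float
    channel_fits: Dict[str, FitResult]
    weights: Dict[str, float]
    converged: bool

    @property
    def channels(self) -> Tuple[str, ...]:
        return tuple(self.channel_fits)


def _joint_residuals(
    theta: np.ndarray,
    designs: Sequence[np.ndarray],
    series: Sequence[np.ndarray],
    sqrt_w: Sequence[float],
    slope_term: bool,
) -> np.ndarray:
    """Stacked weighted residuals. theta = [tau, phi, then per channel
    (A, gamma, y0[, m])]."""
    tau, phi = theta[0], theta[1]
    per = 4 if slope_term else 3
    out = []
    for c, (t, y) in enumerate(zip(designs, series)):
        block = theta[2 + c * per : 2 + (c + 1) * per]
        amp, gamma, y0 = block[0], block[1], block[2]
        pred = amp * np.exp(-gamma * t / 2.0) * np.cos(_TWO_PI * t / tau + phi) + y0
        if slope_term:
            pred = pred + block[3] * t
        out.append(sqrt_w[c] * (pred - y))
    return np.concatenate(out)


def _extract_echo(fit: FitResult) -> Tuple[EchoParams, float]:
    if isinstance(fit.params, EchoParams):
        return fit.params, 0.0
    if isinstance(fit.params, EchoLinearParams):
        return fit.params.echo, fit.params.slope
    raise TypeError("independent fit is not oscillatory")


def fit_joint(
    series_by_channel: Mapping[str, Sequence[float]],
    designs_by_channel: Mapping[str, Design],
    feature_id: str = "",
    slope_term: bool = False,
    period_bounds: Optional[Tuple[float, float]] = None,
    independent_fits: Optional[Mapping[str, FitResult]] = None,
    gamma_bounds: Tuple[float, float] = (-3.0, 3.0),
    n_reweight: int = 1,
    harmonic_cutoff: float = 0.15,
    extreme_cutoff: float = 1.0,
) -> JointFitResult:
    """Weighted joint oscillator fit sharing period and phase across channels.

    Channel weights start at the inverse residual variance of each
    channel's independent fit and are re-estimated once from the joint
    residuals (``n_reweight`` iterations). Per-channel p-values come from a
    nested F-test of that channel's joint-model residuals against its
    intercept-only model. If a channel has (numerically) zero variance the
    joint problem is ill-posed and the independent fits are returned with a
    warning.
    """
    channels = list(series_by_channel)
    if len(channels) != 2:
        raise ValueError("joint fitting expects exactly two channels")
    series = {c: np.asarray(series_by_channel[c], dtype=float) for c in channels}
    designs = {c: designs_by_channel[c] for c in channels}
    for c in channels:
        if series[c].shape != designs[c].times.shape:
            raise ValueError(f"channel {c!r}: series length must match its design")
    if period_bounds is None:
        period_bounds = free_run_bounds(designs[channels[0]])

    if independent_fits is None:
        independent_fits = {
            c: fit_echo(
                series[c],
                designs[c],
                feature_id,
                period_bounds=period_bounds,
                slope_term=slope_term,
                gamma_bounds=gamma_bounds,
                harmonic_cutoff=harmonic_cutoff,
                extreme_cutoff=extreme_cutoff,
            )
            for c in channels
        }

    variances = {c: float(np.var(series[c])) for c in channels}
    if any(v <= 1e-24 for v in variances.values()):
        warnings.warn(
            f"feature {feature_id!r}: a channel has zero variance; "
            "falling back to independent fits"
        )
        fits = dict(independent_fits)
        anchor, _ = _extract_echo(max(fits.values(), key=lambda f: f.rss))
        return JointFitResult(
            feature_id=feature_id,
            period=anchor.period,
            phase=anchor.phase,
            channel_fits=fits,
            weights={c: 1.0 for c in channels},
            converged=False,
        )

    weights = {}
    for c in channels:
        resid_var = independent_fits[c].rss / independent_fits[c].n_obs
        weights[c] = 1.0 / max(resid_var, 1e-12)

    # Anchor the shared period/phase on the higher-weight (cleaner) channel.
    anchor_channel = max(channels, key=lambda c: weights[c])
    anchor_echo, _ = _extract_echo(independent_fits[anchor_channel])

    per = 4 if slope_term else 3
    theta0 = [anchor_echo.period, anchor_echo.phase]
    lo = [period_bounds[0], -_TWO_PI]
    hi = [period_bounds[1], 2 * _TWO_PI]
    for c in channels:
        echo_c, slope_c = _extract_echo(independent_fits[c])
        theta0 += [echo_c.amplitude, echo_c.ac_coefficient, echo_c.baseline]
        lo += [0.0, gamma_bounds[0], -np.inf]
        hi += [np.inf, gamma_bounds[1], np.inf]
        if slope_term:
            theta0.append(slope_c)
            lo.append(-np.inf)
            hi.append(np.inf)
    theta0 = np.clip(np.asarray(theta0, dtype=float), lo, hi)

    t_list = [designs[c].times for c in channels]
    y_list = [series[c] for c in channels]
    theta = theta0
    converged = False
    for _ in range(max(1, n_reweight + 1)):
        sqrt_w = [math.sqrt(weights[c]) for c in channels]
        try:
            res = optimize.least_squares(
                _joint_residuals,
                theta,
                bounds=(lo, hi),
                args=(t_list, y_list, sqrt_w, slope_term),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                max_nfev=400,
            )
        except Exception:
            break
        if not res.success:
            break
        converged = True
        theta = res.x
        # Re-estimate channel weights from the joint residuals.
        for c_idx, c in enumerate(channels):
            block = theta[2 + c_idx * per : 2 + (c_idx + 1) * per]
            pred = (
                block[0]
                * np.exp(-block[1] * t_list[c_idx] / 2.0)
                * np.cos(_TWO_PI * t_list[c_idx] / theta[0] + theta[1])
                + block[2]
            )
            if slope_term:
                pred = pred + block[3] * t_list[c_idx]
            resid = pred - y_list[c_idx]
            weights[c] = 1.0 / max(float(resid @ resid) / resid.size, 1e-12)

    tau, phi = float(theta[0]), float(theta[1])
    channel_fits: Dict[str, FitResult] = {}
    for c_idx, c in enumerate(channels):
        block = theta[2 + c_idx * per : 2 + (c_idx + 1) * per]
        echo = EchoParams(
            amplitude=float(block[0]),
            ac_coefficient=float(block[1]),
            period=tau,
            phase=phi,
            baseline=float(block[2]),
        )
        params = EchoLinearParams(echo=echo, slope=float(block[3])) if slope_term else echo
        y = y_list[c_idx]
        resid = evaluate_trend(params, t_list[c_idx]) - y
        rss = float(resid @ resid)
        n = y.size
        k = n_free_params("echo_linear" if slope_term else "echo")
        channel_fits[c] = FitResult(
            feature_id=feature_id,
            model="echo_linear_joint" if slope_term else "echo_joint",
            params=params,
            rss=rss,
            n_obs=n,
            p_value=significance(rss, _null_rss(y), n, k),
            bh_q=float("nan"),
            converged=converged,
            ac_category=classify_ac(echo.ac_coefficient, harmonic_cutoff, extreme_cutoff),
        )
    # Report the normalized phase from the constructed params (phi may have
    # left [0, 2pi) during optimization).
    phi_norm = _extract_echo(channel_fits[channels[0]])[0].phase
    return JointFitResult(
        feature_id=feature_id,
        period=tau,
        phase=phi_norm,
        channel_fits=channel_fits,
        weights=dict(weights),
        converged=converged,
    )


def _circadian_call(
    fit: FitResult, period_window: Optional[Tuple[float, float]], q_cutoff: float
) -> bool:
    """Significant oscillation inside the circadian window with a circadian AC."""
    if not (fit.bh_q < q_cutoff):
        return False
    tau = fit.period
    if tau is None:
        return False
    if period_window is not None and not (period_window[0] <= tau <= period_window[1]):
        return False
    return fit.ac_category in CIRCADIAN_CATEGORIES


def assign_trend_label(
    independent_best: FitResult,
    joint_fit: Optional[FitResult],
    q_cutoff: float = 0.05,
    period_window: Optional[Tuple[float, float]] = None,
) -> Optional[str]:
    """Assign one of the six trend labels to a channel (or None).

    Priority: an independently significant oscillation is "ECHO" /
    "ECHO Linear"; an oscillation only significant under joint modeling is
    "ECHO Joint" / "ECHO Linear Joint"; otherwise a significant
    non-oscillatory winner keeps its own name; otherwise unlabeled.
    """
    if independent_best.is_oscillatory and _circadian_call(
        independent_best, period_window, q_cutoff
    ):
        return "ECHO Linear" if independent_best.model == "echo_linear" else "ECHO"
    if joint_fit is not None and _circadian_call(joint_fit, period_window, q_cutoff):
        return (
            "ECHO Linear Joint"
            if joint_fit.model in ("echo_linear", "echo_linear_joint")
            else "ECHO Joint"
        )
    if not independent_best.is_oscillatory and independent_best.bh_q < q_cutoff:
        return "Linear" if independent_best.model == "linear" else "Exponential"
    return None


def trend_distribution(labels: Sequence[Optional[str]]) -> Dict[str, Dict[str, float]]:
    """Counts and percentages per trend category over the labeled features.

    Unlabeled (None) entries are excluded from the total; percentages are
    over labeled features and sum to 100 when any label is present.
    """
    labeled = [lab for lab in labels if lab is not None]
    total = len(labeled)
    out: Dict[str, Dict[str, float]] = {}
    for cat in TREND_LABELS:
        n = sum(1 for lab in labeled if lab == cat)
        out[cat] = {"count": n, "percent": (100.0 * n / total) if total else 0.0}
    extra = sorted(set(labeled) - set(TREND_LABELS))
    for cat in extra:
        n = sum(1 for lab in labeled if lab == cat)
        out[cat] = {"count": n, "percent": 100.0 * n / total}
    return out
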
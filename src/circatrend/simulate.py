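"""Synthetic time-course expression data with ground truth.

The generator emulates a serum-shock synchronization experiment: samples
every 2 h over 48 h with 3 replicates per timepoint, an RNA channel with
moderate noise and a protein channel with substantially higher noise.
Curves are drawn from the trend library on the z-scored scale and iid
Gaussian noise is added per sample; paired channels share the period and
phase of a common underlying rhythm while amplitude, AC coefficient and
baseline vary per channel. Every stochastic test in the package draws its
fixtures from here under a pinned seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import FitResult
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
)
from .preprocess import Design, ExpressionMatrix

__all__ = ["SimSpec", "GroundTruth", "simulate_dataset", "recovery_report"]

_TWO_PI = 2.0 * math.pi

#: Trend classes the generator knows how to draw.
SIM_CLASSES = (
    "flat",
    "oscillator",
    "harmonic",
    "damped",
    "forced",
    "linear",
    "exponential",
    "echo_linear",
)

# AC-coefficient band per named oscillator class (1/h). The plain
# "oscillator" class draws uniformly over gamma_range and takes its truth
# category from classify_ac.
_CLASS_GAMMA_BANDS = {
    "harmonic": (-0.15, 0.15),
    "damped": (0.15, 0.3),
    "forced": (-0.3, -0.15),
}


@dataclass(frozen=True)
class SimSpec:
    """Study-design parameters for the generator.

    Defaults mirror the emulated experiment: 25 timepoints (0–48 h, step
    2 h), 3 replicates, RNA noise SD 0.2 and protein noise SD 0.8 in
    z-units, circadian periods of 20–28 h, amplitudes of 0.5–2, uniform
    phases and zero baseline.
    """

    n_features: Mapping[str, int]
    timepoints: Tuple[float, ...] = tuple(float(t) for t in range(0, 49, 2))
    replicates: int = 3
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"rna": 0.2, "protein": 0.8}
    )
    period_range: Tuple[float, float] = (20.0, 28.0)
    amplitude_range: Tuple[float, float] = (0.5, 2.0)
    gamma_range: Tuple[float, float] = (-0.3, 0.3)
    slope_range: Tuple[float, float] = (-0.05, 0.05)
    exp_rate_range: Tuple[float, float] = (0.01, 0.05)
    baseline: float = 0.0
    missing_rate: float = 0.0
    paired: bool = False

    def __post_init__(self) -> None:
        for cls in self.n_features:
            if cls not in SIM_CLASSES:
                raise ValueError(f"unknown simulation class {cls!r}")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def channels(self) -> Tuple[str, ...]:
        return tuple(self.noise_sd)


@dataclass
class GroundTruth:
    """Per-feature truth labels and parameters.

    ``table`` has one row per feature with the trend class and, for
    oscillators, the true period/phase/AC category. ``params`` maps
    (feature_id, channel) to the exact :class:`TrendParams` used for that
    channel's curve.
    """

    table: pd.DataFrame
    params: Dict[Tuple[str, str], TrendParams]

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index


def _draw_echo(
    rng: np.random.Generator, spec: SimSpec, gamma_band: Tuple[float, float]
) -> EchoParams:
    return EchoParams(
        amplitude=float(rng.uniform(*spec.amplitude_range)),
        ac_coefficient=float(rng.uniform(*gamma_band)),
        period=float(rng.uniform(*spec.period_range)),
        phase=float(rng.uniform(0.0, _TWO_PI)),
        baseline=spec.baseline,
    )


def _draw_params(rng: np.random.Generator, spec: SimSpec, cls: str) -> TrendParams:
    if cls == "flat":
        return LinearParams(slope=0.0, intercept=spec.baseline)
    if cls == "linear":
        slope = float(rng.uniform(*spec.slope_range))
        if abs(slope) < 0.01:  # keep the trend distinguishable from flat
            slope = math.copysign(0.01, slope if slope != 0 else 1.0)
        return LinearParams(slope=slope, intercept=spec.baseline)
    if cls == "exponential":
        rate = float(rng.uniform(*spec.exp_rate_range)) * (1 if rng.random() < 0.5 else -1)
        return ExponentialParams(
            scale=float(rng.uniform(*spec.amplitude_range)), rate=rate, offset=spec.baseline
        )
    if cls == "echo_linear":
        echo = _draw_echo(rng, spec, spec.gamma_range)
        slope = float(rng.uniform(*spec.slope_range))
        if abs(slope) < 0.01:
            slope = math.copysign(0.01, slope if slope != 0 else 1.0)
        return EchoLinearParams(echo=echo, slope=slope)
    band = _CLASS_GAMMA_BANDS.get(cls, spec.gamma_range)
    return _draw_echo(rng, spec, band)


def _shared_variant(
    rng: np.random.Generator, spec: SimSpec, base: TrendParams
) -> TrendParams:
    """Channel-specific re-draw keeping the rhythm's period and phase."""
    if isinstance(base, EchoParams):
        return EchoParams(
            amplitude=float(rng.uniform(*spec.amplitude_range)),
            ac_coefficient=float(
                rng.uniform(*_band_of(base.ac_coefficient, spec))
            ),
            period=base.period,
            phase=base.phase,
            baseline=spec.baseline,
        )
    if isinstance(base, EchoLinearParams):
        echo = _shared_variant(rng, spec, base.echo)
        return EchoLinearParams(echo=echo, slope=base.slope)
    return base


def _band_of(gamma: float, spec: SimSpec) -> Tuple[float, float]:
    cat = classify_ac(gamma)
    return _CLASS_GAMMA_BANDS.get(cat.value, spec.gamma_range)


def _truth_category(params: TrendParams) -> Optional[str]:
    if isinstance(params, EchoParams):
        return classify_ac(params.ac_coefficient).value
    if isinstance(params, EchoLinearParams):
        return classify_ac(params.echo.ac_coefficient).value
    return None


def simulate_dataset(
    spec: SimSpec, seed: int
) -> Tuple[Dict[str, ExpressionMatrix], GroundTruth]:
    """Generate one matrix per channel plus ground truth, deterministically.

    Values are the model curve plus iid Gaussian noise (channel-specific
    SD); missingness, if requested, is applied uniformly at random before
    any filtering. The same seed always reproduces the same output.
    """
    rng = np.random.default_rng(seed)
    design = {
        ch: Design.regular(spec.timepoints, spec.replicates, channel=ch)
        for ch in spec.channels
    }
    times = design[spec.channels[0]].times

    min_presence = 0.70
    if spec.missing_rate >= 1 - min_presence:
        warnings.warn(
            f"missing_rate {spec.missing_rate} may remove features at the "
            f"{min_presence:.0%} presence filter"
        )

    feature_ids: list[str] = []
    rows_by_channel: Dict[str, list[np.ndarray]] = {ch: [] for ch in spec.channels}
    truth_rows = []
    params_map: Dict[Tuple[str, str], TrendParams] = {}

    counter = 0
    for cls in SIM_CLASSES:
        for _ in range(spec.n_features.get(cls, 0)):
            fid = f"{cls}_{counter:05d}"
            counter += 1
            feature_ids.append(fid)
            base = _draw_params(rng, spec, cls)
            per_channel: Dict[str, TrendParams] = {}
            for i, ch in enumerate(spec.channels):
                if i == 0 or not spec.paired:
                    p = base if i == 0 else _draw_params(rng, spec, cls)
                else:
                    p = _shared_variant(rng, spec, base)
                per_channel[ch] = p
                params_map[(fid, ch)] = p
                curve = evaluate_trend(p, times)
                noise = rng.normal(0.0, spec.noise_sd[ch], size=times.size)
                rows_by_channel[ch].append(curve + noise)
            first = per_channel[spec.channels[0]]
            truth_rows.append(
                {
                    "class": cls,
                    "oscillatory": isinstance(first, (EchoParams, EchoLinearParams)),
                    "category": _truth_category(first),
                    "period_h": getattr(
                        first, "period", getattr(getattr(first, "echo", None), "period", None)
                    ),
                    "phase_rad": getattr(
                        first, "phase", getattr(getattr(first, "echo", None), "phase", None)
                    ),
                }
            )

    matrices = {}
    for ch in spec.channels:
        values = np.vstack(rows_by_channel[ch]) if feature_ids else np.empty((0, times.size))
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) < spec.missing_rate
            values = np.where(mask, np.nan, values)
        frame = pd.DataFrame(
            values, index=pd.Index(feature_ids, name="id"), columns=design[ch].column_labels()
        )
        matrices[ch] = ExpressionMatrix(data=frame, design=design[ch])

    truth = GroundTruth(
        table=pd.DataFrame(truth_rows, index=pd.Index(feature_ids, name="id")),
        params=params_map,
    )
    return matrices, truth


def _circular_error_h(est_phase: float, true_phase: float, period: float) -> float:
    """Shortest angular distance between phases, expressed in hours."""
    d = (est_phase - true_phase) % _TWO_PI
    d = min(d, _TWO_PI - d)
    return d * period / _TWO_PI


def recovery_report(
    fit_results: Sequence[FitResult],
    truth: GroundTruth,
    q_cutoff: float = 0.05,
    period_window: Optional[Tuple[float, float]] = None,
) -> Dict[str, object]:
    """Compare fits to ground truth: period/phase errors, AC confusion,
    detection recall and empirical FDR at the q cutoff.

    Detection counts a feature as called when its fit is oscillatory with
    ``bh_q < q_cutoff``, a circadian AC category, and (if given) a period
    inside ``period_window``. Recall is over truly oscillatory features;
    FDR is the fraction of calls whose truth is non-oscillatory.
    """
    by_id = {r.feature_id: r for r in fit_results}
    ids = [fid for fid in truth.feature_ids if fid in by_id]
    if not ids:
        return {
            "n": 0,
            "period_mae_h": float("nan"),
            "phase_mae_h": float("nan"),
            "confusion": pd.DataFrame(),
            "recall": float("nan"),
            "fdr": float("nan"),
            "category_accuracy": float("nan"),
            "period_within_1h": float("nan"),
        }

    period_errors, phase_errors = [], []
    confusion_pairs = []
    n_true_osc = n_called = n_true_called = n_false_called = 0
    n_cat_correct = n_within_1h = 0

    for fid in ids:
        r = by_id[fid]
        row = truth.table.loc[fid]
        called = (
            r.is_oscillatory
            and r.bh_q < q_cutoff
            and r.ac_category in CIRCADIAN_CATEGORIES
            and (
                period_window is None
                or (period_window[0] <= (r.period or np.nan) <= period_window[1])
            )
        )
        n_called += int(called)
        if bool(row["oscillatory"]):
            n_true_osc += 1
            n_true_called += int(called)
            err = abs(float(r.period) - float(row["period_h"]))
            period_errors.append(err)
            n_within_1h += int(err <= 1.0)
            est_echo = r.params if isinstance(r.params, EchoParams) else r.params.echo
            phase_errors.append(
                _circular_error_h(est_echo.phase, float(row["phase_rad"]), float(row["period_h"]))
            )
            est_cat = r.ac_category.value if r.ac_category else None
            confusion_pairs.append((row["category"], est_cat))
            n_cat_correct += int(est_cat == row["category"])
        elif called:
            n_false_called += 1

    confusion = (
        pd.crosstab(
            pd.Series([t for t, _ in confusion_pairs], name="truth"),
            pd.Series([e for _, e in confusion_pairs], name="estimated"),
        )
        if confusion_pairs
        else pd.DataFrame()
    )
    return {
        "n": len(ids),
        "period_mae_h": float(np.mean(period_errors)) if period_errors else float("nan"),
        "phase_mae_h": float(np.mean(phase_errors)) if phase_errors else float("nan"),
        "confusion": confusion,
        "recall": (n_true_called / n_true_osc) if n_true_osc else float("nan"),
        "fdr": (n_false_called / n_called) if n_called else 0.0,
        "category_accuracy": (n_cat_correct / n_true_osc) if n_true_osc else float("nan"),
        "period_within_1h": (n_within_1h / n_true_osc) if n_true_osc else float("nan"),
    }
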
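"""Standard benchmark runs used for validation and reporting.

Each function simulates under the package's reference study conditions
(25 timepoints x 3 replicates), runs the full analysis path, and returns
summary metrics. Problem sizes are chosen to finish in minutes on one
core; the methods note records them.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .fitting import attach_bh_q, fit_echo
from .models import (
    CIRCADIAN_CATEGORIES,
    EchoLinearParams,
    EchoParams,
    ExponentialParams,
    LinearParams,
    evaluate_trend,
)
from .mosaic import fit_joint, fit_trend_library
from .preprocess import Design
from .simulate import SimSpec, recovery_report, simulate_dataset

__all__ = [
    "oscillator_recovery",
    "null_false_discovery",
    "joint_modeling_power",
    "noiseless_exactness",
]


def oscillator_recovery(seed: int, n_features: int = 200, noise_sd: float = 0.3) -> Dict[str, float]:
    """Period/AC recovery on simulated oscillators (AC in [-0.3, 0.3]/h,
    periods 20-28 h, amplitudes 0.5-2 z-units, stated noise SD)."""
    spec = SimSpec(n_features={"oscillator": n_features}, noise_sd={"rna": noise_sd})
    mats, truth = simulate_dataset(spec, seed)
    m = mats["rna"]
    fits = attach_bh_q(
        [fit_echo(m.data.loc[f].to_numpy(), m.design, f) for f in m.feature_ids]
    )
    rep = recovery_report(fits, truth)
    return {
        "period_within_1h": float(rep["period_within_1h"]),
        "category_accuracy": float(rep["category_accuracy"]),
        "recall": float(rep["recall"]),
        "period_mae_h": float(rep["period_mae_h"]),
        "n": n_features,
    }


def null_false_discovery(seed: int, n_features: int = 1000) -> Dict[str, float]:
    """Fraction of pure-noise features called at BH q < 0.05."""
    spec = SimSpec(n_features={"flat": n_features}, noise_sd={"rna": 1.0})
    mats, _ = simulate_dataset(spec, seed)
    m = mats["rna"]
    fits = attach_bh_q(
        [fit_echo(m.data.loc[f].to_numpy(), m.design, f) for f in m.feature_ids]
    )
    q = np.array([r.bh_q for r in fits])
    return {"bh_positive_rate": float((q < 0.05).mean()), "n": n_features}


def joint_modeling_power(
    seed: int,
    n_features: int = 200,
    rna_sd: float = 0.2,
    protein_sd: float = 0.8,
    protein_window: Tuple[float, float] = (18.0, 30.0),
) -> Dict[str, float]:
    """Protein-channel detection recall: independent fits vs joint modeling.

    Both channels share the true period and phase; the protein channel is
    noisier. Detection = BH q < 0.05, period inside the protein circadian
    window, circadian AC category.
    """
    spec = SimSpec(
        n_features={"oscillator": n_features},
        noise_sd={"rna": rna_sd, "protein": protein_sd},
        paired=True,
    )
    mats, truth = simulate_dataset(spec, seed)
    mr, mp = mats["rna"], mats["protein"]
    indep, joint = [], []
    for fid in mr.feature_ids:
        series = {"rna": mr.data.loc[fid].to_numpy(), "protein": mp.data.loc[fid].to_numpy()}
        designs = {"rna": mr.design, "protein": mp.design}
        fits = {ch: fit_echo(series[ch], designs[ch], fid) for ch in series}
        jf = fit_joint(series, designs, fid, independent_fits=fits)
        indep.append(fits["protein"])
        joint.append(jf.channel_fits["protein"])
    indep = attach_bh_q(indep)
    joint = attach_bh_q(joint)

    def recall(fits):
        lo, hi = protein_window
        hit = sum(
            1
            for r in fits
            if r.bh_q < 0.05 and lo <= r.period <= hi and r.ac_category in CIRCADIAN_CATEGORIES
        )
        return hit / len(fits)

    return {
        "independent_recall": recall(indep),
        "joint_recall": recall(joint),
        "n": n_features,
    }


def noiseless_exactness(seed: int) -> Dict[str, float]:
    """Generate-and-refit on noiseless curves for every trend-library model.

    Returns the worst relative parameter error across models (baselines and
    slopes near zero compared absolutely).
    """
    design = Design.regular(np.arange(0.0, 49.0, 2.0), 3)
    rng = np.random.default_rng(seed)
    echo = EchoParams(
        amplitude=float(rng.uniform(0.5, 2)),
        ac_coefficient=float(rng.uniform(-0.3, 0.3)),
        period=float(rng.uniform(20, 28)),
        phase=float(rng.uniform(0, 2 * np.pi)),
        baseline=0.0,
    )
    cases = {
        "linear": LinearParams(slope=float(rng.uniform(0.02, 0.1)), intercept=1.0),
        "exponential": ExponentialParams(scale=1.2, rate=float(rng.uniform(0.02, 0.05)), offset=0.3),
        "echo": echo,
        "echo_linear": EchoLinearParams(echo=echo, slope=0.2),
    }

    def rel_err(est: float, true: float) -> float:
        return abs(est - true) / max(abs(true), 1.0)

    worst = 0.0
    for model, truth in cases.items():
        y = evaluate_trend(truth, design.times)
        best, _ = fit_trend_library(y, design, model)
        assert best.model == model, f"{model} curve selected as {best.model}"
        est, tru = best.params, truth
        if model == "linear":
            errs = [rel_err(est.slope, tru.slope), rel_err(est.intercept, tru.intercept)]
        elif model == "exponential":
            errs = [
                rel_err(est.scale, tru.scale),
                rel_err(est.rate, tru.rate),
                rel_err(est.offset, tru.offset),
            ]
        else:
            e_est = est.echo if model == "echo_linear" else est
            e_tru = tru.echo if model == "echo_linear" else tru
            errs = [
                rel_err(e_est.amplitude, e_tru.amplitude),
                rel_err(e_est.ac_coefficient, e_tru.ac_coefficient),
                rel_err(e_est.period, e_tru.period),
                rel_err(e_est.phase, e_tru.phase),
                rel_err(e_est.baseline, e_tru.baseline),
            ]
            if model == "echo_linear":
                errs.append(rel_err(est.slope, tru.slope))
        worst = max(worst, max(errs))
    return {"max_rel_error": worst, "n": len(cases)}
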
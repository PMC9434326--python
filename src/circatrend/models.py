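"""Oscillator and trend models, and the amplitude-change classification rule.

The central model is a damped harmonic oscillator for gene-expression
rhythms::

    y(t) = A * exp(-gamma * t / 2) * cos(2*pi*t/tau + phi) + y0

where ``A`` is the initial amplitude (in z-scored expression units),
``gamma`` the amplitude-change (AC) coefficient in 1/hour, ``tau`` the
period in hours, ``phi`` the phase in radians and ``y0`` the baseline.
Positive ``gamma`` shrinks the oscillation envelope over time (a *damped*
rhythm), negative ``gamma`` grows it (*forced*), and ``gamma`` near zero is
a classical fixed-amplitude (*harmonic*) rhythm.

The trend library adds non-oscillatory alternatives (linear, exponential)
and an oscillator-plus-linear-trend hybrid, used for model selection on
time-course omics data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "AcCategory",
    "CIRCADIAN_CATEGORIES",
    "EchoParams",
    "LinearParams",
    "ExponentialParams",
    "EchoLinearParams",
    "TrendParams",
    "DEFAULT_HARMONIC_CUTOFF",
    "DEFAULT_EXTREME_CUTOFF",
    "evaluate_echo",
    "evaluate_trend",
    "classify_ac",
    "peak_time",
]

TWO_PI = 2.0 * math.pi

#: AC-coefficient magnitude below which an oscillation counts as harmonic (1/h).
DEFAULT_HARMONIC_CUTOFF = 0.15
#: AC-coefficient magnitude beyond which damping/forcing is considered extreme
#: (overall expression collapse or blow-up rather than a circadian rhythm), 1/h.
DEFAULT_EXTREME_CUTOFF = 1.0


class AcCategory(str, Enum):
    """Amplitude-change category of an oscillation, assigned from ``gamma``.

    ``forced``, ``harmonic`` and ``damped`` are the three circadian
    categories; ``overexpressed`` and ``repressed`` flag extreme negative /
    positive AC coefficients that are reported but excluded from circadian
    calls.
    """

    FORCED = "forced"
    HARMONIC = "harmonic"
    DAMPED = "damped"
    OVEREXPRESSED = "overexpressed"
    REPRESSED = "repressed"


#: The three AC categories eligible for a circadian call.
CIRCADIAN_CATEGORIES = frozenset(
    {AcCategory.DAMPED, AcCategory.HARMONIC, AcCategory.FORCED}
)


def _require_finite(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class EchoParams:
    """Parameters of the damped-harmonic-oscillator expression model.

    Construction normalizes the representation: a negative amplitude is
    absorbed into the phase (``-A cos(x) = A cos(x + pi)``) and the phase is
    reduced to ``[0, 2*pi)``.

    Attributes
    ----------
    amplitude
        Initial amplitude ``A`` at t=0, z-scored expression units, >= 0.
    ac_coefficient
        Amplitude-change coefficient ``gamma``, 1/hour.
    period
        Oscillation period ``tau``, hours, > 0.
    phase
        Phase ``phi`` in radians, normalized to [0, 2*pi).
    baseline
        Vertical offset ``y0``, z-scored expression units.
    """

    amplitude: float
    ac_coefficient: float
    period: float
    phase: float
    baseline: float

    def __post_init__(self) -> None:
        _require_finite(
            amplitude=self.amplitude,
            ac_coefficient=self.ac_coefficient,
            period=self.period,
            phase=self.phase,
            baseline=self.baseline,
        )
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        amplitude, phase = self.amplitude, self.phase
        if amplitude < 0:
            amplitude, phase = -amplitude, phase + math.pi
        phase = phase % TWO_PI
        object.__setattr__(self, "amplitude", float(amplitude))
        object.__setattr__(self, "phase", float(phase))

    @property
    def angular_frequency(self) -> float:
        """omega = 2*pi / tau, radians per hour."""
        return TWO_PI / self.period


@dataclass(frozen=True)
class LinearParams:
    """Straight-line trend ``y(t) = m*t + b``."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        _require_finite(slope=self.slope, intercept=self.intercept)


@dataclass(frozen=True)
class ExponentialParams:
    """Exponential trend ``y(t) = a * exp(k*t) + c``."""

    scale: float
    rate: float
    offset: float

    def __post_init__(self) -> None:
        _require_finite(scale=self.scale, rate=self.rate, offset=self.offset)


@dataclass(frozen=True)
class EchoLinearParams:
    """Oscillator superimposed on a linear trend: ``evaluate_echo + m*t``."""

    echo: EchoParams
    slope: float

    def __post_init__(self) -> None:
        _require_finite(slope=self.slope)


TrendParams = Union[LinearParams, ExponentialParams, EchoParams, EchoLinearParams]


def evaluate_echo(params: EchoParams, times) -> np.ndarray:
    """Evaluate the damped oscillator at the given times (hours).

    Returns one value per time. For ``gamma > 0`` the envelope
    ``|y - y0|`` decays; for ``gamma = 0`` the output is exactly periodic.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    envelope = params.amplitude * np.exp(-params.ac_coefficient * t / 2.0)
    return envelope * np.cos(params.angular_frequency * t + params.phase) + params.baseline


def evaluate_trend(params: TrendParams, times) -> np.ndarray:
    """Evaluate any member of the trend library at the given times (hours)."""
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if isinstance(params, LinearParams):
        return params.slope * t + params.intercept
    if isinstance(params, ExponentialParams):
        return params.scale * np.exp(params.rate * t) + params.offset
    if isinstance(params, EchoParams):
        return evaluate_echo(params, t)
    if isinstance(params, EchoLinearParams):
        return evaluate_echo(params.echo, t) + params.slope * t
    raise TypeError(f"unknown trend parameter type: {type(params).__name__}")


def classify_ac(
    gamma: float,
    harmonic_cutoff: float = DEFAULT_HARMONIC_CUTOFF,
    extreme_cutoff: float = DEFAULT_EXTREME_CUTOFF,
) -> AcCategory:
    """Assign the amplitude-change category for an AC coefficient.

    The real line is partitioned as::

        gamma <= -extreme_cutoff                    -> overexpressed
        -extreme_cutoff < gamma < -harmonic_cutoff  -> forced
        |gamma| <= harmonic_cutoff                  -> harmonic
        harmonic_cutoff < gamma < extreme_cutoff    -> damped
        gamma >= extreme_cutoff                     -> repressed

    A boundary value goes to the milder category (harmonic at the inner
    cutoffs; the extreme categories claim their cutoff exactly).
    """
    if not math.isfinite(gamma):
        raise ValueError(f"gamma must be finite, got {gamma!r}")
    if not (0 < harmonic_cutoff < extreme_cutoff):
        raise ValueError("cutoffs must satisfy 0 < harmonic_cutoff < extreme_cutoff")
    if abs(gamma) <= harmonic_cutoff:
        return AcCategory.HARMONIC
    if gamma >= extreme_cutoff:
        return AcCategory.REPRESSED
    if gamma <= -extreme_cutoff:
        return AcCategory.OVEREXPRESSED
    return AcCategory.DAMPED if gamma > 0 else AcCategory.FORCED


def peak_time(params: EchoParams) -> float:
    """First non-negative time at which the cosine component peaks.

    Solves ``cos(2*pi*t/tau + phi) = 1`` for the smallest ``t >= 0``,
    i.e. ``((-phi) mod 2*pi) * tau / (2*pi)``. Undefined for zero amplitude.
    """
    if params.amplitude == 0:
        raise ValueError("peak time undefined for zero-amplitude oscillation")
    t = ((-params.phase) % TWO_PI) * params.period / TWO_PI
    # a denormal phase can round the modulus up to a full turn
    return t if t < params.period else 0.0
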
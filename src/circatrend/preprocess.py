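"""Data conditioning for time-course expression matrices.

The chain mirrors standard practice for rhythm detection in time-resolved
omics: presence filtering, imputation, per-feature z-scoring, linear
de-trending and light smoothing, applied in that order. Replicates are
kept as separate samples throughout — nothing here averages across
replicates, because the fitting stage uses every point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Design",
    "ExpressionMatrix",
    "presence_filter",
    "impute_missing",
    "zscore_rows",
    "detrend_linear",
    "smooth",
    "paired_presence_filter",
    "preprocess",
    "DEFAULT_SMOOTH_WEIGHTS",
]

logger = logging.getLogger(__name__)

#: Default centered smoothing kernel, renormalized at series boundaries.
DEFAULT_SMOOTH_WEIGHTS: Tuple[float, ...] = (1.0, 2.0, 1.0)


@dataclass(frozen=True)
class Design:
    """Sample layout of an expression matrix.

    ``times`` holds the collection time (hours post synchronization) of every
    sample column and ``reps`` its 1-based replicate index; both have one
    entry per column, so timepoints with unequal replicate counts are
    representable.
    """

    times: np.ndarray
    reps: np.ndarray
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        reps = np.asarray(self.reps, dtype=int)
        if times.shape != reps.shape or times.ndim != 1:
            raise ValueError("times and reps must be 1-D arrays of equal length")
        if not np.all(np.isfinite(times)):
            raise ValueError("sample times must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "reps", reps)

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def timepoints(self) -> np.ndarray:
        """Distinct collection times, ascending."""
        return np.unique(self.times)

    @property
    def replicate_ids(self) -> np.ndarray:
        return np.unique(self.reps)

    def column_labels(self) -> list[str]:
        """Sample labels in the ``<timepoint>.<replicate>`` convention."""
        out = []
        for t, r in zip(self.times, self.reps):
            t_str = f"{t:g}"
            out.append(f"{t_str}.{r}")
        return out

    @classmethod
    def regular(
        cls, timepoints: Sequence[float], replicates: int, channel: Optional[str] = None
    ) -> "Design":
        """Balanced design: every timepoint measured with the same replicates.

        Columns are ordered time-major (t0.1, t0.2, ..., t1.1, ...).
        """
        tp = np.asarray(timepoints, dtype=float)
        if tp.ndim != 1 or tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        times = np.repeat(tp, replicates)
        reps = np.tile(np.arange(1, replicates + 1), tp.size)
        return cls(times=times, reps=reps, channel=channel)


@dataclass
class ExpressionMatrix:
    """Features x samples numeric grid with missing-value support.

    ``data`` is a pandas DataFrame indexed by unique feature ids whose
    columns follow ``design`` order; missing measurements are NaN.
    """

    data: pd.DataFrame
    design: Design = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.design.n_samples:
            raise ValueError(
                f"matrix has {self.data.shape[1]} columns but the design "
                f"describes {self.design.n_samples} samples"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def with_data(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same features and design, new values."""
        frame = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(data=frame, design=self.design)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(data=self.data.loc[list(feature_ids)], design=self.design)


def presence_filter(matrix: ExpressionMatrix, min_fraction: float = 0.70) -> ExpressionMatrix:
    """Drop features detected in fewer than ``min_fraction`` of samples.

    The boundary is inclusive: a feature present in exactly the minimum
    fraction of samples is kept. Feature order is preserved.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if matrix.n_features == 0:
        return matrix
    present = matrix.data.notna().mean(axis=1)
    keep = present >= min_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("presence_filter removed %d/%d features", dropped, matrix.n_features)
    return ExpressionMatrix(data=matrix.data.loc[keep], design=matrix.design)


def _impute_series_linear(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Linear interpolation over time with constant extrapolation at the ends."""
    observed = np.isfinite(values)
    if observed.all():
        return values
    if not observed.any():
        return values  # caller falls back to the feature mean
    out = values.copy()
    out[~observed] = np.interp(times[~observed], times[observed], values[observed])
    return out


def impute_missing(matrix: ExpressionMatrix, method: str = "linear") -> ExpressionMatrix:
    """Fill missing values; non-missing entries are untouched.

    ``linear`` interpolates over time within each replicate series, holding
    the edge values constant beyond the observed range. A feature with fewer
    than two observed points anywhere — or a replicate series with none —
    falls back to the feature mean. ``mean`` fills every gap with the
    feature mean directly.
    """
    if method not in {"linear", "mean"}:
        raise ValueError(f"unknown imputation method {method!r}")
    values = matrix.values.copy()
    times = matrix.design.times
    reps = matrix.design.reps
    feature_means = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)

    for i in range(values.shape[0]):
        row = values[i]
        finite = np.isfinite(row)
        if finite.all():
            continue
        if not finite.any():
            raise ValueError(
                f"feature {matrix.feature_ids[i]!r} has no observed values; "
                "apply presence_filter first"
            )
        if method == "mean" or finite.sum() < 2:
            row[~finite] = feature_means[i]
            continue
        for rep in np.unique(reps):
            mask = reps == rep
            series = row[mask]
            if not np.isfinite(series).any():
                row[mask] = feature_means[i]
                continue
            order = np.argsort(times[mask], kind="stable")
            filled = np.empty_like(series)
            filled[order] = _impute_series_linear(times[mask][order], series[order])
            row[mask] = filled
    return matrix.with_data(values)


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each feature to mean 0, sample SD (ddof=1) 1.

    Constant rows map to all-zeros rather than raising.
    """
    values = matrix.values
    if not np.all(np.isfinite(values)):
        raise ValueError("zscore_rows requires a complete matrix; impute first")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    centered = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return matrix.with_data(scaled)


def detrend_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's ordinary-least-squares line over time.

    Residuals have zero mean and zero OLS slope; already-detrended rows
    pass through unchanged (idempotent).
    """
    values = matrix.values
    if not np.all(np.isfinite(values)):
        raise ValueError("detrend_linear requires a complete matrix; impute first")
    t = matrix.design.times
    t_centered = t - t.mean()
    denom = float(t_centered @ t_centered)
    if denom == 0:
        return matrix.with_data(values - values.mean(axis=1, keepdims=True))
    slope = (values @ t_centered) / denom
    fitted = values.mean(axis=1, keepdims=True) + np.outer(slope, t_centered)
    return matrix.with_data(values - fitted)


def _smoothing_matrix(n: int, weights: Sequence[float]) -> np.ndarray:
    """n x n centered weighted-moving-average operator with boundary
    renormalization over the available neighbors."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size % 2 != 1:
        raise ValueError("weights must be a 1-D odd-length kernel")
    half = w.size // 2
    op = np.zeros((n, n))
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        seg = w[(lo - i + half):(hi - i + half)]
        op[i, lo:hi] = seg / seg.sum()
    return op


def smooth(
    matrix: ExpressionMatrix, weights: Sequence[float] = DEFAULT_SMOOTH_WEIGHTS
) -> ExpressionMatrix:
    """Weighted moving average along time within each replicate series.

    Endpoints renormalize the kernel over the neighbors that exist. With
    fewer than three timepoints the matrix is returned unchanged.
    """
    values = matrix.values
    if not np.all(np.isfinite(values)):
        raise ValueError("smooth requires a complete matrix; impute first")
    if matrix.design.timepoints.size < 3:
        return matrix
    out = values.copy()
    reps = matrix.design.reps
    times = matrix.design.times
    for rep in np.unique(reps):
        mask = reps == rep
        order = np.argsort(times[mask], kind="stable")
        cols = np.flatnonzero(mask)[order]
        op = _smoothing_matrix(cols.size, weights)
        out[:, cols] = values[:, cols] @ op.T
    return matrix.with_data(out)


def paired_presence_filter(
    matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix
) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two channels to their shared feature ids, same order.

    Used before joint modeling: a feature must be detectable at both omic
    levels to be analyzed jointly.
    """
    shared = matrix_a.feature_ids.intersection(matrix_b.feature_ids)
    shared = [fid for fid in matrix_a.feature_ids if fid in set(shared)]
    if not shared:
        warnings.warn("paired_presence_filter: no shared features between channels")
    return matrix_a.subset(shared), matrix_b.subset(shared)


def preprocess(
    matrix: ExpressionMatrix,
    min_fraction: float = 0.70,
    impute_method: str = "linear",
    smooth_weights: Optional[Sequence[float]] = DEFAULT_SMOOTH_WEIGHTS,
) -> ExpressionMatrix:
    """Full conditioning chain: filter -> impute -> z-score -> detrend -> smooth."""
    out = presence_filter(matrix, min_fraction)
    out = impute_missing(out, impute_method)
    out = zscore_rows(out)
    out = detrend_linear(out)
    if smooth_weights is not None:
        out = smooth(out, smooth_weights)
    return out
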
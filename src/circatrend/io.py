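"""Wide-matrix file format, results tables and time-coordinate helpers.

The wide CSV dialect: first column holds feature ids, remaining columns
are samples named ``<timepoint>.<replicate>`` (hours, 1-based replicate),
e.g. ``0.1, 0.2, 0.3, 2.1, ...`` for three replicates sampled every 2 h.
Missing measurements are empty cells or ``NA``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import Design, ExpressionMatrix

__all__ = [
    "read_wide_matrix",
    "write_wide_matrix",
    "write_results",
    "read_annotation",
    "hps_to_ct",
    "parse_sample_label",
]

PathLike = Union[str, Path]
_NA_VALUES = ["", "NA"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def parse_sample_label(label: str) -> tuple[float, int]:
    """Split ``"<timepoint>.<replicate>"`` into (hours, replicate).

    The split is at the last dot, so fractional timepoints like
    ``"2.5.1"`` parse as (2.5, 1).
    """
    head, _, tail = label.rpartition(".")
    if not head or not tail:
        raise ParseError(f"sample column {label!r} is not '<timepoint>.<replicate>'")
    try:
        t = float(head)
        rep = int(tail)
    except ValueError as exc:
        raise ParseError(f"sample column {label!r} is not '<timepoint>.<replicate>'") from exc
    if rep < 1:
        raise ParseError(f"sample column {label!r}: replicate index must be >= 1")
    return t, rep


def read_wide_matrix(
    path: PathLike, channel: Optional[str] = None, sep: Optional[str] = None
) -> ExpressionMatrix:
    """Read a wide expression matrix; the header defines the design.

    ``sep`` defaults to tab for ``.tsv`` files and comma otherwise.
    Duplicate feature ids and non-numeric cells are rejected with the
    offending location named.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False,
        comment="#", dtype=str,
    )
    labels = [str(c) for c in frame.columns]
    parsed = [parse_sample_label(lab) for lab in labels]
    times = np.array([t for t, _ in parsed])
    reps = np.array([r for _, r in parsed])
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"{path.name}: duplicate feature ids {dupes[:5]}")
    numeric = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ParseError(
                f"{path.name}: non-numeric value {frame.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        numeric[col] = converted
    design = Design(times=times, reps=reps, channel=channel)
    return ExpressionMatrix(data=numeric, design=design)


def write_wide_matrix(matrix: ExpressionMatrix, path: PathLike, sep: Optional[str] = None) -> None:
    """Write a matrix in the wide dialect; NaN becomes an empty cell."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = matrix.data.copy()
    frame.columns = matrix.design.column_labels()
    frame.index.name = frame.index.name or "id"
    frame.to_csv(path, sep=sep, na_rep="")


def write_results(
    results: pd.DataFrame, path: PathLike, parameters: Optional[Mapping[str, object]] = None
) -> None:
    """Write a results table as TSV with a provenance comment line."""
    path = Path(path)
    param_str = " ".join(f"{k}={v}" for k, v in (parameters or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# circatrend v{__version__} {param_str}".rstrip() + "\n")
        results.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_results(path: PathLike) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=_NA_VALUES)


def read_annotation(path: PathLike) -> dict[str, str]:
    """Read a two-column (feature_id, label) TSV into a mapping."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#", na_values=_NA_VALUES,
        keep_default_na=False, dtype=str,
    )
    if frame.shape[1] < 2:
        raise ParseError(f"{Path(path).name}: expected two tab-separated columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def hps_to_ct(hours: float, ct_offset: float = 0.0) -> float:
    """Convert hours post synchronization to circadian time in [0, 24).

    ``ct_offset`` is the HPS hour corresponding to CT0, anchored on a
    reference rhythm's peak/trough (e.g. Per2).
    """
    if not (np.isfinite(hours) and np.isfinite(ct_offset)):
        raise ValueError("hours and ct_offset must be finite")
    return float((hours - ct_offset) % 24.0)
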
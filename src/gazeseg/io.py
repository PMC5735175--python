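"""Reading, writing and preparing gaze traces.

The interchange format is a plain CSV with a header row, comma separated,
``.`` decimal separator, UTF-8.  Mandatory columns are ``t`` (time in
seconds, strictly increasing), ``x`` and ``y`` (gaze position in degrees of
visual angle).  Optional columns: ``valid`` (boolean flag, false for
outlier/blink samples) and ``label`` (per-sample event code, one of
``fixation|saccade|pso|pursuit|blink|other``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

EVENT_LABELS = ("fixation", "saccade", "pso", "pursuit", "blink", "other")
#: Labels treated as outliers: excluded from training and agreement scoring.
OUTLIER_LABELS = frozenset({"blink", "other"})


@dataclass
class GazeTrace:
    """A timestamped 2-D gaze position series.

    Attributes
    ----------
    t : ndarray of float, shape (n,)
        Sample times in seconds, strictly increasing.
    x, y : ndarray of float, shape (n,)
        Horizontal / vertical gaze position in degrees of visual angle.
    valid : ndarray of bool, shape (n,)
        False marks outlier samples (blinks, tracker dropouts).
    label : ndarray of str or None
        Optional per-sample event codes.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    label: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=object)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("all GazeTrace columns must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if n and not np.all(np.isfinite(self.t)):
            raise ValueError("timestamps must be finite")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise ValueError("x, y must be finite wherever valid is true")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) array."""
        return np.column_stack([self.x, self.y])

    @property
    def median_rate(self) -> float:
        """Median sampling rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.t)))

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            self.t.copy(),
            self.x.copy(),
            self.y.copy(),
            self.valid.copy(),
            None if self.label is None else self.label.copy(),
        )


def read_gaze_csv(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> GazeTrace:
    """Read a gaze trace from a delimited text file.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    column_map : mapping, optional
        Maps the canonical names ``t``, ``x``, ``y`` (and optionally
        ``valid``, ``label``) to the column names used in the file.

    Rows whose position fields are missing or unparseable are kept but
    marked ``valid=False``.  Non-increasing timestamps are an error.
    """
    cmap = {k: k for k in ("t", "x", "y", "valid", "label")}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    for key in ("t", "x", "y"):
        if cmap[key] not in df.columns:
            raise ValueError(f"missing mandatory column {cmap[key]!r}")
    t = pd.to_numeric(df[cmap["t"]], errors="raise").to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotonic timestamps in input file")
    x = pd.to_numeric(df[cmap["x"]], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[cmap["y"]], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(x) & np.isfinite(y)
    if cmap["valid"] in df.columns:
        file_valid = df[cmap["valid"]].astype(bool).to_numpy()
        valid &= file_valid
    label = None
    if cmap["label"] in df.columns:
        label = df[cmap["label"]].astype(str).to_numpy(dtype=object)
    # invalid positions are replaced by NaN placeholders; the trace invariant
    # only requires finiteness where valid is true
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeTrace(t, x, y, valid, label)


def write_gaze_csv(trace: GazeTrace, path) -> None:
    """Write a trace in the interchange CSV format."""
    cols = {"t": trace.t, "x": trace.x, "y": trace.y, "valid": trace.valid.astype(int)}
    if trace.label is not None:
        cols["label"] = trace.label
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def interpolate_outliers(trace: GazeTrace):
    """Replace invalid samples by linear interpolation between the nearest
    valid neighbours.

    Invalid samples before the first (after the last) valid sample are held
    at the nearest valid value.  Returns the repaired trace together with a
    boolean mask marking the replaced samples, so error metrics can exclude
    them downstream.
    """
    valid = trace.valid
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError("need at least two valid samples to interpolate")
    mask = ~valid
    if not mask.any():
        return trace.copy(), mask.copy()
    tv = trace.t[valid]
    out = trace.copy()
    # np.interp holds the boundary values constant outside [tv[0], tv[-1]]
    out.x[mask] = np.interp(trace.t[mask], tv, trace.x[valid])
    out.y[mask] = np.interp(trace.t[mask], tv, trace.y[valid])
    out.valid = np.ones(len(trace), dtype=bool)
    return out, mask.copy()


def write_segments_csv(seg, path, labels: Optional[Sequence[str]] = None) -> None:
    """Write a segmentation as a CSV table, one row per segment.

    Columns: start/end time, start/end sample index, node x/y values at both
    segment ends, mean speed in deg/s, and the event class if given.
    """
    m = seg.n_segments
    if m == 0:
        raise ValueError("empty segmentation")
    if labels is not None and len(labels) != m:
        raise ValueError("labels must have one entry per segment")
    starts = seg.breakpoints
    ends = np.append(seg.breakpoints[1:], seg.n_samples)
    rows = {
        "t_start": seg.node_times[:-1],
        "t_end": seg.node_times[1:],
        "i_start": starts,
        "i_end": ends,
        "x_start": seg.node_values[:-1, 0],
        "x_end": seg.node_values[1:, 0],
        "y_start": seg.node_values[:-1, 1],
        "y_end": seg.node_values[1:, 1],
        "mean_speed": seg.segment_speeds(),
    }
    if labels is not None:
        rows["class"] = list(labels)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_segments_csv(path) -> pd.DataFrame:
    """Read back a segment table written by :func:`write_segments_csv`."""
    return pd.read_csv(path)
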
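"""Localization-table I/O, drift correction, and axial windowing.

A localization table holds one row per detected single-molecule blink
("event"): acquisition frame, 3D position in nm, and the lateral/axial
localization precision of that event. Tables come from delimited text files
whose column names and units vary between acquisition software packages, so
reading goes through a small ``Dialect`` mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "Dialect",
    "LocalizationTable",
    "read_localizations",
    "write_localizations",
    "correct_drift",
    "filter_axial_window",
]

log = logging.getLogger(__name__)

#: canonical column order of a localization table
COLUMNS = ["frame", "x", "y", "z", "precision_xy", "precision_z"]


class FormatError(ValueError):
    """Raised when a localization file does not match its dialect."""


class DriftEstimationError(RuntimeError):
    """Raised when a table has too few events to estimate drift."""


@dataclass
class Dialect:
    """Column-name mapping plus unit scale factors for reading tables.

    ``columns`` maps canonical names (see :data:`COLUMNS`) to the names used
    in the file; ``scale_to_nm`` multiplies each spatial column to convert it
    to nm (e.g. 1000.0 for micron-valued files). ``sep=None`` sniffs comma
    vs. tab.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in COLUMNS}
    )
    scale_to_nm: float = 1.0
    sep: str | None = None


@dataclass
class LocalizationTable:
    """Ordered collection of localization events plus acquisition metadata."""

    events: pd.DataFrame
    n_frames: int = 20_000
    frame_exposure_ms: float = 50.0

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"localization table missing columns {missing}")
        if len(ev):
            if not ev["frame"].is_monotonic_increasing:
                self.events = ev.sort_values("frame", kind="stable").reset_index(drop=True)
            if (self.events["frame"] < 0).any():
                raise ValueError("negative frame index")
            if (self.events[["precision_xy", "precision_z"]] <= 0).any().any():
                raise ValueError("non-positive localization precision")
            max_frame = int(self.events["frame"].max())
            if self.n_frames < max_frame + 1:
                self.n_frames = max_frame + 1

    def __len__(self) -> int:
        return len(self.events)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of event positions in nm."""
        return self.events[["x", "y", "z"]].to_numpy(dtype=float)

    def with_positions(self, xyz: np.ndarray) -> "LocalizationTable":
        ev = self.events.copy()
        ev[["x", "y", "z"]] = xyz
        return LocalizationTable(ev, self.n_frames, self.frame_exposure_ms)


def read_localizations(
    path: str | Path,
    dialect: Dialect | None = None,
    n_frames: int = 20_000,
    frame_exposure_ms: float = 50.0,
) -> LocalizationTable:
    """Read a delimited localization file into a :class:`LocalizationTable`.

    Rows with non-finite coordinates are dropped (and counted in the log);
    spatial columns are rescaled to nm according to the dialect.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    import csv

    try:
        raw = pd.read_csv(path, sep=dialect.sep, engine="python")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"unreadable localization file {path}: {exc}") from exc
    missing = [v for v in dialect.columns.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"{path}: mapped columns absent from file: {missing}")
    inv = {v: k for k, v in dialect.columns.items()}
    ev = raw[list(dialect.columns.values())].rename(columns=inv)[COLUMNS]
    ev = ev.apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(ev[["x", "y", "z"]]).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.info("%s: dropped %d rows with non-finite coordinates", path, n_dropped)
    ev = ev[finite].reset_index(drop=True)
    if len(ev) == 0:
        raise FormatError(f"{path}: no finite localization events")
    for col in ("x", "y", "z", "precision_xy", "precision_z"):
        ev[col] = ev[col] * dialect.scale_to_nm
    ev["frame"] = ev["frame"].astype(int)
    return LocalizationTable(ev, n_frames=n_frames, frame_exposure_ms=frame_exposure_ms)


def write_localizations(table: LocalizationTable, path: str | Path, sep: str = ",") -> None:
    """Write a table back to delimited text (canonical columns, nm units)."""
    table.events[COLUMNS].to_csv(path, sep=sep, index=False, float_format="%.17g")


def _piecewise_linear_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix for a continuous piecewise-linear function.

    Columns: intercept, global slope, and one hinge max(0, t-k) per interior
    knot; continuity at the knots is automatic in this parameterization.
    """
    cols = [np.ones_like(t), t]
    for k in knots:
        cols.append(np.maximum(0.0, t - k))
    return np.column_stack(cols)


def _binned_shifts(
    xyz: np.ndarray,
    which: np.ndarray,
    n_bins: int,
    bin_nm: float,
    upsample: int,
) -> np.ndarray:
    """Per-temporal-bin (x, y, z) shifts by subpixel phase correlation.

    Each temporal bin's localization histogram (2D in xy, 1D in z,
    Gaussian-smoothed by one pixel to stabilize the correlation peak on
    sparse data) is registered against the first occupied bin's histogram;
    registering bin-to-bin rather than against the whole-table average
    avoids the bias a drift-smeared reference would introduce. Returned
    shifts are drift relative to the first bin.
    """
    from scipy.ndimage import gaussian_filter, gaussian_filter1d
    from skimage.registration import phase_cross_correlation

    lo = xyz.min(axis=0) - 4 * bin_nm
    hi = xyz.max(axis=0) + 4 * bin_nm
    nbx = np.maximum(8, np.ceil((hi - lo) / bin_nm)).astype(int)
    edges = [np.linspace(lo[a], hi[a], nbx[a] + 1) for a in range(3)]

    def _images(sel):
        img, _, _ = np.histogram2d(xyz[sel, 0], xyz[sel, 1], bins=[edges[0], edges[1]])
        prof, _ = np.histogram(xyz[sel, 2], bins=edges[2])
        return gaussian_filter(img, 1.5), gaussian_filter1d(prof, 1.5)

    shifts = np.full((n_bins, 3), np.nan)
    ref_xy = ref_z = None
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        img, prof = _images(sel)
        if ref_xy is None:
            ref_xy, ref_z = img, prof
            shifts[b] = 0.0
            continue
        s_xy, *_ = phase_cross_correlation(
            ref_xy, img, upsample_factor=upsample, normalization=None
        )
        s_z, *_ = phase_cross_correlation(
            ref_z, prof, upsample_factor=upsample, normalization=None
        )
        # phase correlation returns the shift taking the bin image onto the
        # reference; the bin's drift is the opposite displacement
        shifts[b] = -np.array([s_xy[0], s_xy[1], s_z[0]]) * bin_nm
    return shifts


def correct_drift(
    table: LocalizationTable,
    n_segments: int = 5,
    bin_nm: float = 50.0,
    upsample: int = 100,
) -> LocalizationTable:
    """Estimate and subtract piecewise-linear sample drift, fiducial-free.

    The acquisition is split into temporal bins; each bin's localization
    histogram is registered to the whole-table histogram by subpixel phase
    correlation (redundant cross-correlation drift estimation), and the
    per-bin shifts are fitted per axis with a continuous piecewise-linear
    function over ``n_segments`` equal spans of the frame range. The
    fitted drift minus its event-weighted mean is subtracted, so the mean
    position of the table is preserved and a pure constant offset is left
    untouched.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    n = len(table)
    min_bins = 2 * n_segments
    if n < min_bins:
        raise DriftEstimationError(
            f"need at least {min_bins} events for {n_segments} drift segments, got {n}"
        )
    frames = table.events["frame"].to_numpy(dtype=float)
    f_lo, f_hi = frames.min(), frames.max()
    if f_hi == f_lo:
        return table  # single-frame table: no temporal axis to fit
    n_bins = int(np.clip(n // 200, min_bins, 32))
    edges = np.linspace(f_lo, f_hi + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(frames, edges) - 1, 0, n_bins - 1)
    if (np.bincount(which, minlength=n_bins) > 0).sum() < min_bins:
        raise DriftEstimationError("too few occupied temporal bins for drift estimation")

    xyz = table.xyz
    shifts = _binned_shifts(xyz, which, n_bins, bin_nm, upsample)
    ok = np.isfinite(shifts[:, 0])
    bin_t = np.array([frames[which == b].mean() for b in range(n_bins)])[ok]
    knots = np.linspace(f_lo, f_hi, n_segments + 1)[1:-1]
    A_bins = _piecewise_linear_basis(bin_t, knots)
    A_events = _piecewise_linear_basis(frames, knots)

    corrected = xyz.copy()
    for ax in range(3):
        coef, *_ = np.linalg.lstsq(A_bins, shifts[ok, ax], rcond=None)
        drift = A_events @ coef
        corrected[:, ax] -= drift - drift.mean()
    return table.with_positions(corrected)


def filter_axial_window(
    table: LocalizationTable,
    width_nm: float = 600.0,
    center_nm: float | None = None,
) -> LocalizationTable:
    """Keep only events within ``width_nm`` of the axial analysis center.

    Events far from the focal plane carry larger axial error; the default
    600 nm window retains the well-localized core of the 4 um capture range.
    ``center_nm`` defaults to the median event z.
    """
    if width_nm <= 0:
        raise ValueError("width_nm must be positive")
    if len(table) == 0:
        return table
    z = table.events["z"].to_numpy(dtype=float)
    if center_nm is None:
        center_nm = float(np.median(z))
    keep = np.abs(z - center_nm) <= width_nm / 2.0
    ev = table.events[keep].reset_index(drop=True)
    return LocalizationTable(ev, table.n_frames, table.frame_exposure_ms)
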
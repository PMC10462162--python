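"""From BOLD timeseries to functional-connectivity matrices and vectors.

The pipeline stages implemented here are: mean BOLD extraction over ROI
sphere masks, zero-phase Butterworth band-pass filtering (default
0.01-0.15 Hz, removing scanner drift and cardiac/respiratory components),
Pearson correlation of the filtered series, and reduction of the symmetric
correlation matrix to its strict upper triangle in row-major order (for 264
ROIs: 34,716 unique edges).

Raw correlation coefficients are carried throughout; no Fisher z-transform is
applied, so block averages and change statistics are on the rho scale.
ROIs with empty masks or zero-variance series are flagged invalid and
propagate as missing (NaN) rows/columns rather than silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigError, DataError, FormatError

#: Repetition time (s) of the resting-state acquisitions this package targets.
DEFAULT_TR = 0.735


@dataclass
class BoldTimeseries:
    """Mean BOLD signal per ROI: ``data`` is frames x ROIs."""

    data: np.ndarray
    tr: float = DEFAULT_TR
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("timeseries data must be 2-D (frames x ROIs)")
        if self.data.shape[0] < 2:
            raise DataError("at least 2 frames required")
        if not self.tr > 0:
            raise DataError("TR must be positive")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.data.shape[1],):
                raise DataError("valid flags must have one entry per ROI")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FilterConfig:
    """Band-pass design: Butterworth of the given order, applied forward and
    backward (zero phase) so that no inter-ROI lag is introduced."""

    low_hz: float = 0.01
    high_hz: float = 0.15
    order: int = 2

    def validate(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if not (0 <= self.low_hz < self.high_hz < nyquist):
            raise ConfigError(
                f"band [{self.low_hz}, {self.high_hz}] Hz infeasible for "
                f"TR={tr} s (Nyquist {nyquist:.4g} Hz)"
            )
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")


@dataclass
class FCMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal.

    Rows/columns of invalid ROIs are NaN and flagged in ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError("FC matrix must be square")
        if self.valid is None:
            self.valid = ~np.any(np.isnan(self.values), axis=0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class FCVector:
    """Strict upper triangle of an FC matrix, row-major (i < j) order."""

    values: np.ndarray
    n_rois: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.values.shape != (expected,):
            raise FormatError(
                f"FC vector for {self.n_rois} ROIs must have length {expected}, "
                f"got {self.values.shape}"
            )


def extract_roi_timeseries(
    volume: np.ndarray,
    masks: Sequence[np.ndarray],
    tr: float = DEFAULT_TR,
) -> BoldTimeseries:
    """Mean BOLD signal over each ROI's voxel mask.

    ``volume`` is a 4-D array (x, y, z, frames); ``masks`` holds per-ROI
    (m, 3) voxel-index arrays as produced by :func:`fclong.atlas.roi_masks`.
    ROIs with empty masks are flagged invalid and their series set to NaN.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4:
        raise DataError("expected a 4-D volume (x, y, z, frames)")
    n_frames = volume.shape[3]
    if n_frames < 2:
        raise DataError("volume must have at least 2 frames")
    n_rois = len(masks)
    valid = np.array([m is not None and len(m) > 0 for m in masks], dtype=bool)
    if not valid.any():
        raise DataError("every ROI mask is empty; nothing to extract")
    data = np.full((n_frames, n_rois), np.nan)
    for r, mask in enumerate(masks):
        if not valid[r]:
            continue
        mask = np.asarray(mask, dtype=int)
        data[:, r] = volume[mask[:, 0], mask[:, 1], mask[:, 2], :].mean(axis=0)
    return BoldTimeseries(data=data, tr=tr, valid=valid)


def bandpass(ts: BoldTimeseries, cfg: FilterConfig = FilterConfig()) -> BoldTimeseries:
    """Zero-phase band-pass filter each ROI series.

    DC (and any drift slower than ``low_hz``) is removed; frequencies above
    ``high_hz`` are attenuated.  Invalid ROI columns pass through as NaN.
    """
    cfg.validate(ts.tr)
    fs = 1.0 / ts.tr
    if cfg.low_hz > 0:
        sos = signal.butter(cfg.order, [cfg.low_hz, cfg.high_hz],
                            btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(cfg.order, cfg.high_hz, btype="lowpass",
                            fs=fs, output="sos")
    out = np.full_like(ts.data, np.nan)
    cols = np.asarray(ts.valid, dtype=bool)
    if cols.any():
        out[:, cols] = signal.sosfiltfilt(sos, ts.data[:, cols], axis=0)
    return BoldTimeseries(data=out, tr=ts.tr, valid=ts.valid.copy())


def fc_from_timeseries(ts: BoldTimeseries) -> FCMatrix:
    """Pearson correlation between all pairs of ROI series.

    Zero-variance and invalid ROIs become NaN rows/columns, flagged in the
    result's ``valid`` mask.  Fewer than 3 frames leave no degree of freedom
    for a correlation and raise :class:`DataError`.
    """
    if ts.n_frames < 3:
        raise DataError("at least 3 frames required for Pearson correlation")
    valid = np.asarray(ts.valid, dtype=bool).copy()
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(ts.data, axis=0)
    valid &= variances > 0
    valid &= ~np.any(np.isnan(ts.data), axis=0)
    values = np.full((ts.n_rois, ts.n_rois), np.nan)
    if valid.sum() >= 1:
        sub = np.corrcoef(ts.data[:, valid], rowvar=False)
        sub = np.atleast_2d(sub)
        sub = np.clip(sub, -1.0, 1.0)
        idx = np.flatnonzero(valid)
        values[np.ix_(idx, idx)] = sub
    np.fill_diagonal(values, np.where(valid, 1.0, np.nan))
    return FCMatrix(values=values, valid=valid)


def vectorize_fc(m: FCMatrix | np.ndarray) -> FCVector:
    """Reduce a symmetric FC matrix to its strict upper triangle.

    Row-major (i < j) order; for N ROIs the vector has N(N-1)/2 entries
    (34,716 for the 264-ROI atlas).
    """
    values = m.values if isinstance(m, FCMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError("FC matrix must be square")
    finite = np.isfinite(values)
    both = finite & finite.T
    if not np.allclose(np.where(both, values, 0.0),
                       np.where(both, values.T, 0.0), atol=1e-12):
        raise FormatError("FC matrix must be symmetric")
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    return FCVector(values=values[iu], n_rois=n)


def devectorize_fc(v: FCVector | np.ndarray, n_rois: int | None = None) -> FCMatrix:
    """Rebuild the symmetric unit-diagonal matrix from an upper-triangle vector."""
    if isinstance(v, FCVector):
        values, n = v.values, v.n_rois
    else:
        values = np.asarray(v, dtype=float)
        if n_rois is None:
            # solve L = n(n-1)/2 for integer n
            n = int(round((1 + np.sqrt(1 + 8 * values.size)) / 2))
        else:
            n = n_rois
        if n * (n - 1) // 2 != values.size:
            raise FormatError(
                f"vector length {values.size} is not of the form N(N-1)/2"
            )
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = values
    out[(iu[1], iu[0])] = values
    nan_roi = np.zeros(n, dtype=bool)
    rows, cols = iu[0][np.isnan(values)], iu[1][np.isnan(values)]
    # a ROI is invalid if every one of its off-diagonal edges is missing
    if rows.size:
        counts = np.bincount(np.concatenate([rows, cols]), minlength=n)
        nan_roi = counts == n - 1
        out[nan_roi, nan_roi] = np.nan
    return FCMatrix(values=out, valid=~nan_roi)
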
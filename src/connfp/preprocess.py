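"""ROI-level rs-fMRI time-series preprocessing.

Covers the signal-level steps applied to atlas-extracted ROI time series:
discarding initial volumes acquired before magnetization equilibrium,
nuisance regression with polynomial detrending, and band-pass filtering to
the low-frequency band carrying resting-state connectivity. Voxel-level
spatial preprocessing (registration, smoothing, motion correction) is out of
scope; inputs are assumed already registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class RoiTimeSeries:
    """T x R matrix of ROI signals with acquisition metadata."""

    data: np.ndarray
    tr_seconds: float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a T x R matrix with T >= 1")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError("column count must equal len(roi_names)")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains missing/non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass(frozen=True)
class BandpassConfig:
    low_hz: float = 0.009
    high_hz: float = 0.08

    def validate(self, tr_seconds: float) -> None:
        nyq = 1.0 / (2.0 * tr_seconds)
        if not 0 < self.low_hz < self.high_hz < nyq:
            raise ValueError(
                f"band ({self.low_hz} Hz, {self.high_hz} Hz) invalid for "
                f"Nyquist {nyq:.4f} Hz at TR {tr_seconds} s")


def extract_roi_timeseries(image4d, atlas, roi_labels,
                           tr_seconds: float = 3.0,
                           roi_names: list[str] | None = None) -> RoiTimeSeries:
    """Mean-signal extraction from a 4-D image using an integer label volume.

    ``image4d`` and ``atlas`` may be numpy arrays or nibabel spatial images;
    column j holds, per volume, the arithmetic mean intensity over voxels
    with atlas value ``roi_labels[j]``.
    """
    image4d = _as_array(image4d)
    atlas = _as_array(atlas)
    if image4d.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {image4d.shape}")
    if image4d.shape[:3] != atlas.shape:
        raise ValueError(f"image spatial dims {image4d.shape[:3]} do not match "
                         f"atlas dims {atlas.shape}")
    atlas = np.rint(atlas).astype(int)
    cols = []
    for lab in roi_labels:
        mask = atlas == lab
        if not mask.any():
            raise ValueError(f"atlas label {lab} not present in label volume")
        cols.append(image4d[mask].mean(axis=0))
    names = roi_names if roi_names is not None else [f"ROI_{lab}" for lab in roi_labels]
    return RoiTimeSeries(np.column_stack(cols), tr_seconds, list(names))


def _as_array(obj) -> np.ndarray:
    if hasattr(obj, "dataobj"):  # nibabel image
        return np.asanyarray(obj.dataobj)
    return np.asarray(obj)


def discard_initial_volumes(ts: RoiTimeSeries, k: int = 4) -> RoiTimeSeries:
    """Drop the first ``k`` volumes (pre-equilibrium scans)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= ts.n_timepoints:
        raise ValueError(f"cannot discard {k} of {ts.n_timepoints} volumes")
    if k == 0:
        return RoiTimeSeries(ts.data.copy(), ts.tr_seconds, list(ts.roi_names))
    return RoiTimeSeries(ts.data[k:], ts.tr_seconds, list(ts.roi_names))


def _polynomial_basis(n: int, order: int) -> np.ndarray:
    """Orthonormal columns spanning polynomials up to ``order`` in time."""
    t = np.linspace(-1.0, 1.0, n)
    vander = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(vander)
    return q


def regress_nuisance(ts: RoiTimeSeries, nuisance: np.ndarray | None = None,
                     poly_order: int = 3) -> RoiTimeSeries:
    """OLS residualization against polynomial trends plus nuisance columns.

    The design is an orthonormalized [1, t, t^2, ..., t^poly_order] basis
    joined with any user-supplied nuisance regressors (e.g. white-matter/CSF
    mean signals, motion parameters). A rank-deficient design falls back to
    the minimum-norm least-squares solution with a warning.
    """
    design = _polynomial_basis(ts.n_timepoints, poly_order)
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim == 1:
            nuisance = nuisance[:, None]
        if nuisance.shape[0] != ts.n_timepoints:
            raise ValueError(f"nuisance has {nuisance.shape[0]} rows, "
                             f"expected {ts.n_timepoints}")
        design = np.column_stack([design, nuisance])
    beta, _, rank, _ = np.linalg.lstsq(design, ts.data, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(f"rank-deficient nuisance design (rank {rank} < "
                      f"{design.shape[1]}); using minimum-norm solution")
    residuals = ts.data - design @ beta
    return RoiTimeSeries(residuals, ts.tr_seconds, list(ts.roi_names))


def bandpass(ts: RoiTimeSeries, cfg: BandpassConfig = BandpassConfig()) -> RoiTimeSeries:
    """Zero-phase band-pass (forward-backward Butterworth, order 2 per pass)."""
    cfg.validate(ts.tr_seconds)
    fs = 1.0 / ts.tr_seconds
    b, a = signal.butter(2, [cfg.low_hz, cfg.high_hz], btype="bandpass", fs=fs)
    filtered = signal.filtfilt(b, a, ts.data, axis=0)
    return RoiTimeSeries(filtered, ts.tr_seconds, list(ts.roi_names))
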
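"""Denoising of masked BOLD time series.

The fixed pipeline order is confound regression → high-pass/detrend →
voxelwise standardization, mirroring FSL-style resting-state cleanup after
registration.  High-pass filtering is implemented as regression against a
discrete cosine drift basis (all DCT frequencies below the cutoff) plus a
linear trend, which is deterministic and free of filter edge effects.

Standard deviations throughout the package use the population (1/T)
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gradpain.errors import DataError
from gradpain.volume import BoldVolume, Mask, check_grid

log = logging.getLogger(__name__)


@dataclass
class ConfoundSet:
    """T × C matrix of nuisance regressors (motion, white matter, CSF...)."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise DataError("non-finite values in confound matrix")
        if not self.labels:
            self.labels = [f"conf{i}" for i in range(self.matrix.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


def _drop_collinear(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Remove columns that are numerically linear combinations of earlier ones."""
    keep: list[int] = []
    for j in range(C.shape[1]):
        cand = C[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
        else:
            log.warning("dropping collinear confound column %d", j)
    return C[:, keep]


def regress_confounds(Y: np.ndarray, confounds: ConfoundSet | np.ndarray | None) -> np.ndarray:
    """Residualize every voxel time series (columns of T × N ``Y``) on the
    confound columns plus an intercept.

    Residuals are orthogonal to each confound column and to the constant.
    Rank-deficient confound sets are repaired by dropping collinear columns.
    """
    Y = np.asarray(Y, dtype=np.float64)
    T = Y.shape[0]
    if confounds is None:
        C = np.empty((T, 0))
    else:
        C = confounds.matrix if isinstance(confounds, ConfoundSet) else np.atleast_2d(np.asarray(confounds, float))
    if C.size and C.shape[0] != T:
        raise DataError(f"confound rows ({C.shape[0]}) != timepoints ({T})")
    X = np.column_stack([np.ones(T), C - C.mean(axis=0)]) if C.size else np.ones((T, 1))
    X = _drop_collinear(X)
    if X.shape[1] >= T:
        raise DataError(f"confound design has rank {X.shape[1]} >= {T} timepoints")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def dct_drift_basis(T: int, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Discrete cosine drift regressors with frequencies strictly below the
    cutoff, plus a linear-trend column; the constant is handled separately.

    DCT-II component k has frequency k / (2 · T · TR) Hz.
    """
    n_k = int(np.ceil(cutoff_hz * 2 * T * tr)) - 1  # k = 1 .. n_k have f < cutoff
    t = np.arange(T)
    cols = [np.linspace(-1.0, 1.0, T)]  # linear trend
    for k in range(1, max(n_k, 0) + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / T))
    return np.column_stack(cols)


def highpass(Y: np.ndarray, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Remove slow drifts below ``cutoff_hz`` (plus the linear trend and the
    mean) from each column of T × N ``Y``."""
    Y = np.asarray(Y, dtype=np.float64)
    if tr <= 0 or cutoff_hz <= 0:
        raise DataError("tr and cutoff must be positive")
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise DataError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    T = Y.shape[0]
    X = np.column_stack([np.ones(T), dct_drift_basis(T, tr, cutoff_hz)])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def standardize(Y: np.ndarray, ddof: int = 0, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Scale each column of T × N ``Y`` to zero mean and unit (population) sd.

    Returns the standardized matrix and a boolean array flagging columns with
    (numerically) zero variance; flagged columns are returned as zeros and
    should be excluded from downstream masks.
    """
    Y = np.asarray(Y, dtype=np.float64)
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=ddof)
    degenerate = sd <= tol * np.maximum(1.0, np.abs(mu))
    if degenerate.any():
        log.warning("standardize: %d zero-variance voxel(s) flagged", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, sd)
    Z = (Y - mu) / safe
    Z[:, degenerate] = 0.0
    return Z, degenerate


def clean(
    volume: BoldVolume,
    brain: Mask,
    confounds: ConfoundSet | None = None,
    cutoff_hz: float = 0.01,
) -> tuple[BoldVolume, Mask]:
    """Full denoising pipeline on a masked volume.

    Returns a cleaned volume (voxels outside the brain mask zeroed) and a
    possibly reduced brain mask with zero-variance voxels removed.
    """
    check_grid(volume, brain)
    Y = volume.timeseries(brain)
    if confounds is not None:
        # high-pass the confounds first: filtered regressors are exactly
        # orthogonal to the drift basis, so the sequential stages compose
        # into one projection and the pipeline is idempotent
        C = confounds.matrix if isinstance(confounds, ConfoundSet) else np.asarray(confounds, float)
        confounds = ConfoundSet(highpass(C, volume.tr, cutoff_hz)) if C.size else None
    Y = regress_confounds(Y, confounds)
    Y = highpass(Y, volume.tr, cutoff_hz)
    Z, degenerate = standardize(Y)
    out = np.zeros_like(volume.data)
    out[brain.data] = Z.T
    new_mask = brain.data.copy()
    if degenerate.any():
        idx = brain.indices()[degenerate]
        new_mask[tuple(idx.T)] = False
    return (
        BoldVolume(out, volume.affine, volume.tr),
        Mask(new_mask, label=brain.label, affine=brain.affine),
    )
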
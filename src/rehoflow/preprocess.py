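"""Functional preprocessing on volumes already in a common grid.

Implements the chain: initial-volume discard, framewise-displacement motion
QC, Friston-24 + tissue-signal confound construction, linear nuisance
regression, ideal (frequency-domain) band-pass filtering and Gaussian spatial
smoothing. Spatial stages (realignment, normalization) are out of scope: the
input volumes are assumed grid-aligned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Volume4D, StatMap, voxel_sizes

__all__ = [
    "ConfoundSet", "discard_initial_volumes", "framewise_displacement",
    "flag_motion_exclusions", "build_friston24", "bandpass_filter",
    "regress_nuisance", "smooth_gaussian", "extract_tissue_signal",
    "build_confounds",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ConfoundSet:
    """A T x C nuisance regressor matrix with column labels."""

    matrix: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("confound matrix must be 2D (T x C)")
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("number of labels does not match confound columns")


def discard_initial_volumes(vol: Volume4D, k: int = 10) -> Volume4D:
    """Drop the first ``k`` volumes (signal-stabilization discard)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= vol.n_timepoints:
        raise ValueError(f"cannot discard {k} of {vol.n_timepoints} volumes")
    if k == 0:
        return vol
    return vol.with_data(vol.data[..., k:])


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power framewise displacement from a (6, T) motion trace.

    FD[t] = sum |d translation| + head_radius * sum |d rotation|, FD[0] = 0.
    Translations in mm (rows 0-2), rotations in rad (rows 3-5).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6 or motion.shape[1] < 2:
        raise ValueError(f"motion trace must be (6, T>=2), got {motion.shape}")
    d = np.diff(motion, axis=1)
    fd = np.zeros(motion.shape[1])
    fd[1:] = np.abs(d[:3]).sum(axis=0) + head_radius_mm * np.abs(d[3:]).sum(axis=0)
    return fd


def flag_motion_exclusions(mean_fd: np.ndarray, n_sd: float = 2.5) -> np.ndarray:
    """Flag subjects whose mean FD exceeds cohort mean + ``n_sd`` * cohort SD."""
    mean_fd = np.asarray(mean_fd, dtype=float)
    if mean_fd.ndim != 1 or mean_fd.size < 3:
        raise ValueError("need mean FD for at least 3 subjects")
    return mean_fd > mean_fd.mean() + n_sd * mean_fd.std(ddof=1)


def build_friston24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 motion expansion: [R, R^2, R_{t-1}, R_{t-1}^2] per parameter.

    Input (6, T); output (T, 24) with the lagged rows zero-padded at t=0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6 or motion.shape[1] < 2:
        raise ValueError(f"motion trace must be (6, T>=2), got {motion.shape}")
    R = motion.T  # (T, 6)
    lag = np.zeros_like(R)
    lag[1:] = R[:-1]
    return np.hstack([R, R ** 2, lag, lag ** 2])


def bandpass_filter(vol: Volume4D, low_hz: float = 0.01, high_hz: float = 0.08) -> Volume4D:
    """Ideal rectangular band-pass per voxel, removing the temporal mean.

    DFT bins with low_hz <= f <= high_hz are kept, everything else (including
    DC) zeroed. ``high_hz`` must lie below the Nyquist frequency 1/(2 TR).
    """
    nyq = 1.0 / (2.0 * vol.tr)
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist {nyq:.4g}")
    data = np.asarray(vol.data)
    series = data[vol.mask]  # (n_vox, T)
    series = series - series.mean(axis=1, keepdims=True)
    out = _bandpass_series(series, vol.tr, low_hz, high_hz)
    filtered = np.zeros_like(data)
    filtered[vol.mask] = out
    return vol.with_data(filtered)


def _bandpass_series(series: np.ndarray, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    T = series.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1).astype(series.dtype)


def extract_tissue_signal(vol: Volume4D, tissue_mask: np.ndarray) -> np.ndarray:
    """Mean time series over a tissue mask (e.g. WM or CSF)."""
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != vol.data.shape[:3]:
        raise ValueError("tissue mask shape does not match volume grid")
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    return vol.data[tissue_mask].mean(axis=0)


def build_confounds(motion: np.ndarray, vol: Volume4D | None = None,
                    wm_mask: np.ndarray | None = None,
                    csf_mask: np.ndarray | None = None) -> ConfoundSet:
    """Friston-24 block plus optional WM and CSF mean signals (26 columns)."""
    mat = build_friston24(motion)
    labels = [f"{p}{s}" for s in ("", "_sq", "_lag", "_lag_sq")
              for p in ("tx", "ty", "tz", "rx", "ry", "rz")]
    cols = [mat]
    if wm_mask is not None:
        if vol is None:
            raise ValueError("volume required to extract WM signal")
        cols.append(extract_tissue_signal(vol, wm_mask)[:, None])
        labels.append("wm")
    if csf_mask is not None:
        if vol is None:
            raise ValueError("volume required to extract CSF signal")
        cols.append(extract_tissue_signal(vol, csf_mask)[:, None])
        labels.append("csf")
    return ConfoundSet(matrix=np.hstack(cols), labels=labels)


def regress_nuisance(vol: Volume4D, confounds: ConfoundSet,
                     filter_confounds: tuple | None = None) -> Volume4D:
    """Per-voxel least-squares residuals after regressing the confounds.

    An intercept is added internally. Residuals are orthogonal to every
    confound column. If ``filter_confounds`` is a (low_hz, high_hz) tuple the
    confounds are band-passed with the same ideal filter as the data first,
    so regression cannot reintroduce out-of-band nuisance frequencies.
    All-zero (constant) confound columns are dropped; genuinely collinear
    designs raise with the offending columns named.
    """
    X = np.asarray(confounds.matrix, dtype=float)
    if X.shape[0] != vol.n_timepoints:
        raise ValueError(f"confounds have {X.shape[0]} rows for {vol.n_timepoints} timepoints")
    T = X.shape[0]
    X = X - X.mean(axis=0, keepdims=True)
    keep = X.std(axis=0) > 1e-12
    labels = [l for l, k in zip(confounds.labels, keep) if k]
    X = X[:, keep]
    design = np.column_stack([np.ones(T), X])
    if T <= design.shape[1]:
        raise ValueError("need more timepoints than confound columns")
    # the rank contract applies to the confounds as provided; band-limiting
    # them below can legitimately reduce rank and is handled by SVD lstsq
    if np.linalg.matrix_rank(design) < design.shape[1]:
        dep = _dependent_columns(design[:, 1:], labels)
        raise ValueError(f"rank-deficient confound design; dependent columns: {dep}")
    if filter_confounds is not None:
        X = _bandpass_series(X.T, vol.tr, *filter_confounds).T
        design = np.column_stack([np.ones(T), X])

    data = np.asarray(vol.data)
    Y = data[vol.mask].T.astype(np.float64)  # (T, n_vox)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = (Y - design @ beta).T.astype(data.dtype)
    out = np.zeros_like(data)
    out[vol.mask] = resid
    return vol.with_data(out)


def _dependent_columns(X: np.ndarray, labels: list) -> list:
    dep = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(X.shape[0]), others])) == \
           np.linalg.matrix_rank(np.column_stack([np.ones(X.shape[0]), X])):
            dep.append(labels[j] if j < len(labels) else f"col{j}")
    return dep


def smooth_gaussian(obj, fwhm_mm: float = 6.0):
    """Separable Gaussian smoothing of a StatMap or Volume4D (per timepoint).

    sigma per axis = fwhm / (2.3548 * voxel size); the mask is re-applied
    after smoothing. fwhm_mm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return obj
    if isinstance(obj, Volume4D):
        sig = tuple(fwhm_mm * _FWHM_TO_SIGMA / v for v in obj.voxel_size) + (0.0,)
        out = ndimage.gaussian_filter(np.asarray(obj.data, dtype=np.float32), sigma=sig)
        out[~obj.mask] = 0.0
        return obj.with_data(out)
    if isinstance(obj, StatMap):
        sig = tuple(fwhm_mm * _FWHM_TO_SIGMA / v for v in voxel_sizes(obj.affine))
        out = ndimage.gaussian_filter(np.asarray(obj.values, dtype=float), sigma=sig)
        out[~obj.mask] = 0.0
        return obj.with_values(out)
    raise TypeError(f"cannot smooth object of type {type(obj).__name__}")
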
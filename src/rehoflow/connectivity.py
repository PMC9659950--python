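"""Seed-based whole-brain functional connectivity with Fisher r-to-z maps.

A seed region's mean time series is correlated (Pearson) with every in-mask
voxel; the correlation map is variance-stabilized with z = atanh(r) before
parametric group inference. Seeds are typically regions of interest defined
from significant ReHo clusters.
"""
from __future__ import annotations

import warnings

import numpy as np

from .grid import Volume4D, StatMap

__all__ = ["extract_roi_timeseries", "fc_map", "fisher_r_to_z", "fc_pipeline"]


def extract_roi_timeseries(vol: Volume4D, roi: np.ndarray) -> np.ndarray:
    """Per-timepoint mean over the ROI voxels."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vol.data.shape[:3]:
        raise ValueError("ROI grid does not match volume grid")
    if not roi.any():
        raise ValueError("ROI is empty")
    return np.asarray(vol.data[roi], dtype=np.float64).mean(axis=0)


def fc_map(vol: Volume4D, seed_series: np.ndarray) -> StatMap:
    """Pearson correlation of every in-mask voxel with the seed series.

    Voxels with zero variance get r = 0 (flagged with a warning).
    """
    seed = np.asarray(seed_series, dtype=np.float64)
    if seed.ndim != 1 or seed.size != vol.n_timepoints:
        raise ValueError("seed series length does not match volume timepoints")
    seed = seed - seed.mean()
    seed_ss = float(seed @ seed)
    if seed_ss <= 0:
        raise ValueError("seed series is constant")
    Y = np.asarray(vol.data[vol.mask], dtype=np.float64)
    Y = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Y * Y).sum(axis=1) * seed_ss)
    num = Y @ seed
    flat = np.zeros(Y.shape[0])
    ok = denom > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-variance voxels set to r=0", RuntimeWarning)
    flat[ok] = num[ok] / denom[ok]
    values = np.zeros(vol.mask.shape)
    values[vol.mask] = np.clip(flat, -1.0, 1.0)
    return StatMap(values=values, affine=vol.affine, mask=vol.mask, label="fc_r")


def fisher_r_to_z(r, clip: float = 1e-7):
    """Fisher variance-stabilizing transform z = atanh(r).

    |r| = 1 is clipped to 1 - ``clip`` with a warning; |r| > 1 raises.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlations must satisfy |r| <= 1")
    if np.any(np.abs(arr) >= 1 - clip):
        warnings.warn("|r| at or near 1 clipped before atanh", RuntimeWarning)
        arr = np.clip(arr, -1 + clip, 1 - clip)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def fc_pipeline(volumes, rois, roi_labels=None) -> dict:
    """Per-subject, per-ROI Fisher-z FC maps.

    ``volumes`` is a sequence of preprocessed (and typically smoothed)
    :class:`Volume4D`; ``rois`` a sequence of boolean masks on the same grid.
    Returns {roi_label: [z-map per subject]}.
    """
    rois = [np.asarray(r, dtype=bool) for r in rois]
    if roi_labels is None:
        roi_labels = [f"roi{i + 1}" for i in range(len(rois))]
    out = {label: [] for label in roi_labels}
    for vol in volumes:
        for roi, label in zip(rois, roi_labels):
            if roi.shape != vol.data.shape[:3]:
                raise ValueError(f"ROI {label} grid does not match volume grid")
            seed = extract_roi_timeseries(vol, roi)
            rmap = fc_map(vol, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                zvals = fisher_r_to_z(rmap.values[rmap.mask])
            values = np.zeros_like(rmap.values)
            values[rmap.mask] = zvals
            out[label].append(StatMap(values=values, affine=vol.affine,
                                      mask=vol.mask, label=f"zfc_{label}"))
    return out
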
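"""End-to-end orchestration: preprocess -> ReHo -> group inference -> ROI ->
seed-based FC -> group inference -> feature table -> classifier -> clinical
statistics, plus a recovery harness used for calibration studies.

The stage order mirrors the analysis design it implements: significant
group differences in the szReHo maps define the regions of interest that seed
the connectivity analysis; the significant ReHo and FC clusters provide the
classifier features.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, clinical, connectivity, inference, preprocess, reho, synthetic
from .grid import StatMap, Volume4D

__all__ = ["AnalysisParams", "CohortAnalysis", "preprocess_subject",
           "analyze_cohort", "run_full_analysis", "run_recovery_study"]

log = logging.getLogger("rehoflow")


@dataclass
class AnalysisParams:
    """Tunable parameters of the full analysis."""

    discard_volumes: int = 10
    head_radius_mm: float = 50.0
    fd_sd_threshold: float = 2.5
    low_hz: float = 0.01
    high_hz: float = 0.08
    smooth_fwhm_mm: float = 6.0
    neighborhood: int = 27
    voxel_p: float = 0.005
    cluster_alpha: float = 0.05
    tails: str = "two"
    connectivity: int = 26
    fc_on_smoothed: bool = True
    prune_threshold: float = 0.75
    c_grid: tuple = classify.DEFAULT_C_GRID
    n_perm: int = 199
    run_classifier: bool = True
    run_permutation: bool = True
    seed: int = 0


@dataclass
class CohortAnalysis:
    """All stage outputs of one cohort analysis."""

    qc: pd.DataFrame
    excluded: np.ndarray
    szreho_maps: list
    reho_tmap: inference.TMap
    reho_clusters: list
    rois: list
    roi_labels: list
    fc_tmaps: dict
    fc_clusters: dict
    features: pd.DataFrame | None
    labels: np.ndarray
    report: classify.ClassifierReport | None
    clinical_stats: pd.DataFrame | None
    smoothness: inference.SmoothnessEstimate


def preprocess_subject(vol: Volume4D, motion: np.ndarray, params: AnalysisParams,
                       wm_mask=None, csf_mask=None) -> Volume4D:
    """Single-subject functional chain: discard, band-pass, nuisance regression.

    Filtering precedes regression, and the confounds are filtered with the
    same band so regression cannot reintroduce nuisance frequencies. The
    output is unsmoothed (ReHo input); FC smoothing happens downstream.
    """
    vol = preprocess.discard_initial_volumes(vol, params.discard_volumes)
    motion = motion[:, params.discard_volumes:]
    vol = preprocess.bandpass_filter(vol, params.low_hz, params.high_hz)
    confounds = preprocess.build_confounds(motion, vol, wm_mask, csf_mask)
    return preprocess.regress_nuisance(vol, confounds,
                                       filter_confounds=(params.low_hz, params.high_hz))


def analyze_cohort(volumes, motions, labels, params: AnalysisParams | None = None,
                   clinical_table: pd.DataFrame | None = None,
                   wm_mask=None, csf_mask=None) -> CohortAnalysis:
    """Run the full in-memory analysis on a cohort of 4D volumes.

    ``labels`` is an array of 1 (group 1, e.g. impaired) and 2 aligned with
    ``volumes``/``motions``. Subjects flagged by motion QC are excluded from
    every subsequent stage.
    """
    params = params or AnalysisParams()
    labels = np.asarray(labels)
    mask = volumes[0].mask

    # --- motion QC
    mean_fd = np.array([
        preprocess.framewise_displacement(m[:, params.discard_volumes:],
                                          params.head_radius_mm).mean()
        for m in motions])
    excluded = preprocess.flag_motion_exclusions(mean_fd, params.fd_sd_threshold)
    qc = pd.DataFrame({"mean_fd": mean_fd, "excluded": excluded})
    keep = ~excluded
    if keep.sum() < 4 or len(np.unique(labels[keep])) < 2:
        raise ValueError("motion QC left fewer than 2 usable subjects per group")
    log.info("motion QC: excluded %d of %d subjects", int(excluded.sum()), len(motions))

    # --- preprocess + szReHo per subject; keep preprocessed volumes for FC
    pre_volumes, sz_maps = [], []
    for i, flag in enumerate(keep):
        if not flag:
            pre_volumes.append(None)
            sz_maps.append(None)
            continue
        pv = preprocess_subject(volumes[i], motions[i], params, wm_mask, csf_mask)
        pre_volumes.append(pv)
        raw = reho.reho_map(pv, neighborhood=params.neighborhood)
        m = reho.normalize_global_mean(raw)
        m = preprocess.smooth_gaussian(m, params.smooth_fwhm_mm)
        sz_maps.append(reho.standardize_z(m))
    reho_mask = next(m for m in sz_maps if m is not None).mask

    g1 = [m for m, l, k in zip(sz_maps, labels, keep) if k and l == 1]
    g2 = [m for m, l, k in zip(sz_maps, labels, keep) if k and l == 2]

    # --- ReHo group inference
    tmap = inference.voxelwise_ttest(g1, g2, reho_mask, contrast="group1-group2")
    smooth_est = inference.estimate_smoothness(
        inference.group_residuals(g1, g2), reho_mask, volumes[0].voxel_size)
    clusters = inference.grf_cluster_threshold(
        tmap, smooth_est, voxel_p=params.voxel_p, cluster_alpha=params.cluster_alpha,
        tails=params.tails, connectivity=params.connectivity)
    log.info("ReHo inference: %d significant clusters", len(clusters))

    rois = [inference.define_roi_from_cluster(c, mask.shape) for c in clusters]
    roi_labels = [f"reho_c{j + 1}" for j in range(len(rois))]

    # --- seed-based FC per ROI (skipped when no ROIs survive)
    fc_tmaps: dict = {}
    fc_clusters: dict = {}
    fc_maps_by_roi: dict = {lab: [] for lab in roi_labels}
    if rois:
        fc_subject_labels = []
        for i, flag in enumerate(keep):
            if not flag:
                continue
            pv = pre_volumes[i]
            if params.fc_on_smoothed:
                pv = preprocess.smooth_gaussian(pv, params.smooth_fwhm_mm)
            zmaps = connectivity.fc_pipeline([pv], rois, roi_labels)
            for lab in roi_labels:
                fc_maps_by_roi[lab].append(zmaps[lab][0])
            fc_subject_labels.append(labels[i])
        fc_subject_labels = np.asarray(fc_subject_labels)
        for lab in roi_labels:
            maps = fc_maps_by_roi[lab]
            f1 = [m for m, l in zip(maps, fc_subject_labels) if l == 1]
            f2 = [m for m, l in zip(maps, fc_subject_labels) if l == 2]
            ft = inference.voxelwise_ttest(f1, f2, mask, contrast=f"group1-group2 zFC {lab}")
            fsm = inference.estimate_smoothness(
                inference.group_residuals(f1, f2), mask, volumes[0].voxel_size)
            fc_tmaps[lab] = ft
            fc_clusters[lab] = inference.grf_cluster_threshold(
                ft, fsm, voxel_p=params.voxel_p, cluster_alpha=params.cluster_alpha,
                tails=params.tails, connectivity=params.connectivity)
            log.info("FC inference (%s): %d significant clusters", lab, len(fc_clusters[lab]))

    # --- feature table from significant clusters
    features = None
    report = None
    kept_idx = [i for i, f in enumerate(keep) if f]
    if rois:
        names, per_subject = [], [[] for _ in kept_idx]
        for j, lab in enumerate(roi_labels):
            names.append(f"szreho_{lab}")
            for s, i in enumerate(kept_idx):
                per_subject[s].append(sz_maps[i].values)
        cluster_masks = [c.mask(mask.shape) for c in clusters]
        for lab in roi_labels:
            for q, fc_c in enumerate(fc_clusters.get(lab, [])):
                names.append(f"zfc_{lab}_c{q + 1}")
                cluster_masks.append(fc_c.mask(mask.shape))
                for s in range(len(kept_idx)):
                    per_subject[s].append(fc_maps_by_roi[lab][s].values)
        features = classify.assemble_features(per_subject, cluster_masks, names)
        y = labels[keep]
        if params.run_classifier and features.shape[1] >= 1:
            best_c, _ = classify.grid_search_logistic(
                features, y, grid=params.c_grid, threshold=params.prune_threshold)
            preds, scores = classify.loocv_evaluate(
                features, y, C=best_c, threshold=params.prune_threshold)
            report = classify.compute_metrics(preds, scores, y)
            if params.run_permutation:
                report.permutation_p = classify.permutation_test(
                    features, y, n_perm=params.n_perm, seed=params.seed,
                    threshold=params.prune_threshold, c_grid=(best_c,))

    clin_stats = None
    if clinical_table is not None:
        clin_stats = clinical.clinical_comparison_table(clinical_table)

    return CohortAnalysis(qc=qc, excluded=excluded, szreho_maps=sz_maps,
                          reho_tmap=tmap, reho_clusters=clusters, rois=rois,
                          roi_labels=roi_labels, fc_tmaps=fc_tmaps,
                          fc_clusters=fc_clusters, features=features,
                          labels=labels[keep], report=report,
                          clinical_stats=clin_stats, smoothness=smooth_est)


# ---------------------------------------------------------------------------
# calibration / recovery harness

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|)."""
    a, b = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 0.0


def run_recovery_study(n_replicates: int = 20, seed: int = 0,
                       spec_kwargs: dict | None = None,
                       params: AnalysisParams | None = None) -> pd.DataFrame:
    """Planted-effect recovery over replicate synthetic cohorts.

    For each replicate cohort the full pipeline runs end to end; the study
    records the best Dice between a significant ReHo cluster and the planted
    synchrony-drop region, and whether any significant FC cluster (from any
    recovered ROI) overlaps the planted coupling target.
    """
    kwargs = dict(grid_shape=(24, 24, 24), n_group1=20, n_group2=20)
    if spec_kwargs:
        kwargs.update(spec_kwargs)
    params = params or AnalysisParams(run_classifier=False, run_permutation=False)
    rows = []
    for rep in range(n_replicates):
        spec = synthetic.CohortSpec(rng_seed=int(seed) * 1000 + rep, **kwargs)
        volumes, motions, _, truth = synthetic.generate_cohort(spec)
        res = analyze_cohort(volumes, motions, truth.labels, params)
        truth_mask = truth.effect_masks[0]
        best_dice = max((dice(c.mask(spec.grid_shape), truth_mask)
                         for c in res.reho_clusters), default=0.0)
        fc_hit = False
        if truth.target_mask is not None:
            for lab, cl in res.fc_clusters.items():
                for c in cl:
                    if (c.mask(spec.grid_shape) & truth.target_mask).any():
                        fc_hit = True
        rows.append({"replicate": rep, "n_reho_clusters": len(res.reho_clusters),
                     "best_dice": best_dice, "fc_target_detected": fc_hit})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk-based full run

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(spec: synthetic.CohortSpec, out_dir: str | Path,
                      params: AnalysisParams | None = None) -> dict:
    """Simulate a cohort, run every stage, write artifacts and a manifest.

    Writes per-subject NIfTI volumes, motion TSVs, the clinical table, ROI
    masks, t-maps, cluster tables, the feature table, the classifier report
    and a manifest listing every file with its sha256 and the master seed.
    """
    params = params or AnalysisParams()
    out = Path(out_dir)
    (out / "sub").mkdir(parents=True, exist_ok=True)
    volumes, motions, clin, truth = synthetic.generate_cohort(spec)
    files = []

    import nibabel as nib
    nib.save(nib.Nifti1Image(spec.mask.astype(np.uint8), spec.affine), str(out / "mask.nii.gz"))
    files.append(out / "mask.nii.gz")
    for i, (vol, mot) in enumerate(zip(volumes, motions)):
        vp = out / "sub" / f"sub-{i + 1:03d}_bold.nii.gz"
        vol.save(vp)
        mp = out / "sub" / f"sub-{i + 1:03d}_motion.tsv"
        pd.DataFrame(mot.T, columns=["tx", "ty", "tz", "rx", "ry", "rz"]).to_csv(
            mp, sep="\t", index=False)
        files += [vp, mp]
    clin_path = out / "clinical.tsv"
    clin.to_csv(clin_path, sep="\t", index=False)
    files.append(clin_path)

    res = analyze_cohort(volumes, motions, truth.labels, params, clinical_table=clin,
                         wm_mask=spec.wm_mask, csf_mask=spec.csf_mask)

    qc_path = out / "qc.json"
    qc_path.write_text(json.dumps(res.qc.to_dict(orient="list"), indent=2))
    files.append(qc_path)
    tpath = out / "reho_tmap.nii.gz"
    StatMap(res.reho_tmap.values, res.reho_tmap.affine, res.reho_tmap.mask).save(tpath)
    files.append(tpath)
    ct = _cluster_table(res.reho_clusters)
    cpath = out / "reho_clusters.csv"
    ct.to_csv(cpath, index=False)
    files.append(cpath)
    for lab in res.roi_labels:
        rpath = out / f"{lab}_roi.nii.gz"
        nib.save(nib.Nifti1Image(res.rois[res.roi_labels.index(lab)].astype(np.uint8),
                                 spec.affine), str(rpath))
        files.append(rpath)
        fpath = out / f"fc_{lab}_clusters.csv"
        _cluster_table(res.fc_clusters.get(lab, [])).to_csv(fpath, index=False)
        files.append(fpath)
    if res.features is not None:
        fpath = out / "features.csv"
        res.features.assign(label=res.labels).to_csv(fpath, index=False)
        files.append(fpath)
    if res.report is not None:
        rpath = out / "classifier_report.json"
        rpath.write_text(json.dumps(res.report.to_dict(), indent=2))
        files.append(rpath)
    if res.clinical_stats is not None:
        spath = out / "clinical_stats.csv"
        res.clinical_stats.to_csv(spath, index=False)
        files.append(spath)

    manifest = {
        "seed": spec.rng_seed,
        "params": asdict(params),
        "n_reho_clusters": len(res.reho_clusters),
        "n_fc_clusters": {k: len(v) for k, v in res.fc_clusters.items()},
        "files": [{"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in files],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _cluster_table(clusters) -> pd.DataFrame:
    rows = [{"cluster": c.cluster_id, "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
             "peak_z_mm": c.peak_mm[2], "extent_voxels": c.extent,
             "peak_stat": c.peak_stat, "p_cluster": c.p_cluster} for c in clusters]
    return pd.DataFrame(rows, columns=["cluster", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                                       "extent_voxels", "peak_stat", "p_cluster"])
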
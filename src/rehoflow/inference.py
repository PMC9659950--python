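"""Voxelwise two-sample t-tests with Gaussian-random-field cluster correction.

The group contrast is a pooled-variance two-sample t per voxel. Cluster-level
multiple-comparison control follows classical random-field theory: field
smoothness (FWHM per axis) is estimated from the variance of spatial first
differences of standardized group-model residuals; the mask is expressed in
resolution elements (resels); the t-field is thresholded at the voxel-level
quantile and, via the probability transform, treated as a Gaussian field for
the expected-cluster-count (Euler characteristic) and cluster-extent
distributions. The cluster-level p for a cluster of k voxels is

    p = 1 - exp(-E[m] * P(extent >= k)),   P(extent >= k) = exp(-beta k_r^(2/3))

with E[m] the expected suprathreshold cluster count over all tails searched,
k_r the extent in resels and beta set by the expected cluster size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn

from .grid import StatMap, voxel_sizes

__all__ = [
    "TMap", "ClusterResult", "SmoothnessEstimate",
    "voxelwise_ttest", "estimate_smoothness", "resel_counts",
    "extract_clusters", "grf_cluster_threshold", "define_roi_from_cluster",
    "permutation_cluster_threshold", "null_fwe_rate",
]

_SQRT_4LN2 = np.sqrt(4.0 * np.log(2.0))


@dataclass
class TMap:
    """Voxelwise t statistics with their degrees of freedom."""

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    df: int
    contrast: str = "A-B"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("t values must be finite inside the mask")


@dataclass
class ClusterResult:
    """A suprathreshold connected component of a statistic map."""

    cluster_id: int
    indices: tuple                 # voxel indices (arrays) of the cluster
    extent: int                    # voxels
    peak_ijk: tuple
    peak_mm: tuple
    peak_stat: float
    p_cluster: float | None = None
    sign: int = 1

    def mask(self, shape: tuple) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.indices] = True
        return m


@dataclass
class SmoothnessEstimate:
    """Estimated field smoothness and the mask's resel counts."""

    fwhm_mm: np.ndarray           # per axis
    fwhm_vox: np.ndarray
    resels: np.ndarray            # R0..R3 of the mask at this smoothness

    def __post_init__(self) -> None:
        if not np.all(self.fwhm_mm > 0):
            raise ValueError("FWHM must be positive")


def voxelwise_ttest(group_a, group_b, mask: np.ndarray,
                    equal_var: bool = True, contrast: str = "A-B") -> TMap:
    """Pooled-variance two-sample t per voxel, sign convention A - B.

    ``group_a``/``group_b`` are sequences of StatMap or 3D arrays on the same
    grid. Zero-variance voxels get t = 0.
    """
    A = _stack(group_a)
    B = _stack(group_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    affine = group_a[0].affine if isinstance(group_a[0], StatMap) else np.eye(4)
    mask = np.asarray(mask, dtype=bool)
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    if equal_var:
        df = na + nb - 2
        sp2 = (A.var(axis=0, ddof=1) * (na - 1) + B.var(axis=0, ddof=1) * (nb - 1)) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        va, vb = A.var(axis=0, ddof=1) / na, B.var(axis=0, ddof=1) / nb
        se = np.sqrt(va + vb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df_w = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
        df = int(np.floor(np.nanmedian(df_w[mask])))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    t[~mask] = 0.0
    return TMap(values=t, affine=affine, mask=mask, df=df, contrast=contrast)


def _stack(maps) -> np.ndarray:
    arrs = [m.values if isinstance(m, StatMap) else np.asarray(m) for m in maps]
    return np.stack([np.asarray(a, dtype=np.float64) for a in arrs], axis=0)


def group_residuals(group_a, group_b) -> np.ndarray:
    """Residual maps of the two-group model (each map minus its group mean)."""
    A = _stack(group_a)
    B = _stack(group_b)
    return np.concatenate([A - A.mean(axis=0), B - B.mean(axis=0)], axis=0)


def estimate_smoothness(residual_maps: np.ndarray, mask: np.ndarray,
                        voxel_size) -> SmoothnessEstimate:
    """Per-axis FWHM from spatial first differences of standardized residuals.

    Residuals are standardized per voxel; for a Gaussian autocorrelation
    function the lag-1 correlation rho satisfies var(diff) = 2(1 - rho) and
    the generating kernel sigma (voxels) is sqrt(-1 / (4 ln rho)). The FWHM is
    floored at one voxel (a discrete white-noise field has no resolvable
    smoothness below the lattice spacing).
    """
    R = np.asarray(residual_maps, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if R.ndim != 4 or R.shape[0] < 3:
        raise ValueError("need at least 3 residual maps (n_maps, X, Y, Z)")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    sd = R.std(axis=0)
    ok = mask & (sd > 0)
    Z = np.where(ok, R / np.where(sd > 0, sd, 1.0), np.nan)

    fwhm_vox = np.empty(3)
    for axis in range(3):
        d = np.diff(Z, axis=axis + 1)
        pair_ok = _axis_pairs(ok, axis)
        vdiff = np.nanmean((d ** 2)[:, pair_ok]) if pair_ok.any() else 2.0
        rho = np.clip(1.0 - vdiff / 2.0, 1e-8, 1.0 - 1e-8)
        sigma = np.sqrt(-1.0 / (4.0 * np.log(rho)))
        fwhm_vox[axis] = max(1.0, 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma)
    fwhm_mm = fwhm_vox * voxel_size
    return SmoothnessEstimate(fwhm_mm=fwhm_mm, fwhm_vox=fwhm_vox,
                              resels=resel_counts(mask, fwhm_vox))


def _axis_pairs(mask: np.ndarray, axis: int) -> np.ndarray:
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    return mask[tuple(sl_lo)] & mask[tuple(sl_hi)]


def resel_counts(mask: np.ndarray, fwhm_vox) -> np.ndarray:
    """Resel counts R0..R3 of a mask lattice at the given per-axis FWHM.

    Counts points, edges, faces and cubes of the in-mask lattice and combines
    them with the per-axis resel sizes (voxel/FWHM), following the standard
    lattice formula used for random-field expectations on irregular masks.
    """
    m = np.asarray(mask, dtype=bool)
    rx, ry, rz = 1.0 / np.asarray(fwhm_vox, dtype=float)
    ex = m[:-1, :, :] & m[1:, :, :]
    ey = m[:, :-1, :] & m[:, 1:, :]
    ez = m[:, :, :-1] & m[:, :, 1:]
    fxy = ex[:, :-1, :] & ex[:, 1:, :]
    fxz = ex[:, :, :-1] & ex[:, :, 1:]
    fyz = ey[:, :, :-1] & ey[:, :, 1:]
    cub = fxy[:, :, :-1] & fxy[:, :, 1:]
    P, Ex, Ey, Ez = m.sum(), ex.sum(), ey.sum(), ez.sum()
    Fxy, Fxz, Fyz, C = fxy.sum(), fxz.sum(), fyz.sum(), cub.sum()
    r0 = P - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C
    r1 = (Ex * rx + Ey * ry + Ez * rz) - (Fxy * (rx + ry) + Fxz * (rx + rz) + Fyz * (ry + rz)) \
        + C * (rx + ry + rz)
    r2 = Fxy * rx * ry + Fxz * rx * rz + Fyz * ry * rz - C * (rx * ry + rx * rz + ry * rz)
    r3 = C * rx * ry * rz
    return np.array([r0, r1, r2, r3], dtype=float)


def _ec_densities(u: float) -> np.ndarray:
    """Euler-characteristic densities rho_0..rho_3 of a unit Gaussian field."""
    e = np.exp(-u * u / 2.0)
    return np.array([
        stats.norm.sf(u),
        _SQRT_4LN2 / (2.0 * np.pi) * e,
        (4.0 * np.log(2.0)) / (2.0 * np.pi) ** 1.5 * u * e,
        _SQRT_4LN2 ** 3 / (2.0 * np.pi) ** 2 * (u * u - 1.0) * e,
    ])


def extract_clusters(stat_values: np.ndarray, threshold_mask: np.ndarray,
                     connectivity: int = 26, affine: np.ndarray | None = None,
                     sign: int = 1) -> list:
    """Connected components of a thresholded map with peak and extent.

    ``connectivity`` in {6, 18, 26}; the peak is the max |stat| voxel and its
    coordinate is reported in mm through the affine.
    """
    structure = {6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2),
                 26: ndimage.generate_binary_structure(3, 3)}.get(connectivity)
    if structure is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    if affine is None:
        affine = np.eye(4)
    labeled, n = ndimage.label(np.asarray(threshold_mask, dtype=bool), structure=structure)
    clusters = []
    for cid in range(1, n + 1):
        idx = np.nonzero(labeled == cid)
        vals = stat_values[idx]
        peak_pos = int(np.argmax(np.abs(vals)))
        ijk = tuple(int(a[peak_pos]) for a in idx)
        mm = tuple((affine @ np.array(ijk + (1,)))[:3])
        clusters.append(ClusterResult(cluster_id=cid, indices=idx, extent=len(vals),
                                      peak_ijk=ijk, peak_mm=mm,
                                      peak_stat=float(vals[peak_pos]), sign=sign))
    return clusters


def grf_cluster_threshold(tmap: TMap, smoothness: SmoothnessEstimate,
                          voxel_p: float = 0.005, cluster_alpha: float = 0.05,
                          tails: str = "two", connectivity: int = 26,
                          return_all: bool = False) -> list:
    """Random-field cluster-level correction of a t map.

    Thresholds the t field at the voxel-level quantile (two-tailed by default,
    with voxel_p split symmetrically over the tails), forms connected
    clusters, and assigns each a corrected cluster-level p from the Gaussian
    random-field expected cluster count and extent distribution. Returns the
    clusters with p < ``cluster_alpha`` (all clusters if ``return_all``),
    sorted by extent, descending. An empty suprathreshold set returns [].
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0,1)")
    if tails not in ("two", "pos", "neg"):
        raise ValueError("tails must be 'two', 'pos' or 'neg'")
    p_tail = voxel_p / 2.0 if tails == "two" else voxel_p
    n_tails = 2 if tails == "two" else 1
    tcrit = stats.t.ppf(1.0 - p_tail, tmap.df)
    u = stats.norm.isf(p_tail)  # Gaussianized height threshold

    resels = smoothness.resels
    Em = float(resels @ _ec_densities(u))          # expected clusters, one tail
    EN = stats.norm.sf(u) * resels[3]              # expected suprathreshold resels
    vox_per_resel = float(np.prod(smoothness.fwhm_vox))

    clusters = []
    if tails in ("two", "pos"):
        clusters += extract_clusters(tmap.values, tmap.mask & (tmap.values > tcrit),
                                     connectivity, tmap.affine, sign=1)
    if tails in ("two", "neg"):
        clusters += extract_clusters(tmap.values, tmap.mask & (tmap.values < -tcrit),
                                     connectivity, tmap.affine, sign=-1)
    if Em <= 0 or EN <= 0:
        for c in clusters:
            c.p_cluster = 1.0
    else:
        En = EN / Em  # expected cluster size in resels
        beta = (gamma_fn(2.5) / En) ** (2.0 / 3.0)
        for c in clusters:
            k_resel = c.extent / vox_per_resel
            Pn = np.exp(-beta * k_resel ** (2.0 / 3.0))
            c.p_cluster = float(min(1.0, 1.0 - np.exp(-n_tails * Em * Pn)))
    clusters.sort(key=lambda c: -c.extent)
    if return_all:
        return clusters
    return [c for c in clusters if c.p_cluster < cluster_alpha]


def define_roi_from_cluster(cluster: ClusterResult, shape: tuple) -> np.ndarray:
    """Boolean ROI mask of a cluster's voxels."""
    if cluster.extent < 1:
        raise ValueError("cluster is empty")
    return cluster.mask(shape)


def permutation_cluster_threshold(group_a, group_b, mask: np.ndarray,
                                  voxel_p: float = 0.005, cluster_alpha: float = 0.05,
                                  tails: str = "two", connectivity: int = 26,
                                  n_perm: int = 500, seed: int = 0,
                                  return_all: bool = False) -> list:
    """Nonparametric fallback: cluster-level FWE p from label permutations.

    The cluster-forming threshold matches :func:`grf_cluster_threshold`; the
    corrected p of each observed cluster is the fraction of label
    permutations whose maximum suprathreshold extent (over the searched
    tails) reaches the cluster's extent, with the +1 correction. Useful as a
    validation of the random-field p-values where their lattice assumptions
    are in doubt.
    """
    A = _stack(group_a)
    B = _stack(group_b)
    mask = np.asarray(mask, dtype=bool)
    na = A.shape[0]
    allmaps = np.concatenate([A, B], axis=0)
    rng = np.random.default_rng(seed)

    p_tail = voxel_p / 2.0 if tails == "two" else voxel_p
    tcrit = stats.t.ppf(1.0 - p_tail, na + B.shape[0] - 2)
    structure = {6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2),
                 26: ndimage.generate_binary_structure(3, 3)}[connectivity]

    def max_extent(tvals: np.ndarray) -> int:
        mx = 0
        signs = {"two": (1, -1), "pos": (1,), "neg": (-1,)}[tails]
        for sgn in signs:
            labeled, n = ndimage.label(mask & (sgn * tvals > tcrit), structure=structure)
            if n:
                mx = max(mx, int(np.bincount(labeled.ravel())[1:].max()))
        return mx

    observed = voxelwise_ttest(A, B, mask)
    clusters = []
    if tails in ("two", "pos"):
        clusters += extract_clusters(observed.values, mask & (observed.values > tcrit),
                                     connectivity, observed.affine, sign=1)
    if tails in ("two", "neg"):
        clusters += extract_clusters(observed.values, mask & (observed.values < -tcrit),
                                     connectivity, observed.affine, sign=-1)
    null_max = np.empty(n_perm)
    idx = np.arange(allmaps.shape[0])
    for b in range(n_perm):
        perm = rng.permutation(idx)
        t_b = voxelwise_ttest(allmaps[perm[:na]], allmaps[perm[na:]], mask)
        null_max[b] = max_extent(t_b.values)
    for c in clusters:
        c.p_cluster = float((1 + np.sum(null_max >= c.extent)) / (n_perm + 1))
    clusters.sort(key=lambda c: -c.extent)
    if return_all:
        return clusters
    return [c for c in clusters if c.p_cluster < cluster_alpha]


def null_fwe_rate(n_cohorts: int = 200, grid_shape=(24, 24, 24), n_per_group: int = 10,
                  smooth_fwhm_vox: float = 2.75, voxel_p: float = 0.005,
                  cluster_alpha: float = 0.05, seed: int = 0,
                  mask: np.ndarray | None = None) -> float:
    """Monte-Carlo family-wise error rate of the cluster correction under the null.

    Each cohort draws per-subject Gaussian white-noise maps smoothed to a
    known FWHM (in voxels), runs the group t-test, estimates smoothness from
    the group residuals and applies the cluster correction; the FWE rate is
    the fraction of cohorts with at least one surviving cluster.

    The default smoothness (2.75 voxels) is the operating point of the group
    maps this correction is applied to, as measured by the pipeline's own
    smoothness estimator on synthetic szReHo cohorts (4 mm intrinsic noise
    smoothness, the 27-voxel ReHo neighborhood, and the 6 mm analysis kernel
    at 3 mm voxels combine to ~8.3 mm). The continuum cluster-count
    approximation degrades on lattices much coarser than that (FWHM of ~2
    voxels or below), where the correction becomes conservative.
    """
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    sigma = smooth_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    affine = np.eye(4)
    hits = 0
    for _ in range(n_cohorts):
        maps = ndimage.gaussian_filter(
            rng.standard_normal((2 * n_per_group,) + tuple(grid_shape)),
            sigma=(0.0, sigma, sigma, sigma))
        A, B = maps[:n_per_group], maps[n_per_group:]
        tmap = voxelwise_ttest(A, B, mask)
        sm = estimate_smoothness(group_residuals(A, B), mask, 1.0)
        if grf_cluster_threshold(tmap, sm, voxel_p=voxel_p, cluster_alpha=cluster_alpha):
            hits += 1
    return hits / n_cohorts
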
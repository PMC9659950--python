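"""Synthetic resting-state cohorts with known ground truth.

Generates two groups of 4D BOLD volumes on a common grid, with

* group-specific reductions of local temporal synchrony in designated regions
  (the quantity regional homogeneity measures),
* group-specific seed-to-target coupling (the quantity seed-based functional
  connectivity measures),
* AR(1) temporal noise with configurable spatial smoothness,
* linear drift, motion-parameter leakage and WM/CSF-like global components,
* per-subject motion traces, a clinical covariate table, and optional
  airflow/SpO2 traces with planted apnea/hypopnea events.

The local-synchrony model: every voxel in a planted region mixes a shared
AR(1) latent signal u(t) into its own noise with weight w, so its series is
``w*u + sqrt(1-w^2)*noise``. The shared-variance fraction s = w^2 sets the
expected pairwise correlation inside the region; the group effect is realized
by scaling s down by the region's ``synchrony_drop`` in group 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .grid import Volume4D

__all__ = [
    "EffectRegion", "SeedCoupling", "CohortSpec", "GroundTruth",
    "default_brain_mask", "generate_cohort", "generate_subject_bold",
    "generate_motion_params", "generate_clinical_table",
    "generate_respiratory_traces", "TABLE1_DEFAULTS",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


# ---------------------------------------------------------------------------
# specification types

@dataclass
class EffectRegion:
    """A region with planted local-synchrony difference between groups."""

    mask: np.ndarray
    synchrony_drop: float  # fraction of shared variance removed in group 1, in [0, 1]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.synchrony_drop <= 1.0:
            raise ValueError(f"synchrony_drop must be in [0,1], got {self.synchrony_drop}")
        if not self.mask.any():
            raise ValueError("effect region mask is empty")


@dataclass
class SeedCoupling:
    """Planted seed-to-target coupling, with per-group correlation."""

    seed: np.ndarray
    target: np.ndarray
    r_group1: float
    r_group2: float

    def __post_init__(self) -> None:
        self.seed = np.asarray(self.seed, dtype=bool)
        self.target = np.asarray(self.target, dtype=bool)
        for name, r in (("r_group1", self.r_group1), ("r_group2", self.r_group2)):
            if not -1.0 < r < 1.0:
                raise ValueError(f"{name} must be in (-1,1), got {r}")
        if not self.seed.any() or not self.target.any():
            raise ValueError("seed/target masks must be nonempty")


def default_brain_mask(grid_shape: tuple) -> np.ndarray:
    """Spherical brain mask centered in the grid."""
    shape = tuple(grid_shape)
    center = (np.asarray(shape) - 1) / 2.0
    radius = min(shape) / 2.0 - 0.5
    ijk = np.indices(shape)
    dist2 = sum((ijk[a] - center[a]) ** 2 for a in range(3))
    return dist2 <= radius ** 2


def _cube(grid_shape: tuple, lo: int, hi: int, axis_offsets=(0, 0, 0)) -> np.ndarray:
    m = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(lo + o, hi + o) for o in axis_offsets)
    m[sl] = True
    return m


def _frac_cube(grid_shape: tuple, frac_start: tuple, size: int) -> np.ndarray:
    """Cube at fractional grid position, scaled so defaults work on any grid."""
    m = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(min(int(round(f * s)), s - size), min(int(round(f * s)), s - size) + size)
               for f, s in zip(frac_start, grid_shape))
    m[sl] = True
    return m


def _default_cubes(grid_shape: tuple) -> dict:
    s = min(grid_shape)
    eff_size = max(3, int(round(0.21 * s)))
    tissue_size = max(2, min(4, s // 6))
    return {
        "effect": _frac_cube(grid_shape, (0.25, 0.25, 0.25), eff_size),
        "target": _frac_cube(grid_shape, (0.54, 0.54, 0.54), eff_size),
        "wm": _frac_cube(grid_shape, (0.35, 0.55, 0.35), tissue_size),
        "csf": _frac_cube(grid_shape, (0.55, 0.25, 0.55), tissue_size),
    }


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group cohort.

    Defaults emulate the acquisition the pipeline targets: 240 volumes at
    TR = 2 s on a 3 mm isotropic grid, two groups of 48 and 47 subjects.
    """

    grid_shape: tuple = (24, 24, 24)
    n_timepoints: int = 240
    tr: float = 2.0
    n_group1: int = 48
    n_group2: int = 47
    voxel_size_mm: float = 3.0
    ar1_phi: float = 0.3
    spatial_fwhm_mm: float = 4.0
    base_synchrony: float = 0.5       # shared-variance fraction s in effect regions (group 2)
    effect_regions: list = None       # list[EffectRegion]; None -> one 5^3 cube, drop 0.6
    seed_coupling: SeedCoupling | None | str = "auto"  # "auto" -> seed = first effect
                                      # region, default target cube, r 0.2 vs 0.6; None -> none
    seed_coherence: float = 0.9       # latent weight of seed voxels when seed is not an effect region
    target_local_synchrony: float = 0.3  # latent weight inside the coupling residual of target voxels
    motion_amplitude: float = 0.02    # random-walk step SD in mm
    drift_amplitude: float = 0.2      # per-voxel linear drift coefficient SD (signal units)
    motion_leak: float = 0.1          # leakage of motion regressors into BOLD
    nuisance_leak: float = 0.15       # global leakage of the WM/CSF latents
    baseline: float = 100.0           # additive BOLD baseline
    mask: np.ndarray = None           # brain mask; None -> centered sphere
    wm_mask: np.ndarray = None
    csf_mask: np.ndarray = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >=4 voxels, got {self.grid_shape}")
        for name in ("n_timepoints", "n_group1", "n_group2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError(f"ar1_phi must be in (-1,1), got {self.ar1_phi}")
        if not 0.0 <= self.base_synchrony <= 1.0:
            raise ValueError(f"base_synchrony must be in [0,1], got {self.base_synchrony}")
        if self.spatial_fwhm_mm < 0 or self.voxel_size_mm <= 0:
            raise ValueError("spatial_fwhm_mm must be >=0 and voxel_size_mm > 0")
        if self.mask is None:
            self.mask = default_brain_mask(self.grid_shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid_shape:
            raise ValueError("mask shape does not match grid_shape")
        cubes = _default_cubes(self.grid_shape)
        if self.wm_mask is None:
            self.wm_mask = cubes["wm"] & self.mask
        if self.csf_mask is None:
            self.csf_mask = cubes["csf"] & self.mask
        for name in ("wm_mask", "csf_mask"):
            if not getattr(self, name).any():
                raise ValueError(f"{name} is empty")
        if self.effect_regions is None:
            self.effect_regions = [EffectRegion(cubes["effect"], 0.6)]
        self.effect_regions = list(self.effect_regions)
        if isinstance(self.seed_coupling, str):
            if self.seed_coupling != "auto":
                raise ValueError("seed_coupling must be a SeedCoupling, None or 'auto'")
            self.seed_coupling = SeedCoupling(
                seed=self.effect_regions[0].mask.copy(),
                target=cubes["target"],
                r_group1=0.2, r_group2=0.6) if self.effect_regions else None
        for i, reg in enumerate(self.effect_regions):
            if reg.mask.shape != self.grid_shape:
                raise ValueError(f"effect_regions[{i}] mask shape does not match grid")
            if not (reg.mask & self.mask).any():
                raise ValueError(f"effect_regions[{i}] lies entirely outside the brain mask")
        if self.seed_coupling is not None:
            for name, m in (("seed", self.seed_coupling.seed), ("target", self.seed_coupling.target)):
                if m.shape != self.grid_shape:
                    raise ValueError(f"seed_coupling {name} mask shape does not match grid")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2


@dataclass
class GroundTruth:
    """Planted effects and labels for a generated cohort."""

    labels: np.ndarray                      # 1 = group 1 (impaired), 2 = group 2
    effect_masks: list                      # bool masks of planted synchrony-drop regions
    effect_drops: list                      # drop per region
    seed_mask: np.ndarray | None
    target_mask: np.ndarray | None
    coupling_r: tuple | None                # (r group1, r group2)
    respiratory_event_counts: np.ndarray | None = None


# ---------------------------------------------------------------------------
# low-level generators

def _ar1(rng: np.random.Generator, n: int, phi: float, size=()) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis (burn-in start)."""
    if phi == 0.0:
        return rng.standard_normal(size + (n,))
    burn = 100
    innov = rng.standard_normal(size + (n + burn,))
    out = signal.lfilter([1.0], [1.0, -phi], innov, axis=-1)[..., burn:]
    return out * np.sqrt(1.0 - phi ** 2)


def generate_motion_params(n_timepoints: int, amplitude: float, subject_seed) -> np.ndarray:
    """Smooth random-walk rigid-body motion trace.

    Returns a (6, T) array: 3 translations (mm) then 3 rotations (rad),
    zero at t=0. ``amplitude`` is the per-step SD in mm; rotation steps are
    scaled by 1/50 mm^-1 so that, under the 50 mm head-radius convention,
    rotations contribute to framewise displacement on the same scale as
    translations. The trace is linear in ``amplitude``, so mean FD scales
    proportionally.
    """
    if n_timepoints <= 1:
        raise ValueError("n_timepoints must be > 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(subject_seed)
    steps = rng.standard_normal((6, n_timepoints - 1))
    # mild temporal smoothing keeps the walk drift-like rather than jittery
    steps = ndimage.uniform_filter1d(steps, size=3, axis=1, mode="nearest")
    walk = np.cumsum(steps, axis=1)
    trace = np.zeros((6, n_timepoints))
    trace[:, 1:] = walk
    trace[:3] *= amplitude
    trace[3:] *= amplitude / 50.0
    return trace


def generate_subject_bold(spec: CohortSpec, group: int, subject_seed) -> Volume4D:
    """One subject's 4D BOLD series under the spec's generative model.

    Each voxel series is a mixture of a shared local latent signal (weight set
    by the region's synchrony level), spatially smoothed AR(1) noise, a linear
    drift, leakage of the subject's motion parameters, and WM/CSF-like global
    components, on a common baseline.
    """
    if group not in (1, 2):
        raise ValueError(f"group must be 1 or 2, got {group}")
    rng = np.random.default_rng(subject_seed)
    shape, T = spec.grid_shape, spec.n_timepoints

    # spatially smoothed AR(1) noise field, unit in-mask variance
    noise = rng.standard_normal(shape + (T,), dtype=np.float32)
    if spec.spatial_fwhm_mm > 0:
        sigma_vox = spec.spatial_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_size_mm
        noise = ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0.0,))
    if spec.ar1_phi != 0.0:
        noise = signal.lfilter([1.0], [1.0, -spec.ar1_phi], noise, axis=-1).astype(np.float32)
    noise /= noise[spec.mask].std()

    data = noise.copy()

    def latent() -> np.ndarray:
        u = _ar1(rng, T, spec.ar1_phi)
        return u / u.std()

    # planted local synchrony
    region_latents = []
    for reg in spec.effect_regions:
        u = latent()
        region_latents.append(u)
        s = spec.base_synchrony * (1.0 - reg.synchrony_drop if group == 1 else 1.0)
        m = reg.mask & spec.mask
        data[m] = np.sqrt(s) * u + np.sqrt(1.0 - s) * noise[m]

    # planted seed-target coupling
    if spec.seed_coupling is not None:
        sc = spec.seed_coupling
        seed_m = sc.seed & spec.mask
        overlaps = any((reg.mask & sc.seed).any() for reg in spec.effect_regions)
        if overlaps and region_latents:
            g = region_latents[0]  # seed region is an effect region: reuse its latent
        else:
            g = latent()
            a = spec.seed_coherence
            data[seed_m] = a * g + np.sqrt(1.0 - a * a) * noise[seed_m]
        r = sc.r_group1 if group == 1 else sc.r_group2
        h = latent()
        wt = spec.target_local_synchrony
        tgt_m = sc.target & spec.mask
        resid = wt * h + np.sqrt(1.0 - wt * wt) * noise[tgt_m]
        data[tgt_m] = r * g + np.sqrt(1.0 - r * r) * resid

    # nuisance structure: drift, motion leakage, WM/CSF components
    t_ramp = np.linspace(-1.0, 1.0, T) * np.sqrt(3.0)  # unit-variance ramp
    if spec.drift_amplitude > 0:
        coef = rng.standard_normal(shape) * spec.drift_amplitude
        data += coef[..., None] * t_ramp

    motion = generate_motion_params(T, spec.motion_amplitude, _child_seed(subject_seed, 1))
    if spec.motion_leak > 0 and spec.motion_amplitude > 0:
        m = motion - motion.mean(axis=1, keepdims=True)
        sd = m.std(axis=1)
        m = m[sd > 0] / sd[sd > 0, None]
        for row in m:
            pattern = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
            pattern /= np.abs(pattern).max() + 1e-12
            data += spec.motion_leak * pattern[..., None] * row

    wm_sig, csf_sig = latent(), latent()
    data[spec.wm_mask] = 0.85 * wm_sig + 0.15 * data[spec.wm_mask]
    data[spec.csf_mask] = 0.85 * csf_sig + 0.15 * data[spec.csf_mask]
    if spec.nuisance_leak > 0:
        data += spec.nuisance_leak * (wm_sig + csf_sig) / 2.0

    data += spec.baseline
    data[~spec.mask] = 0.0
    return Volume4D(data=data.astype(np.float32), affine=spec.affine, tr=spec.tr, mask=spec.mask)


def _child_seed(subject_seed, stream: int):
    if isinstance(subject_seed, (list, tuple)):
        return list(subject_seed) + [stream]
    return [int(subject_seed), stream]


# ---------------------------------------------------------------------------
# clinical covariates

# per-variable ((mean, sd) group 1, (mean, sd) group 2, (lo, hi) truncation)
TABLE1_DEFAULTS = {
    "age": ((38.37, 8.06), (35.48, 8.86), (20.0, 60.0)),
    "education": ((13.06, 2.31), (13.59, 3.13), (0.0, 25.0)),
    "bmi": ((27.35, 3.08), (26.91, 4.13), (15.0, 50.0)),
    "neck_circumference": ((41.47, 2.92), (40.10, 2.60), (25.0, 60.0)),
    "waistline": ((99.66, 6.79), (97.59, 18.78), (50.0, 160.0)),
    "ahi": ((54.38, 23.26), (50.29, 18.78), (15.0, 130.0)),
    "lsao2": ((70.77, 12.46), (68.00, 12.38), (30.0, 100.0)),
    "msao2": ((92.21, 3.58), (91.71, 5.13), (50.0, 100.0)),
    "sleep_efficiency": ((78.91, 22.63), (84.86, 12.04), (0.0, 100.0)),
    "ai": ((30.52, 17.75), (33.59, 21.78), (0.0, 130.0)),
    "odi": ((47.40, 23.09), (43.34, 23.43), (0.0, 130.0)),
    "sao2_below_90": ((24.94, 19.88), (23.67, 16.25), (0.0, 100.0)),
    "moca": ((22.40, 2.36), (27.27, 1.17), (0.0, 30.0)),
}

MOCA_CUTOFF = 26


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_clinical_table(n1: int, n2: int, table1_params: dict | None = None,
                            rng_seed=0) -> pd.DataFrame:
    """Clinical covariate table for two groups.

    Gaussian draws truncated to plausible ranges; MoCA draws for group 1 are
    constrained below the MCI cutoff (26) and group 2 at or above it, so the
    group labels are consistent with the score that defines them. Variables
    are drawn independently (only per-group means/SDs are specified).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"group sizes must be positive, got n1={n1}, n2={n2}")
    params = dict(TABLE1_DEFAULTS)
    if table1_params:
        params.update(table1_params)
    rng = np.random.default_rng(rng_seed)
    rows = {"subject_id": [f"sub-{i + 1:03d}" for i in range(n1 + n2)],
            "group": ["MCI"] * n1 + ["nMCI"] * n2}
    for var, ((m1, s1), (m2, s2), (lo, hi)) in params.items():
        if var == "moca":
            # rejection-style truncation at the diagnostic cutoff; integer scores
            g1 = np.round(_trunc_normal(rng, m1, s1, lo, MOCA_CUTOFF - 0.501, n1))
            g2 = np.round(_trunc_normal(rng, m2, s2, MOCA_CUTOFF - 0.499, hi, n2))
            rows[var] = np.concatenate([g1, g2]).astype(int)
        else:
            g1 = _trunc_normal(rng, m1, s1, lo, hi, n1)
            g2 = _trunc_normal(rng, m2, s2, lo, hi, n2)
            rows[var] = np.concatenate([g1, g2])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# respiratory traces

def generate_respiratory_traces(duration_s: float, sampling_hz: float,
                                apnea_rate: float, hypopnea_rate: float,
                                subject_seed=0):
    """Airflow and SpO2 traces with planted respiratory events.

    Apneas are >=90% airflow amplitude reductions (planted at 95%) lasting
    >=10 s; hypopneas are >=30% reductions (planted at 50%) with a >=4% SpO2
    desaturation lagging the event onset. Event counts are Poisson at the
    given per-hour rates. Returns (airflow, spo2, events) where events is a
    list of dicts with kind, onset (s) and duration (s).
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 s")
    if apnea_rate < 0 or hypopnea_rate < 0:
        raise ValueError("event rates must be >= 0")
    rng = np.random.default_rng(subject_seed)
    n = int(round(duration_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    hours = duration_s / 3600.0

    breath = np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    amp = 1.0 + 0.08 * np.sin(2 * np.pi * 0.003 * t + rng.uniform(0, 2 * np.pi))

    n_ap = rng.poisson(apnea_rate * hours)
    n_hyp = rng.poisson(hypopnea_rate * hours)
    kinds = ["apnea"] * n_ap + ["hypopnea"] * n_hyp

    events: list[dict] = []
    envelope = np.ones(n)
    spo2 = 96.0 + 0.1 * rng.standard_normal(n)
    ramp_s = 2.0
    occupied: list[tuple] = []
    order = rng.permutation(len(kinds))
    for idx in order:
        kind = kinds[idx]
        dur = float(rng.uniform(12.0, 25.0))
        for _ in range(200):  # place without overlap (15 s margin)
            onset = float(rng.uniform(5.0, duration_s - dur - 10.0))
            if all(onset + dur + 15.0 < lo or onset > hi + 15.0 for lo, hi in occupied):
                break
        else:
            continue  # trace too crowded; drop the event (Poisson thinning)
        occupied.append((onset, onset + dur))
        factor = 0.05 if kind == "apnea" else 0.5
        i0, i1 = int(onset * sampling_hz), int((onset + dur) * sampling_hz)
        nr = max(1, int(ramp_s * sampling_hz))
        envelope[i0:i1] = factor
        down = factor + (1 - factor) * 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr))
        envelope[max(0, i0 - nr):i0] = np.minimum(envelope[max(0, i0 - nr):i0], down[-(i0 - max(0, i0 - nr)):])
        up = factor + (1 - factor) * 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        envelope[i1:min(n, i1 + nr)] = np.minimum(envelope[i1:min(n, i1 + nr)], up[:min(n, i1 + nr) - i1])
        desat = None
        if kind == "hypopnea":
            desat = float(rng.uniform(4.5, 7.0))
        elif rng.random() < 0.8:  # most apneas desaturate too
            desat = float(rng.uniform(5.0, 10.0))
        if desat is not None:
            lag = float(rng.uniform(5.0, 12.0))
            center = onset + dur / 2.0 + lag
            width = max(dur / 2.0, 8.0)
            spo2 -= desat * np.exp(-0.5 * ((t - center) / width) ** 2)
        events.append({"kind": kind, "onset": onset, "duration": dur,
                       "desaturation": 0.0 if desat is None else desat})
    events.sort(key=lambda e: e["onset"])
    airflow = amp * envelope * breath
    return airflow, np.clip(spo2, 40.0, 100.0), events


# ---------------------------------------------------------------------------
# cohort assembly

def generate_cohort(spec: CohortSpec):
    """Generate a full cohort: volumes, motion traces, clinical table, truth.

    Deterministic given ``spec.rng_seed``. Returns
    ``(volumes, motion_traces, clinical, truth)`` where volumes is a list of
    :class:`Volume4D` (group 1 subjects first), motion_traces a list of
    (6, T) arrays aligned with volumes, clinical a DataFrame and truth a
    :class:`GroundTruth`.
    """
    labels = np.array([1] * spec.n_group1 + [2] * spec.n_group2)
    volumes, motions = [], []
    for i, group in enumerate(labels):
        subject_seed = [int(spec.rng_seed), 100 + i]
        volumes.append(generate_subject_bold(spec, int(group), subject_seed))
        motions.append(generate_motion_params(spec.n_timepoints, spec.motion_amplitude,
                                              _child_seed(subject_seed, 1)))
    clinical = generate_clinical_table(spec.n_group1, spec.n_group2,
                                       rng_seed=[int(spec.rng_seed), 7])
    sc = spec.seed_coupling
    truth = GroundTruth(
        labels=labels,
        effect_masks=[reg.mask & spec.mask for reg in spec.effect_regions],
        effect_drops=[reg.synchrony_drop for reg in spec.effect_regions],
        seed_mask=None if sc is None else (sc.seed & spec.mask),
        target_mask=None if sc is None else (sc.target & spec.mask),
        coupling_r=None if sc is None else (sc.r_group1, sc.r_group2),
    )
    return volumes, motions, clinical, truth
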
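"""Synthetic multi-modal cohorts with planted brain-behavior signal.

The generator emulates the statistical structure the regression pipeline
assumes of preprocessed data: spatially smooth tissue-density / flow maps
in a common template space, subject-level intracranial-volume (ICV)
scaling, and compact contiguous regions whose mean intensity varies
linearly with a latent cognitive trait.  Raw neuropsychological test
scores are noisy measures of the same trait, so that per-domain composite
averaging is beneficial.

Model, per subject ``i`` with latent trait ``z_i ~ N(0,1)``::

    volume_im = [ base_m + sum_r beta_m * z_i * 1(region_r)
                  + noise_im ] * (icv_i / reference_icv)
    test score s_it = z_i + eps_it,  eps ~ N(0, score_noise_sd**2)

``noise_im`` is a Gaussian random field, optionally smoothed to mimic the
spatial autocorrelation of density/flow maps (set
``noise_smooth_fwhm_mm = 0`` for the unsmoothed field used by analytic
checks).  The multiplicative ICV factor exists to exercise
ICV normalization downstream; all randomness is driven by one seed, and
the same seed reproduces the cohort bitwise.

What this does *not* emulate: real anatomy, registration error, scanner
artifacts, or modality-specific intensity distributions.  Passing tests
on these cohorts demonstrates that the pipeline recovers the kind of
signal it models, not that real data contain such signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from patreg.cognitive_scores import DEFAULT_BATTERIES
from patreg.imaging_io import (
    MODALITIES,
    BrainMask,
    BrainVolume,
    VolumeGrid,
    fwhm_to_sigma_voxels,
    write_labels,
    write_mask,
    write_volume,
)


@dataclass(frozen=True)
class ModalityConfig:
    """Planted-signal parameters for one modality."""

    n_regions: int = 2
    region_radius_vox: float = 3.0
    effect_size: float = 1.0       # intensity units per latent-trait SD
    base_amplitude: float = 10.0   # mean background intensity
    noise_sd: float = 1.0          # voxelwise noise SD before smoothing


@dataclass(frozen=True)
class SyntheticConfig:
    """Desk-scale cohort configuration.

    Defaults: 80 subjects on a 32**3 grid of 2 mm voxels, an ellipsoid
    mask filling 80% of each axis, two planted spherical regions per
    modality of radius 3 voxels, unit effect size against unit-SD noise,
    and test scores with noise SD 0.5 (test-trait correlation
    1/sqrt(1.25) ~ 0.89).
    """

    n_subjects: int = 80
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_mm: float = 2.0
    mask_fraction: float = 0.8
    modalities: dict = field(
        default_factory=lambda: {m: ModalityConfig() for m in MODALITIES}
    )
    noise_smooth_fwhm_mm: float = 8.0
    score_noise_sd: float = 0.5
    icv_range_mm3: tuple[float, float] = (1.3e6, 1.7e6)
    reference_icv_mm3: float = 1.5e6
    batteries: dict = field(default_factory=lambda: dict(DEFAULT_BATTERIES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.score_noise_sd < 0 or self.noise_smooth_fwhm_mm < 0:
            raise ValueError("noise SDs and smoothing fwhm must be >= 0")
        for mod, mc in self.modalities.items():
            if mc.noise_sd < 0:
                raise ValueError(f"{mod}: noise_sd must be >= 0")
            if mc.region_radius_vox < 1:
                raise ValueError(f"{mod}: region radius must be >= 1 voxel")

    def with_null_effects(self) -> "SyntheticConfig":
        mods = {m: replace(mc, effect_size=0.0) for m, mc in self.modalities.items()}
        return replace(self, modalities=mods)


@dataclass
class GroundTruth:
    """Planted structure underlying a synthetic cohort."""

    latent_trait: np.ndarray              # z per subject, N(0,1)
    region_labels: dict[str, np.ndarray]  # modality -> int label volume (0 = background)
    effect_sizes: dict[str, float]        # modality -> beta
    icv: np.ndarray                       # true ICV per subject (mm^3)


@dataclass
class Cohort:
    """Aligned multi-modal cohort: volumes, mask, score table, truth."""

    grid: VolumeGrid
    mask: BrainMask
    volumes: dict[str, list[BrainVolume]]  # modality -> one volume per subject
    scores: pd.DataFrame                   # subject_id, age, sex, icv, test columns
    truth: GroundTruth
    config: SyntheticConfig

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scores["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.scores)


def ellipsoid_mask(grid: VolumeGrid, fraction: float) -> BrainMask:
    """Ellipsoid mask with semi-axes ``fraction/2`` of each grid extent."""
    center = (np.asarray(grid.shape) - 1) / 2.0
    semi = np.asarray(grid.shape) * fraction / 2.0
    idx = np.indices(grid.shape)
    dist = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return BrainMask(grid=grid, data=dist <= 1.0)


def _place_regions(
    rng: np.random.Generator,
    mask: np.ndarray,
    n_regions: int,
    radius: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Plant disjoint spherical regions fully inside the mask.

    Returns an int label volume (0 background, 1..n_regions).  Rejection
    sampling keeps regions non-overlapping and inside the mask.
    """
    shape = mask.shape
    labels = np.zeros(shape, dtype=np.int32)
    idx = np.indices(shape)
    candidates = np.argwhere(mask)
    placed = 0
    for _ in range(max_tries):
        if placed == n_regions:
            break
        c = candidates[rng.integers(len(candidates))]
        dist2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        ball = dist2 <= radius**2
        if not mask[ball].all():
            continue  # exits the mask
        if labels[ball].any():
            continue  # overlaps an earlier region
        placed += 1
        labels[ball] = placed
    if placed < n_regions:
        raise RuntimeError(
            f"could not place {n_regions} disjoint regions of radius {radius} in mask"
        )
    return labels


def _smooth_noise_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sd: float,
    sigma_vox: tuple[float, ...],
) -> np.ndarray:
    """Gaussian field with pointwise SD ``sd`` after optional smoothing.

    Smoothing shrinks the pointwise variance of white noise; the field is
    rescaled so its marginal SD stays ``sd`` regardless of the kernel.
    """
    white = rng.standard_normal(shape)
    if all(s == 0 for s in sigma_vox):
        return sd * white
    sm = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    # variance of smoothed white noise = sum of squared kernel weights
    impulse = np.zeros(tuple(int(8 * s) * 2 + 1 for s in sigma_vox))
    impulse[tuple(s // 2 for s in impulse.shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="constant")
    scale = np.sqrt((kernel**2).sum())
    return sd * sm / scale


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    grid = VolumeGrid.isotropic(cfg.shape, cfg.voxel_mm)
    mask = ellipsoid_mask(grid, cfg.mask_fraction)

    n = cfg.n_subjects
    z = rng.standard_normal(n)
    icv = rng.uniform(*cfg.icv_range_mm3, size=n)
    age = np.clip(rng.normal(70.0, 7.5, size=n), 56.0, 86.0)
    sex = rng.integers(0, 2, size=n)

    sigma_vox = fwhm_to_sigma_voxels(cfg.noise_smooth_fwhm_mm, grid.voxel_size) \
        if cfg.noise_smooth_fwhm_mm > 0 else (0.0, 0.0, 0.0)

    region_labels: dict[str, np.ndarray] = {}
    effect_sizes: dict[str, float] = {}
    bases: dict[str, np.ndarray] = {}
    for mod, mc in cfg.modalities.items():
        region_labels[mod] = _place_regions(
            rng, mask.data, mc.n_regions, mc.region_radius_vox
        )
        effect_sizes[mod] = mc.effect_size
        # fixed smooth background shared by all subjects
        bg = _smooth_noise_field(rng, cfg.shape, 1.0, fwhm_to_sigma_voxels(12.0, grid.voxel_size))
        bases[mod] = mc.base_amplitude * (1.0 + 0.1 * bg)

    volumes: dict[str, list[BrainVolume]] = {m: [] for m in cfg.modalities}
    for i in range(n):
        scale = icv[i] / cfg.reference_icv_mm3
        for mod, mc in cfg.modalities.items():
            signal = mc.effect_size * z[i] * (region_labels[mod] > 0)
            noise = _smooth_noise_field(rng, cfg.shape, mc.noise_sd, sigma_vox)
            data = (bases[mod] + signal + noise) * scale
            data[~mask.data] = 0.0
            volumes[mod].append(BrainVolume(grid=grid, data=data, modality=mod))

    subject_ids = [f"S{i:03d}" for i in range(n)]
    table = {"subject_id": subject_ids, "age": age, "sex": sex, "icv": icv}
    for tests in cfg.batteries.values():
        for t in tests:
            table[t] = z + cfg.score_noise_sd * rng.standard_normal(n)
    scores = pd.DataFrame(table)

    truth = GroundTruth(
        latent_trait=z, region_labels=region_labels,
        effect_sizes=effect_sizes, icv=icv,
    )
    return Cohort(grid=grid, mask=mask, volumes=volumes,
                  scores=scores, truth=truth, config=cfg)


def make_null_cohort(cfg: SyntheticConfig) -> Cohort:
    """Same generative process with every planted effect size set to zero.

    Region labels are still emitted (with beta = 0), so localization
    metrics can be evaluated under the null.
    """
    return generate_cohort(cfg.with_null_effects())


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort directory: per-subject NIfTI volumes, mask, scores, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(cohort.mask, out / "mask.nii.gz")
    for mod, vols in cohort.volumes.items():
        for sid, vol in zip(cohort.subject_ids, vols):
            write_volume(vol, out / f"{sid}_{mod}.nii.gz")
    cohort.scores.to_csv(out / "scores.csv", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for mod, labels in cohort.truth.region_labels.items():
        write_labels(labels, cohort.grid, truth_dir / f"labels_{mod}.nii.gz")
    meta = {
        "latent_trait": cohort.truth.latent_trait.tolist(),
        "effect_sizes": cohort.truth.effect_sizes,
        "icv": cohort.truth.icv.tolist(),
        "subject_ids": cohort.subject_ids,
        "seed": cohort.config.seed,
    }
    (truth_dir / "truth.json").write_text(json.dumps(meta, indent=2))
    return out
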
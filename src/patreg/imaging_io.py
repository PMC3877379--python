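"""NIfTI volume I/O and the preprocessing steps the pipeline owns.

The regression pipeline works on per-subject tissue-density (GM/WM) and
normalized-flow (PET) volumes that have already been segmented and warped
into a common template space.  This module handles reading/writing those
volumes, Gaussian smoothing, intracranial-volume (ICV) normalization and
block-mean downsampling.  Registration, segmentation and skull stripping
are out of scope: grid equality across a cohort is *enforced*, not
established.

All volumes in one cohort share an identical :class:`VolumeGrid`.
Coordinate indexing is 0-based voxel space; world coordinates exist only
through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITIES = ("GM", "WM", "PET")

#: fwhm -> sigma conversion factor, 2*sqrt(2*ln 2)
_FWHM_TO_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


class GridMismatchError(ValueError):
    """A volume's grid differs from the cohort grid (mixed-space cohort)."""


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid of a template-space volume.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    voxel_size
        Voxel edge length in mm along each axis.
    affine
        4x4 voxel-to-world (template-space) transform.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 2.0) -> "VolumeGrid":
        """Axis-aligned grid with isotropic voxels, origin at the corner voxel."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(shape=tuple(shape), voxel_size=(voxel_mm,) * 3, affine=affine)

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class BrainVolume:
    """A scalar volume on a template grid.

    ``data`` holds tissue density for GM/WM or normalized flow for PET;
    values are expected finite inside the analysis mask and non-negative
    for density/flow modalities.
    """

    grid: VolumeGrid
    data: np.ndarray
    modality: str = "GM"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")


@dataclass
class BrainMask:
    """Boolean analysis mask, identical across subjects and modalities."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if not self.data.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SmoothingConfig:
    """Per-modality Gaussian smoothing FWHM in mm.

    Defaults follow common practice for template-space density maps
    (8 mm for GM/WM) and lower-resolution flow images (12 mm for PET).
    """

    fwhm_mm: dict = field(default_factory=lambda: {"GM": 8.0, "WM": 8.0, "PET": 12.0})

    def __post_init__(self) -> None:
        for mod, fwhm in self.fwhm_mm.items():
            if fwhm <= 0:
                raise ValueError(f"fwhm for {mod} must be positive, got {fwhm}")

    def fwhm_for(self, modality: str) -> float:
        if modality not in self.fwhm_mm:
            raise ValueError(f"no fwhm configured for modality {modality!r}")
        return float(self.fwhm_mm[modality])


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size: tuple[float, ...]) -> tuple[float, ...]:
    """Convert a FWHM in mm to per-axis Gaussian sigmas in voxel units."""
    return tuple(fwhm_mm / (v * _FWHM_TO_SIGMA) for v in voxel_size)


# ---------------------------------------------------------------------------
# I/O

def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(shape=tuple(img.shape[:3]), voxel_size=tuple(zooms), affine=img.affine)


def read_volume(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    modality: str = "GM",
) -> BrainVolume:
    """Read a NIfTI-1 volume; optionally enforce the cohort grid.

    Raises
    ------
    FileNotFoundError
        Missing file.
    GridMismatchError
        The file's grid differs from ``expected_grid`` — this signals a
        mixed-space cohort, which the pipeline refuses to analyze.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    if expected_grid is not None and not grid.matches(expected_grid):
        raise GridMismatchError(f"{path}: grid does not match expected cohort grid")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return BrainVolume(grid=grid, data=data, modality=modality)


def read_mask(path: str | Path, expected_grid: VolumeGrid | None = None) -> BrainMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    if expected_grid is not None and not grid.matches(expected_grid):
        raise GridMismatchError(f"{path}: mask grid does not match expected cohort grid")
    return BrainMask(grid=grid, data=np.asarray(img.dataobj) > 0)


def write_volume(volume: BrainVolume, path: str | Path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1; float32 payload by default."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(dtype), volume.grid.affine)
    img.header.set_zooms(volume.grid.voxel_size)
    nib.save(img, str(path))
    return path


def write_mask(mask: BrainMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.voxel_size)
    nib.save(img, str(path))
    return path


def write_labels(labels: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write an integer label/atlas volume as int32 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(labels).astype(np.int32), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Preprocessing

def smooth_volume(volume: BrainVolume, cfg: SmoothingConfig | float) -> BrainVolume:
    """Gaussian-smooth a volume at the FWHM configured for its modality.

    The per-axis sigma is ``fwhm / (voxel_size * sqrt(8 ln 2))``.  Boundary
    handling is reflect-at-edge, which preserves the total of a symmetric
    kernel (interior mass is folded back rather than lost), so the voxel
    sum is conserved.
    """
    fwhm = cfg if isinstance(cfg, (int, float)) else cfg.fwhm_for(volume.modality)
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    sigma = fwhm_to_sigma_voxels(fwhm, volume.grid.voxel_size)
    smoothed = ndimage.gaussian_filter(volume.data.astype(float), sigma=sigma, mode="reflect")
    return replace(volume, data=smoothed)


def icv_normalize(volume: BrainVolume, icv: float, reference_icv: float) -> BrainVolume:
    """Scale a density map by ``reference_icv / icv`` to remove head-size differences."""
    if icv <= 0:
        raise ValueError(f"icv must be positive, got {icv}")
    if reference_icv <= 0:
        raise ValueError(f"reference_icv must be positive, got {reference_icv}")
    return replace(volume, data=volume.data * (reference_icv / icv))


def downsample(volume: BrainVolume, factor: int) -> BrainVolume:
    """Block-mean downsample by an integer factor.

    Each output voxel is the mean of its ``factor**3`` input block; trailing
    partial blocks (when ``factor`` does not divide the shape) are averaged
    over the voxels they contain.  When the factor divides the shape exactly,
    total intensity times voxel volume is conserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(volume, data=volume.data.copy())

    shape = volume.grid.shape
    out_shape = tuple(-(-s // factor) for s in shape)  # ceil division
    idx = np.indices(shape)
    block = (idx[0] // factor, idx[1] // factor, idx[2] // factor)
    flat = np.ravel_multi_index(block, out_shape).ravel()
    n_out = int(np.prod(out_shape))
    sums = np.bincount(flat, weights=volume.data.ravel().astype(float), minlength=n_out)
    counts = np.bincount(flat, minlength=n_out)
    data = (sums / counts).reshape(out_shape)

    # Output voxel centers sit at the centroid of their input block.
    A = volume.grid.affine
    new_affine = A.copy()
    new_affine[:3, :3] = A[:3, :3] * factor
    new_affine[:3, 3] = A[:3, :3] @ (np.full(3, (factor - 1) / 2.0)) + A[:3, 3]
    grid = VolumeGrid(
        shape=out_shape,
        voxel_size=tuple(v * factor for v in volume.grid.voxel_size),
        affine=new_affine,
    )
    return BrainVolume(grid=grid, data=data, modality=volume.modality)
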
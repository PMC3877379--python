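"""Step 1 of the pattern-regression pipeline: regional feature generation.

High-dimensional voxel data are reduced to a modest set of regional
features in four stages:

1. a voxelwise Pearson correlation map between image intensity and the
   composite cognitive score, over training subjects only;
2. watershed clustering of the correlation magnitude ``|r|`` — the relief
   ``-|r|`` is flooded so that peaks of ``|r|`` become basin cores — with
   a spatial-consistency constraint that merges clusters below a minimum
   size into the 26-connected neighbor of closest mean ``|r|``;
3. per-cluster mean intensity per subject (the feature matrix);
4. ranking by correlation power ``|r(feature, score)|`` and truncation to
   the top ``multiplier * (N_c - k_c)`` features.

The relief is unsigned because the regressor exploits regions regardless
of association sign; signed associations are reported separately through
the GLM baseline maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from patreg.imaging_io import (
    BrainMask,
    BrainVolume,
    VolumeGrid,
    fwhm_to_sigma_voxels,
)

#: deterministic modality ordering used for tie-breaks
MODALITY_ORDER = {"GM": 0, "WM": 1, "PET": 2}

#: full 3x3x3 neighborhood = 26-connectivity
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CorrelationVolume:
    """Per-voxel Pearson r between voxel intensity and the composite score."""

    grid: VolumeGrid
    data: np.ndarray  # r in [-1, 1] inside mask, 0 outside


@dataclass
class ClusterAtlas:
    """Labeled partition of the brain mask into regional voxel clusters.

    ``labels``: int volume, 0 = background, 1..K clusters; every mask voxel
    carries a cluster label and each cluster is 26-connected.
    ``table``: per-cluster modality, voxel count and mean |r|.
    """

    grid: VolumeGrid
    labels: np.ndarray
    table: pd.DataFrame  # columns: label, modality, n_voxels, mean_abs_r
    modality: str = "GM"

    @property
    def n_clusters(self) -> int:
        return int(len(self.table))

    def cluster_labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


@dataclass
class FeatureMatrix:
    """Subjects x regional features with per-column provenance.

    ``columns`` holds ``(modality, cluster_label)`` pairs, unique across
    the matrix so pooled multi-modality matrices stay unambiguous.
    """

    values: np.ndarray                      # n_subjects x n_features
    columns: list[tuple[str, int]]
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (subjects x features)")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column provenance length must match feature count")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate (modality, cluster) feature provenance")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            columns=[self.columns[i] for i in idx],
            subject_ids=self.subject_ids,
        )

    def rows(self, subject_indices) -> "FeatureMatrix":
        idx = np.asarray(subject_indices)
        sids = [self.subject_ids[i] for i in idx] if self.subject_ids else None
        return FeatureMatrix(values=self.values[idx], columns=list(self.columns),
                             subject_ids=sids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m}:{lab}" for m, lab in self.columns]
        return pd.DataFrame(self.values, columns=cols, index=self.subject_ids)

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        values = np.hstack([p.values for p in parts])
        columns = [c for p in parts for c in p.columns]
        return FeatureMatrix(values=values, columns=columns,
                             subject_ids=parts[0].subject_ids)


@dataclass(frozen=True)
class RankingConfig:
    """Correlation-power ranking cap: keep the top ``multiplier * (N_c - k_c)``."""

    multiplier: int = 3

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")

    def cap(self, n_subjects: int, k_left_out: int) -> int:
        return self.multiplier * (n_subjects - k_left_out)


# ---------------------------------------------------------------------------

def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X against y; zero-variance columns get 0."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((Xc**2).sum(axis=0))
    num = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def correlation_volume(
    volumes: list[BrainVolume],
    scores: np.ndarray,
    mask: BrainMask,
) -> CorrelationVolume:
    """Voxelwise Pearson correlation map over the given subjects.

    Requires at least 3 subjects and score variance > 0.  Voxels that are
    constant across subjects get r = 0; voxels outside the mask are 0.
    """
    scores = np.asarray(scores, dtype=float)
    if len(volumes) != len(scores):
        raise ValueError(
            f"{len(volumes)} volumes but {len(scores)} scores"
        )
    if len(volumes) < 3:
        raise ValueError("need at least 3 subjects for a correlation map")
    if np.var(scores) == 0:
        raise ValueError("scores have zero variance")
    grid = volumes[0].grid
    for v in volumes:
        if not v.grid.matches(grid) or not v.grid.matches(mask.grid):
            raise ValueError("all volumes and the mask must share one grid")
    m = mask.data
    X = np.stack([v.data[m] for v in volumes])  # n_subjects x n_maskvox
    r = _pearson_rows(X, scores)
    out = np.zeros(grid.shape)
    out[m] = r
    return CorrelationVolume(grid=grid, data=out)


def _plateau_markers(relief: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Marker volume from 3**3-neighborhood local maxima of ``relief``.

    A plateau of equal-valued local maxima collapses to the single voxel
    with the lowest linear index, so marker placement is deterministic.
    """
    work = np.where(mask, relief, -np.inf)
    maxfilt = ndimage.maximum_filter(work, size=3, mode="constant", cval=-np.inf)
    is_max = (work == maxfilt) & mask
    plateau_lbl, n_plateaus = ndimage.label(is_max, structure=CONNECTIVITY_26)
    markers = np.zeros(relief.shape, dtype=np.int32)
    if n_plateaus == 0:
        return markers
    flat = plateau_lbl.ravel()
    # lowest linear index per plateau component
    order = np.flatnonzero(flat)
    first = {}
    for lin in order:
        lab = flat[lin]
        if lab not in first:
            first[lab] = lin
    for k, (lab, lin) in enumerate(sorted(first.items()), start=1):
        markers.ravel()[lin] = k
    return markers


def _merge_small_clusters(
    labels: np.ndarray,
    abs_r: np.ndarray,
    mask: np.ndarray,
    min_voxels: int,
) -> np.ndarray:
    """Merge clusters below ``min_voxels`` into their closest-|r| 26-neighbor.

    Iterates from the smallest cluster up; ties in size or mean |r| break
    toward the lowest label.  A small cluster with no neighboring cluster
    (an isolated mask component) is left as-is.
    """
    labels = labels.copy()
    struct = CONNECTIVITY_26
    while True:
        labs, counts = np.unique(labels[mask], return_counts=True)
        keep = labs > 0
        labs, counts = labs[keep], counts[keep]
        small = labs[counts < min_voxels]
        if len(small) == 0 or len(labs) == 1:
            break
        # smallest first; ties -> lowest label (lexsort is stable)
        order = np.lexsort((small, counts[np.isin(labs, small)]))
        target = small[order[0]]
        region = labels == target
        dilated = ndimage.binary_dilation(region, structure=struct) & mask
        neighbor_labels = np.unique(labels[dilated & ~region])
        neighbor_labels = neighbor_labels[neighbor_labels > 0]
        if len(neighbor_labels) == 0:
            # isolated mask component smaller than the floor: nothing to
            # merge into; park it (negated) so the loop skips it
            labels[region] = -target
            continue
        own_mean = abs_r[region].mean()
        neigh_means = np.array([abs_r[labels == nl].mean() for nl in neighbor_labels])
        best = neighbor_labels[np.lexsort((neighbor_labels, np.abs(neigh_means - own_mean)))[0]]
        labels[region] = best
    labels = np.abs(labels)  # restore any isolated clusters
    return labels


def _relabel_sequential(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K ordered by each cluster's lowest linear index."""
    out = np.zeros_like(labels)
    flat = labels.ravel()
    firsts = {}
    for lin in np.flatnonzero(flat):
        lab = flat[lin]
        if lab not in firsts:
            firsts[lab] = lin
    remap = {lab: k for k, (lab, _) in enumerate(
        sorted(firsts.items(), key=lambda kv: kv[1]), start=1)}
    for lab, new in remap.items():
        out[labels == lab] = new
    return out


def watershed_cluster(
    cv: CorrelationVolume,
    mask: BrainMask,
    min_cluster_voxels: int = 10,
    pre_smooth_fwhm: float = 0.0,
    modality: str = "GM",
) -> ClusterAtlas:
    """Partition the mask into 26-connected clusters of similar |r|.

    ``|r|`` is optionally Gaussian-presmoothed at ``pre_smooth_fwhm`` mm
    (default 0: raw magnitude, which keeps basins at the scale of compact
    effects rather than merging them into their surroundings), local maxima
    of the smoothed magnitude seed a marker-based watershed of the relief
    ``-|r|_smoothed`` restricted to the mask, and clusters below the size
    floor are merged into their closest-|r| neighbor.  The size floor plays
    the role of a spatial-consistency constraint, suppressing noise basins.
    """
    if not mask.data.any():
        raise ValueError("mask is empty")
    if not cv.grid.matches(mask.grid):
        raise ValueError("correlation volume and mask grids differ")
    abs_r = np.abs(cv.data)
    if pre_smooth_fwhm > 0:
        sigma = fwhm_to_sigma_voxels(pre_smooth_fwhm, cv.grid.voxel_size)
        smoothed = ndimage.gaussian_filter(abs_r, sigma=sigma, mode="reflect")
    else:
        smoothed = abs_r

    markers = _plateau_markers(smoothed, mask.data)
    if markers.max() == 0:
        labels = mask.data.astype(np.int32)  # degenerate: one cluster
    else:
        labels = watershed(-smoothed, markers=markers, mask=mask.data,
                           connectivity=CONNECTIVITY_26).astype(np.int32)
    labels = _merge_small_clusters(labels, abs_r, mask.data, min_cluster_voxels)
    labels = _relabel_sequential(labels, mask.data)

    labs = np.unique(labels[mask.data])
    labs = labs[labs > 0]
    table = pd.DataFrame({
        "label": labs,
        "modality": modality,
        "n_voxels": [int((labels == l).sum()) for l in labs],
        "mean_abs_r": [float(abs_r[labels == l].mean()) for l in labs],
    })
    return ClusterAtlas(grid=cv.grid, labels=labels, table=table, modality=modality)


def extract_features(
    atlas: ClusterAtlas,
    volumes: list[BrainVolume],
    subject_ids: list | None = None,
) -> FeatureMatrix:
    """Per-subject mean intensity of every atlas cluster."""
    labs = atlas.cluster_labels()
    if len(labs) == 0:
        raise ValueError("atlas has no clusters")
    for v in volumes:
        if not v.grid.matches(atlas.grid):
            raise ValueError("volume grid does not match atlas grid")
    values = np.empty((len(volumes), len(labs)))
    index = atlas.labels
    for i, v in enumerate(volumes):
        values[i] = ndimage.mean(v.data, labels=index, index=labs)
    return FeatureMatrix(
        values=values,
        columns=[(atlas.modality, int(l)) for l in labs],
        subject_ids=subject_ids,
    )


def rank_and_select(
    fm: FeatureMatrix,
    scores: np.ndarray,
    cfg: RankingConfig,
    k_left_out: int,
    n_subjects: int | None = None,
    f_max: int | None = None,
) -> list[int]:
    """Order features by |Pearson r| with the score and truncate to the cap.

    The cap is ``multiplier * (N_c - k_c)``; ``n_subjects`` defaults to the
    number of rows in ``fm`` (the training portion).  An optional hard
    ceiling ``f_max`` bounds the pool for desk-scale runs.  Ties in |r|
    break by modality order GM < WM < PET, then by cluster label, so the
    ranking is deterministic.

    Returns column indices into ``fm`` in rank order.
    """
    scores = np.asarray(scores, dtype=float)
    if np.var(scores) == 0:
        raise ValueError("scores have zero variance")
    if fm.values.shape[0] != len(scores):
        raise ValueError("feature rows must match scored subjects")
    n_c = n_subjects if n_subjects is not None else fm.values.shape[0] + k_left_out
    cap = cfg.cap(n_c, k_left_out)
    if f_max is not None:
        cap = min(cap, f_max)

    r = _pearson_rows(fm.values, scores)
    abs_r = np.abs(r)
    mod_order = np.array([MODALITY_ORDER[m] for m, _ in fm.columns])
    clus = np.array([lab for _, lab in fm.columns])
    # descending |r|; ties -> GM before WM before PET, then lower label
    order = np.lexsort((clus, mod_order, -abs_r))
    return [int(i) for i in order[: min(cap, fm.n_features)]]
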
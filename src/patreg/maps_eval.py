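"""Contribution maps, model evaluation and the permutation comparison.

The fitted kernel regressor is interpreted back in image space through a
discriminative-direction analysis: for each subject, the minimal change
of the (standardized) feature vector that moves the predicted score
toward the actual score is the normalized gradient of the regressor,
signed by the prediction error.  The per-feature magnitudes of this
direction, averaged over subjects, quantify how much each regional
feature carries the prediction.  Painting those values onto each
cluster's voxels gives a spatial difference map per CV split; averaging
over splits and min-max normalizing jointly across modalities yields the
final contribution map on [0, 1], from which a categorical
modality-maximum map is derived.

Model accuracy is summarized by MSE (mean +/- SD and a percentile 95% CI
over splits) and the Pearson correlation between averaged left-out
predictions and actual scores.  Two models are compared by a paired
permutation test that randomly exchanges the two models' predictions per
subject; a voxelwise GLM correlation map serves as the conventional
mass-univariate baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from patreg.feature_generation import ClusterAtlas, FeatureMatrix
from patreg.imaging_io import BrainMask, BrainVolume, VolumeGrid
from patreg.rvr import KernelConfig, RVRModel, kernel_matrix, predict

MODALITY_CODES = {"GM": 1, "WM": 2, "PET": 3}


@dataclass
class ContributionMap:
    """Per-modality voxel contributions normalized jointly to [0, 1].

    The overlay threshold is a visualization default only; sub-threshold
    regions participate fully in the regression.
    """

    grid: VolumeGrid
    volumes: dict[str, np.ndarray]
    overlay_threshold: float = 0.2
    cluster_contributions: dict = field(default_factory=dict, repr=False)


@dataclass
class ModalityMaxMap:
    """Categorical volume: 0 none, 1 GM, 2 WM, 3 PET."""

    grid: VolumeGrid
    data: np.ndarray


@dataclass
class EvalResult:
    """Accuracy summary for one model run."""

    mse_mean: float
    mse_sd: float
    mse_ci: tuple[float, float]
    pearson_r: float
    p_value: float
    n_subjects: int


@dataclass(frozen=True)
class PermutationConfig:
    n_iterations: int = 10_000
    seed: int = 0
    statistic: str = "delta_r"   # or "delta_mse"
    scheme: str = "swap"         # paired label exchange; or "permute_actual"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.statistic not in ("delta_r", "delta_mse"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.scheme not in ("swap", "permute_actual"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# Discriminative direction

def _gradients(model: RVRModel, X_std: np.ndarray) -> np.ndarray:
    """Analytic gradient of the regressor at standardized points (rows)."""
    if model.intercept_only or model.n_relevance_vectors == 0:
        return np.zeros_like(X_std)
    RV = model.X_train[model.relevance_idx]
    if model.kernel.kind == "rbf":
        g = model.gamma
        diff = X_std[:, None, :] - RV[None, :, :]          # n x m x d
        K = np.exp(-g * (diff**2).sum(axis=2))             # n x m
        return -2.0 * g * np.einsum("nm,nmd->nd", K * model.mu[None, :], diff)
    # linear kernel: f(x) = (sum_i mu_i x_i) . x + b
    w = model.mu @ RV
    return np.tile(w, (X_std.shape[0], 1))


def discriminative_direction(
    model: RVRModel,
    features: FeatureMatrix,
    actual: np.ndarray,
) -> np.ndarray:
    """Per-feature contribution magnitudes from discriminative directions.

    For each subject the direction is ``sign(actual - predicted) *
    grad f / ||grad f||`` — the unit feature-space move that increases
    agreement with the actual score while changing the input least.  The
    contribution of a feature is the mean absolute component of that
    direction over subjects; all-zero gradients (intercept-only models)
    yield all-zero contributions.
    """
    actual = np.asarray(actual, float).ravel()
    X = features.values
    if X.shape[0] != len(actual):
        raise ValueError("feature rows must match actual scores")
    pred = predict(model, X)
    Xs = (X - model.feature_mean) / model.feature_sd
    grads = _gradients(model, Xs)
    norms = np.linalg.norm(grads, axis=1)
    ok = norms > 0
    if not ok.any():
        return np.zeros(X.shape[1])
    dirs = np.zeros_like(grads)
    sign = np.sign(actual - pred)
    sign[sign == 0] = 1.0
    dirs[ok] = sign[ok, None] * grads[ok] / norms[ok, None]
    return np.abs(dirs[ok]).mean(axis=0)


# ---------------------------------------------------------------------------
# Spatial maps

def paint_clusters(
    atlas: ClusterAtlas,
    values_by_label: dict[int, float],
) -> np.ndarray:
    """Paint per-cluster scalar values onto the atlas voxels."""
    out = np.zeros(atlas.grid.shape)
    for lab, val in values_by_label.items():
        out[atlas.labels == lab] = val
    return out


def contribution_volume(
    split_maps: list[dict[str, np.ndarray]],
    grid: VolumeGrid,
    modalities: tuple[str, ...],
    overlay_threshold: float = 0.2,
) -> ContributionMap:
    """Average per-split spatial difference maps and normalize to [0, 1].

    ``split_maps`` holds one dict per CV split mapping modality to that
    split's painted contribution volume (zeros for modalities a split did
    not touch).  Normalization is min-max *jointly* across the modality
    set so the maps stay comparable across modalities; an all-zero result
    is returned unscaled.
    """
    if not split_maps:
        raise ValueError("no split maps to average")
    avg = {m: np.zeros(grid.shape) for m in modalities}
    for sm in split_maps:
        for m in modalities:
            vol = sm.get(m)
            if vol is not None:
                if vol.shape != grid.shape:
                    raise ValueError("split map shape does not match grid")
                avg[m] += vol
    for m in modalities:
        avg[m] /= len(split_maps)

    lo = min(float(avg[m].min()) for m in modalities)
    hi = max(float(avg[m].max()) for m in modalities)
    if hi > lo:
        norm = {m: (avg[m] - lo) / (hi - lo) for m in modalities}
        # keep exact zeros at zero background: shift only if negative values exist
        if lo >= 0:
            norm = {m: avg[m] / hi for m in modalities}
    else:
        norm = avg  # degenerate all-equal case, typically all zeros
    return ContributionMap(grid=grid, volumes=norm, overlay_threshold=overlay_threshold)


def modality_max_map(cm: ContributionMap) -> ModalityMaxMap:
    """Argmax modality per voxel; ties favor GM over WM over PET; 0 if all zero."""
    mods = [m for m in ("GM", "WM", "PET") if m in cm.volumes]
    if len(mods) < 2:
        raise ValueError("modality-maximum map needs at least 2 modalities")
    stack = np.stack([cm.volumes[m] for m in mods])
    best = np.argmax(stack, axis=0)  # ties -> first (GM-priority given ordering)
    codes = np.array([MODALITY_CODES[m] for m in mods])
    out = codes[best]
    out[np.all(stack <= 0, axis=0)] = 0
    return ModalityMaxMap(grid=cm.grid, data=out.astype(np.int8))


# ---------------------------------------------------------------------------
# Evaluation

def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t(n-2) reference."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evaluate(
    predictions: np.ndarray,
    actual: np.ndarray,
    split_mses: np.ndarray,
) -> EvalResult:
    """Summarize a model run: correlation of averaged predictions, MSE over splits."""
    predictions = np.asarray(predictions, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predictions.shape != actual.shape:
        raise ValueError("prediction/actual length mismatch")
    r, p = pearson_with_p(predictions, actual)
    split_mses = np.asarray(split_mses, float).ravel()
    lo, hi = np.percentile(split_mses, [2.5, 97.5]) if len(split_mses) > 1 else (
        split_mses[0], split_mses[0])
    return EvalResult(
        mse_mean=float(split_mses.mean()),
        mse_sd=float(split_mses.std(ddof=1)) if len(split_mses) > 1 else 0.0,
        mse_ci=(float(lo), float(hi)),
        pearson_r=r, p_value=p, n_subjects=len(actual),
    )


def _stat(pred: np.ndarray, actual: np.ndarray, statistic: str) -> np.ndarray:
    """Model-quality statistic; works on a stack of prediction vectors."""
    pred = np.atleast_2d(pred)
    if statistic == "delta_mse":
        return ((pred - actual) ** 2).mean(axis=1)
    ac = actual - actual.mean()
    pc = pred - pred.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = pc @ ac / denom
    r[~np.isfinite(r)] = 0.0
    return r


def permutation_compare(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    actual: np.ndarray,
    cfg: PermutationConfig = PermutationConfig(),
) -> tuple[float, float]:
    """Paired permutation test of two models' prediction quality.

    The observed statistic is ``T = stat(A) - stat(B)`` (prediction-score
    correlation by default, MSE optionally).  Under the default null the
    model labels are exchangeable per subject: each iteration swaps A and
    B predictions independently with probability 1/2 and recomputes T.
    The alternative scheme permutes the actual scores instead.  Returns
    ``(T_observed, p)`` with the add-one rule
    ``p = (#{|T_perm| >= |T_obs|} + 1) / (n_iterations + 1)``.
    """
    a = np.asarray(pred_a, float).ravel()
    b = np.asarray(pred_b, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if not (len(a) == len(b) == len(actual)):
        raise ValueError("prediction/actual length mismatch")
    rng = np.random.default_rng(cfg.seed)
    t_obs = float(_stat(a, actual, cfg.statistic)[0] - _stat(b, actual, cfg.statistic)[0])
    n = len(a)
    if cfg.scheme == "swap":
        flips = rng.random((cfg.n_iterations, n)) < 0.5
        pa = np.where(flips, b, a)
        pb = np.where(flips, a, b)
        t_perm = _stat(pa, actual, cfg.statistic) - _stat(pb, actual, cfg.statistic)
    else:
        t_perm = np.empty(cfg.n_iterations)
        for i in range(cfg.n_iterations):
            perm = rng.permutation(n)
            t_perm[i] = (_stat(a, actual[perm], cfg.statistic)[0]
                         - _stat(b, actual[perm], cfg.statistic)[0])
    p = (np.count_nonzero(np.abs(t_perm) >= abs(t_obs)) + 1) / (cfg.n_iterations + 1)
    return t_obs, float(p)


# ---------------------------------------------------------------------------
# GLM baseline

def glm_map(
    volumes: list[BrainVolume],
    scores: np.ndarray,
    mask: BrainMask,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise (partial) Pearson correlation and t maps against the score.

    With covariates, both the voxel values and the score are residualized
    on the covariate design (with intercept) before correlating; the sign
    of the association is retained, unlike the unsigned contribution maps.
    Returns ``(r_volume, t_volume)``.
    """
    scores = np.asarray(scores, float).ravel()
    n = len(volumes)
    if n != len(scores):
        raise ValueError("volumes/scores length mismatch")
    if n < 4:
        raise ValueError("need at least 4 subjects for a GLM map")
    grid = volumes[0].grid
    m = mask.data
    X = np.stack([v.data[m] for v in volumes])  # n x V
    y = scores.copy()
    n_cov = 0
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariate design")
        n_cov = C.shape[1]
        Q, _ = np.linalg.qr(design)
        X = X - Q @ (Q.T @ X)
        y = y - Q @ (Q.T @ y)
        if np.allclose(y, 0):
            raise ValueError("score is collinear with covariates")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - n_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t[~np.isfinite(t)] = 0.0
    r_vol = np.zeros(grid.shape)
    t_vol = np.zeros(grid.shape)
    r_vol[m] = r
    t_vol[m] = t
    return r_vol, t_vol
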
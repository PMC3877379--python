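"""Step 3 orchestration: leave-k-out cross-validation over the full pipeline.

For one cognitive domain and one modality set, each CV split runs the
whole chain on its training subjects only — correlation mapping,
watershed clustering, feature extraction, correlation-power ranking,
RVR-RFE scored on a tuning subset of the training subjects — then
records the left-out predictions and the split's spatial difference
map.  Averaging
predictions over all splits in which a subject was left out, and
averaging the difference maps voxelwise, gives the final per-subject
predicted scores and the contribution map.

Enumerating *all* leave-k-out subsets is combinatorially infeasible
(C(80, 8) is of order 1e10), so the scheduler draws R balanced random
splits: each subject's validation count is as equal as possible, and in
particular every subject is left out at least floor(R*k/N) times.  R is
the central free parameter of the scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from patreg.cognitive_scores import CompositeScores, TestBattery, composite_score
from patreg.feature_generation import (
    ClusterAtlas,
    FeatureMatrix,
    RankingConfig,
    correlation_volume,
    extract_features,
    rank_and_select,
    watershed_cluster,
)
from patreg.imaging_io import BrainMask, BrainVolume, VolumeGrid, icv_normalize
from patreg.maps_eval import (
    ContributionMap,
    contribution_volume,
    discriminative_direction,
    paint_clusters,
)
from patreg.rfe import rvr_rfe
from patreg.rvr import KernelConfig, fit_rvr, mse, predict
from patreg.synthetic_data import Cohort


@dataclass(frozen=True)
class CVConfig:
    """Leave-k-out configuration.

    ``k_fraction`` of the domain sample is left out per split
    (k_c = round(k_fraction * N_c), at least 1); ``n_splits`` balanced
    random splits are drawn.
    """

    k_fraction: float = 0.1
    n_splits: int = 100
    seed: int = 0
    modalities: tuple[str, ...] = ("GM", "WM", "PET")
    ranking: RankingConfig = field(default_factory=RankingConfig)
    f_max: int | None = 60
    min_cluster_voxels: int = 10
    # 2 mm keeps watershed clusters close to the scale of compact signal
    # regions; heavier marker smoothing merges basins into clusters several
    # times larger than the regions they localize
    pre_smooth_fwhm: float = 0.0
    kernel: KernelConfig = field(default_factory=KernelConfig)
    # iteration cap for the many inner RVR fits of the RFE search; held-out
    # accuracy is insensitive beyond a few dozen updates while full
    # convergence of the diverging precisions costs ~4x more
    rvr_max_iter: int = 40

    def k_c(self, n_subjects: int) -> int:
        k = int(round(self.k_fraction * n_subjects))
        k = max(k, 1)
        if k >= n_subjects:
            raise ValueError(f"k_c={k} must be < N_c={n_subjects}")
        return k


@dataclass
class SplitRecord:
    """Everything retained from one leave-k-out split."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    selected: list[tuple[str, int]]
    val_predictions: np.ndarray
    val_mse: float
    n_rfe_fits: int


@dataclass
class CVResult:
    """Aggregated output of a domain run."""

    domain: str
    modalities: tuple[str, ...]
    subject_ids: list
    actual: np.ndarray
    averaged_predictions: np.ndarray
    coverage: np.ndarray                   # times each subject was left out
    split_records: list[SplitRecord]
    contribution_map: ContributionMap | None

    @property
    def split_mses(self) -> np.ndarray:
        return np.array([s.val_mse for s in self.split_records])


def make_splits(
    n_subjects: int,
    cfg: CVConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw R balanced random leave-k-out splits.

    A greedy quota scheduler assigns each subject a validation quota of
    floor or ceil(R*k/N) and fills each split with the k subjects of
    largest remaining quota (random tie-break), so validation sets are
    disjoint within a split and coverage is maximally even.  Deterministic
    under the config seed.
    """
    k = cfg.k_c(n_subjects)
    R = cfg.n_splits
    if R < 1:
        raise ValueError("need at least one split")
    rng = np.random.default_rng(cfg.seed)
    total = R * k
    if total < n_subjects:
        raise ValueError(
            f"n_splits={R} with k_c={k} cannot leave every one of "
            f"{n_subjects} subjects out at least once; need n_splits >= "
            f"{-(-n_subjects // k)}"
        )
    base, extra = divmod(total, n_subjects)
    quota = np.full(n_subjects, base, dtype=int)
    if extra:
        quota[rng.choice(n_subjects, size=extra, replace=False)] += 1
    splits = []
    all_idx = np.arange(n_subjects)
    for _ in range(R):
        jitter = rng.random(n_subjects)
        order = np.lexsort((jitter, -quota))
        val = np.sort(order[:k])
        quota[val] -= 1
        train = np.setdiff1d(all_idx, val)
        splits.append((train, val))
    return splits


def _composites_for(cohort: Cohort, domain: str) -> CompositeScores:
    battery = TestBattery(domain, cohort.config.batteries[domain]) \
        if domain in cohort.config.batteries else TestBattery.default(domain)
    return composite_score(cohort.scores, battery)


def preprocess_volumes(cohort: Cohort) -> dict[str, list[BrainVolume]]:
    """ICV-normalize every subject's volumes against the cohort reference."""
    ref = cohort.config.reference_icv_mm3
    icv = cohort.scores.set_index("subject_id")["icv"]
    out: dict[str, list[BrainVolume]] = {}
    for mod, vols in cohort.volumes.items():
        out[mod] = [
            icv_normalize(v, float(icv[sid]), ref)
            for v, sid in zip(vols, cohort.subject_ids)
        ]
    return out


def run_split(
    volumes: dict[str, list[BrainVolume]],
    mask: BrainMask,
    scores: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: CVConfig,
    n_subjects: int,
    tuning_rng: np.random.Generator,
    collect_map: bool = True,
) -> tuple[SplitRecord, dict[str, np.ndarray]]:
    """Run steps 1-2 on one split; returns the record and its difference map.

    Every stage — including the RFE search — sees only the split's
    training subjects.  The RFE's selection criterion needs held-out MSE,
    so a tuning subset of the *training* subjects (same fraction as the
    outer left-out set) is carved off for it; scoring the search on the
    outer validation subjects would tune the reported predictions toward
    their own targets and inflate accuracy even on signal-free data.  The
    final model refits the selected features on the full training set.
    """
    y_tr = scores[train_idx]
    y_va = scores[val_idx]
    k = len(val_idx)

    parts_tr, parts_va, atlases = [], [], {}
    for mod in cfg.modalities:
        train_vols = [volumes[mod][i] for i in train_idx]
        cv = correlation_volume(train_vols, y_tr, mask)
        atlas = watershed_cluster(cv, mask, cfg.min_cluster_voxels,
                                  cfg.pre_smooth_fwhm, modality=mod)
        atlases[mod] = atlas
        parts_tr.append(extract_features(atlas, train_vols))
        parts_va.append(extract_features(atlas, [volumes[mod][i] for i in val_idx]))
    fm_tr = FeatureMatrix.concat(parts_tr)
    fm_va = FeatureMatrix.concat(parts_va)

    ranked = rank_and_select(fm_tr, y_tr, cfg.ranking, k_left_out=k,
                             n_subjects=n_subjects, f_max=cfg.f_max)
    fm_tr_r, fm_va_r = fm_tr.subset(ranked), fm_va.subset(ranked)

    n_tr = len(train_idx)
    k_tune = min(max(int(round(cfg.k_fraction * n_tr)), 1), n_tr - 3)
    tune_rows = np.sort(tuning_rng.choice(n_tr, size=k_tune, replace=False))
    fit_rows = np.setdiff1d(np.arange(n_tr), tune_rows)

    state = rvr_rfe(fm_tr_r.rows(fit_rows), y_tr[fit_rows],
                    fm_tr_r.rows(tune_rows), y_tr[tune_rows],
                    rvr_cfg=cfg.kernel, max_iter=cfg.rvr_max_iter)
    sel = state.selected
    model = fit_rvr(fm_tr_r.values[:, sel], y_tr, cfg=cfg.kernel,
                    gamma=state.gamma, max_iter=cfg.rvr_max_iter)
    val_pred = predict(model, fm_va_r.values[:, sel])

    record = SplitRecord(
        train_idx=train_idx, val_idx=val_idx,
        selected=[fm_tr_r.columns[i] for i in sel],
        val_predictions=val_pred,
        val_mse=mse(y_va, val_pred),
        n_rfe_fits=state.n_fits,
    )

    split_map: dict[str, np.ndarray] = {}
    if collect_map:
        contrib = discriminative_direction(model, fm_tr_r.subset(sel), y_tr)
        by_mod: dict[str, dict[int, float]] = {m: {} for m in cfg.modalities}
        for (mod, lab), c in zip(record.selected, contrib):
            by_mod[mod][lab] = float(c)
        for mod in cfg.modalities:
            split_map[mod] = paint_clusters(atlases[mod], by_mod[mod])
    return record, split_map


def run_domain(
    cohort: Cohort,
    domain: str,
    cfg: CVConfig,
    collect_maps: bool = True,
) -> CVResult:
    """Full leave-k-out run for one cognitive domain and modality set."""
    comp = _composites_for(cohort, domain)
    # align imaging subjects with scored subjects
    have_imaging = cohort.subject_ids
    scored = [s for s in comp.subject_ids if s in set(have_imaging)]
    pos = {sid: i for i, sid in enumerate(have_imaging)}
    sel_pos = [pos[s] for s in scored]
    scores = comp.scores.loc[scored].to_numpy(dtype=float)
    n = len(scored)

    volumes = preprocess_volumes(cohort)
    volumes = {m: [volumes[m][i] for i in sel_pos] for m in cfg.modalities}

    splits = make_splits(n, cfg)
    pred_sum = np.zeros(n)
    coverage = np.zeros(n, dtype=int)
    records: list[SplitRecord] = []
    split_maps: list[dict[str, np.ndarray]] = []
    for s_i, (train, val) in enumerate(splits):
        tuning_rng = np.random.default_rng([cfg.seed, s_i])
        try:
            record, smap = run_split(volumes, cohort.mask, scores, train, val,
                                     cfg, n_subjects=n, tuning_rng=tuning_rng,
                                     collect_map=collect_maps)
        except Exception as exc:  # annotate failures with split + stage context
            raise RuntimeError(f"split {s_i} (domain {domain}) failed") from exc
        records.append(record)
        if collect_maps:
            split_maps.append(smap)
        pred_sum[val] += record.val_predictions
        coverage[val] += 1

    if (coverage == 0).any():
        raise RuntimeError("split scheduler left some subjects uncovered")
    averaged = pred_sum / coverage

    cmap = None
    if collect_maps:
        cmap = contribution_volume(split_maps, cohort.grid, cfg.modalities)
    return CVResult(
        domain=domain, modalities=cfg.modalities, subject_ids=scored,
        actual=scores, averaged_predictions=averaged, coverage=coverage,
        split_records=records, contribution_map=cmap,
    )


def average_predictions(result: CVResult) -> pd.DataFrame:
    """Per-subject averaged left-out predictions with coverage counts."""
    if (result.coverage == 0).any():
        raise ValueError("some subjects were never left out")
    return pd.DataFrame({
        "subject_id": result.subject_ids,
        "actual": result.actual,
        "predicted": result.averaged_predictions,
        "coverage": result.coverage,
    })


def result_summary(result: CVResult) -> dict:
    """JSON-serializable summary of a domain run."""
    from patreg.maps_eval import evaluate

    ev = evaluate(result.averaged_predictions, result.actual, result.split_mses)
    return {
        "domain": result.domain,
        "modalities": list(result.modalities),
        "n_subjects": len(result.subject_ids),
        "n_splits": len(result.split_records),
        "pearson_r": ev.pearson_r,
        "p_value": ev.p_value,
        "mse_mean": ev.mse_mean,
        "mse_sd": ev.mse_sd,
        "mse_ci": list(ev.mse_ci),
        "mean_selected_features": float(np.mean(
            [len(s.selected) for s in result.split_records])),
    }


def save_result(result: CVResult, out_dir: str | Path) -> Path:
    """Write predictions.csv, cvresult.json and contribution maps."""
    from patreg.imaging_io import write_volume, BrainVolume as BV

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    average_predictions(result).to_csv(out / "predictions.csv", index=False)
    (out / "cvresult.json").write_text(json.dumps(result_summary(result), indent=2))
    if result.contribution_map is not None:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for mod, vol in result.contribution_map.volumes.items():
            bv = BV(grid=result.contribution_map.grid, data=vol,
                    modality=mod if mod in ("GM", "WM", "PET") else "GM")
            write_volume(bv, maps_dir / f"contribution_{mod}.nii.gz")
    return out
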
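"""RVR-RFE: backward feature elimination then forward re-addition.

Feature-subset search driven by mean squared error (MSE) on a held-out
validation sample.  In the pipeline this sample is a tuning subset
carved from the split's training subjects, never the split's reported
left-out subjects — scoring the search on the latter would tune their
predictions toward their own targets.  Backward
elimination removes, at each iteration, the feature whose removal yields
the smallest candidate MSE — provided that MSE beats the incumbent — and
stops when no removal reduces MSE or one feature remains.  A forward pass
then re-considers eliminated features one at a time with the same
criterion, recovering features whose initial rank was low but which
perform well jointly with the kept ones.

Within one split, kernel hyperparameters (the RBF width from the full
initial feature set's training standardization) are fixed so that MSE
comparisons between candidate subsets are stable; re-deriving the median
heuristic per candidate would move the goalposts between candidates.

Ties in MSE (within 1e-12) break by the correlation ranking: prefer
removing the lower-ranked feature and re-adding the higher-ranked one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from patreg.feature_generation import FeatureMatrix
from patreg.rvr import KernelConfig, RVRModel, fit_rvr, median_heuristic_gamma, mse, predict

_TIE_TOL = 1e-12
_ALPHA_INF = 1e12


class _BatchScorer:
    """Validation-MSE scorer that runs many candidate feature sets at once.

    Candidate subsets of one split share the training/validation subjects
    and the (fixed) kernel width, so their design matrices differ only in
    which per-feature squared distances enter the RBF exponent.  This
    scorer precomputes those per-feature distance blocks and iterates the
    evidence fixed-point updates for all candidates simultaneously as
    stacked linear algebra.  Pruned basis functions are emulated by
    clamping their precision at a huge value rather than removing the
    column, which agrees with ``fit_rvr`` to rounding error (covered by a
    dedicated equivalence test).  RBF kernel with bias only; other
    configurations take the sequential path.
    """

    def __init__(self, X_tr, y_tr, X_va, y_va, gamma, tol=1e-3,
                 max_iter=300, alpha_prune=1e9):
        self.y_tr = np.asarray(y_tr, float)
        self.y_va = np.asarray(y_va, float)
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_prune = alpha_prune
        mean = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs_tr = (X_tr - mean) / sd
        Xs_va = (X_va - mean) / sd
        # per-feature squared-distance blocks
        dt = Xs_tr.T[:, :, None] - Xs_tr.T[:, None, :]
        self.Dtt = dt**2                                     # F x n_tr x n_tr
        dv = Xs_va.T[:, :, None] - Xs_tr.T[:, None, :]
        self.Dvt = dv**2                                     # F x n_va x n_tr

    def val_mse(self, candidates: list[list[int]]) -> np.ndarray:
        """Validation MSE of an RVR fit for each candidate column set."""
        n_c = len(candidates)
        n = len(self.y_tr)
        M = n + 1  # bias column
        y = self.y_tr
        Phi = np.empty((n_c, n, M))
        Phi_va = np.empty((n_c, len(self.y_va), M))
        for i, cols in enumerate(candidates):
            Phi[i, :, :n] = np.exp(-self.gamma * self.Dtt[cols].sum(axis=0))
            Phi_va[i, :, :n] = np.exp(-self.gamma * self.Dvt[cols].sum(axis=0))
        Phi[:, :, n] = 1.0
        Phi_va[:, :, n] = 1.0

        PtP = np.einsum("cnm,cnk->cmk", Phi, Phi)
        Pty = np.einsum("cnm,n->cm", Phi, y)
        alpha = np.full((n_c, M), 1.0 / n**2)
        var_y = float(np.var(y))
        sigma2 = np.full(n_c, 0.1 * var_y if var_y > 0 else 1e-6)
        sigma2_floor = max(1e-12, 1e-9 * var_y)
        pruned = np.zeros((n_c, M), dtype=bool)
        done = np.zeros(n_c, dtype=bool)
        eye = np.eye(M)
        mu = np.zeros((n_c, M))

        for it in range(self.max_iter):
            # periodically drop pruned columns (padded to a common width) so
            # late iterations solve much smaller systems
            if it > 0 and it % 10 == 0:
                live = ~pruned
                width = max(int(live.sum(axis=1).max()), 1)
                if width < 0.8 * M:
                    idx = np.zeros((n_c, width), dtype=int)
                    new_pruned = np.ones((n_c, width), dtype=bool)
                    for c in range(n_c):
                        cols = np.flatnonzero(live[c])
                        idx[c, :len(cols)] = cols
                        new_pruned[c, :len(cols)] = False
                    Phi = np.take_along_axis(Phi, idx[:, None, :], axis=2)
                    Phi_va = np.take_along_axis(Phi_va, idx[:, None, :], axis=2)
                    Phi = np.where(new_pruned[:, None, :], 0.0, Phi)
                    Phi_va = np.where(new_pruned[:, None, :], 0.0, Phi_va)
                    alpha = np.where(new_pruned, _ALPHA_INF,
                                     np.take_along_axis(alpha, idx, axis=1))
                    pruned = new_pruned
                    M = width
                    eye = np.eye(M)
                    PtP = np.einsum("cnm,cnk->cmk", Phi, Phi)
                    Pty = np.einsum("cnm,n->cm", Phi, y)
            G = PtP / sigma2[:, None, None] + \
                (alpha[:, :, None] + 1e-10) * eye[None, :, :]
            S = np.linalg.solve(G, np.broadcast_to(eye, (n_c, M, M)).copy())
            mu = np.einsum("cmk,ck->cm", S, Pty) / sigma2[:, None]
            Sdiag = np.einsum("cmm->cm", S)
            g = np.clip(1.0 - alpha * Sdiag, 1e-12, None)
            mu2 = mu**2
            with np.errstate(divide="ignore"):
                new_alpha = np.where(mu2 > 0, g / np.maximum(mu2, 1e-300), np.inf)
            newly = new_alpha > self.alpha_prune
            new_alpha = np.where(newly | pruned, _ALPHA_INF, new_alpha)
            resid = y[None, :] - np.einsum("cnm,cm->cn", Phi, mu)
            denom = np.maximum(n - g.sum(axis=1), 1e-6)
            new_sigma2 = np.maximum((resid**2).sum(axis=1) / denom, sigma2_floor)

            live = ~(newly | pruned)
            with np.errstate(divide="ignore", invalid="ignore"):
                delta = np.abs(np.log(new_alpha) - np.log(alpha))
            delta = np.where(live, delta, 0.0)
            done |= delta.max(axis=1) < self.tol
            pruned |= newly
            alpha = new_alpha
            sigma2 = new_sigma2
            if done.all():
                break

        mu = np.where(pruned, 0.0, mu)
        pred = np.einsum("cvm,cm->cv", Phi_va, mu)
        all_pruned = pruned.all(axis=1)
        if all_pruned.any():
            pred[all_pruned] = y.mean()
        return ((pred - self.y_va[None, :]) ** 2).mean(axis=1)


def _make_scorer(X_tr, y_tr, X_va, y_va, rvr_cfg, gamma, max_iter):
    """Batch scorer when the configuration supports it, else None."""
    if rvr_cfg.kind != "rbf" or not rvr_cfg.include_bias or gamma is None:
        return None
    return _BatchScorer(X_tr, y_tr, X_va, y_va, gamma, max_iter=max_iter)


def _pick_min(mses: np.ndarray) -> tuple[int, float]:
    """First index attaining the minimum within the tie tolerance."""
    best = float(np.min(mses))
    idx = int(np.flatnonzero(mses <= best + _TIE_TOL)[0])
    return idx, float(mses[idx])


@dataclass
class RFEState:
    """State of a feature-subset search over one CV split.

    ``selected`` holds column indices into the initial ranked feature
    matrix, in rank order.  ``history`` records every accepted step as
    ``(action, feature_index, validation_mse)``; accepted-step MSEs are
    strictly decreasing by construction.
    """

    selected: list[int]
    best_mse: float
    history: list[tuple[str, int, float]] = field(default_factory=list)
    n_fits: int = 0
    model: RVRModel | None = None
    gamma: float | None = None


def _fit_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cols: list[int],
    rvr_cfg: KernelConfig,
    gamma: float | None,
    max_iter: int,
) -> tuple[float, RVRModel]:
    model = fit_rvr(X_train[:, cols], y_train, cfg=rvr_cfg, gamma=gamma, max_iter=max_iter)
    val_mse = mse(y_val, predict(model, X_val[:, cols]))
    return val_mse, model


def backward_eliminate(
    features: FeatureMatrix,
    y_train: np.ndarray,
    val_features: FeatureMatrix,
    y_val: np.ndarray,
    rvr_cfg: KernelConfig = KernelConfig(),
    max_iter: int = 300,
    use_batch: bool = True,
) -> RFEState:
    """Backward elimination over a ranked feature matrix.

    ``features``/``val_features`` rows are training/validation subjects of
    the split; columns are assumed already in rank order (best first).
    """
    if features.n_features < 1:
        raise ValueError("no features to select from")
    X_tr, X_va = features.values, val_features.values
    y_train = np.asarray(y_train, float)
    y_val = np.asarray(y_val, float)

    # fix the kernel width from the full initial training set
    gamma = None
    if rvr_cfg.kind == "rbf" and rvr_cfg.gamma is None:
        mean = X_tr.mean(axis=0)
        sd = np.where(X_tr.std(axis=0) > 0, X_tr.std(axis=0), 1.0)
        gamma = median_heuristic_gamma((X_tr - mean) / sd)

    scorer = use_batch and _make_scorer(X_tr, y_train, X_va, y_val,
                                        rvr_cfg, gamma, max_iter) or None

    current = list(range(features.n_features))
    if scorer is not None:
        cur_mse = float(scorer.val_mse([current])[0])
        cur_model = None
    else:
        cur_mse, cur_model = _fit_and_score(X_tr, y_train, X_va, y_val, current,
                                            rvr_cfg, gamma, max_iter)
    state = RFEState(selected=current, best_mse=cur_mse, gamma=gamma, model=cur_model)
    state.n_fits = 1
    state.history.append(("init", -1, cur_mse))

    while len(state.selected) > 1:
        # candidates ordered worst-ranked first so equal-MSE candidates
        # prefer dropping the lower-ranked feature (first minimum wins)
        drops = sorted(state.selected, reverse=True)
        cands = [[c for c in state.selected if c != f] for f in drops]
        if scorer is not None:
            mses = scorer.val_mse(cands)
            state.n_fits += len(cands)
            i, best_mse = _pick_min(mses)
            best_drop, best_model = drops[i], None
        else:
            best_mse, best_drop, best_model = np.inf, None, None
            for f, cand in zip(drops, cands):
                m, model = _fit_and_score(X_tr, y_train, X_va, y_val, cand,
                                          rvr_cfg, gamma, max_iter)
                state.n_fits += 1
                if m < best_mse - _TIE_TOL:
                    best_mse, best_drop, best_model = m, f, model
        if best_drop is None or best_mse >= state.best_mse - _TIE_TOL:
            break
        state.selected = [c for c in state.selected if c != best_drop]
        state.best_mse = best_mse
        state.model = best_model
        state.history.append(("remove", best_drop, best_mse))
    if state.model is None:
        _, state.model = _fit_and_score(X_tr, y_train, X_va, y_val,
                                        state.selected, rvr_cfg, gamma, max_iter)
    return state


def forward_add(
    state: RFEState,
    eliminated: list[int],
    features: FeatureMatrix,
    y_train: np.ndarray,
    val_features: FeatureMatrix,
    y_val: np.ndarray,
    rvr_cfg: KernelConfig = KernelConfig(),
    max_iter: int = 300,
    use_batch: bool = True,
) -> RFEState:
    """Forward re-addition of eliminated features under the same criterion.

    Accepts, per round, the addition with minimum validation MSE if it
    beats the incumbent; stops when no addition helps.  An empty
    ``eliminated`` list is a no-op.
    """
    X_tr, X_va = features.values, val_features.values
    y_train = np.asarray(y_train, float)
    y_val = np.asarray(y_val, float)
    pool = list(eliminated)
    gamma = state.gamma
    scorer = use_batch and _make_scorer(X_tr, y_train, X_va, y_val,
                                        rvr_cfg, gamma, max_iter) or None

    while pool:
        # higher-ranked (lower index) candidates first: ties prefer re-adding
        adds = sorted(pool)
        cands = [sorted(state.selected + [f]) for f in adds]
        if scorer is not None:
            mses = scorer.val_mse(cands)
            state.n_fits += len(cands)
            i, best_mse = _pick_min(mses)
            best_add, best_model = adds[i], None
        else:
            best_mse, best_add, best_model = np.inf, None, None
            for f, cand in zip(adds, cands):
                m, model = _fit_and_score(X_tr, y_train, X_va, y_val, cand,
                                          rvr_cfg, gamma, max_iter)
                state.n_fits += 1
                if m < best_mse - _TIE_TOL:
                    best_mse, best_add, best_model = m, f, model
        if best_add is None or best_mse >= state.best_mse - _TIE_TOL:
            break
        state.selected = sorted(state.selected + [best_add])
        pool.remove(best_add)
        state.best_mse = best_mse
        state.model = best_model
        state.history.append(("add", best_add, best_mse))
    if state.model is None:
        _, state.model = _fit_and_score(X_tr, y_train, X_va, y_val,
                                        state.selected, rvr_cfg, gamma, max_iter)
    return state


def rvr_rfe(
    features: FeatureMatrix,
    y_train: np.ndarray,
    val_features: FeatureMatrix,
    y_val: np.ndarray,
    rvr_cfg: KernelConfig = KernelConfig(),
    max_iter: int = 300,
    use_batch: bool = True,
) -> RFEState:
    """Full backward-then-forward search; the step-2 entry point."""
    state = backward_eliminate(features, y_train, val_features, y_val,
                               rvr_cfg, max_iter, use_batch=use_batch)
    eliminated = [f for f in range(features.n_features) if f not in state.selected]
    return forward_add(state, eliminated, features, y_train, val_features,
                       y_val, rvr_cfg, max_iter, use_batch=use_batch)


def trace_frame(state: RFEState, columns=None) -> pd.DataFrame:
    """RFE audit trace as a DataFrame (iteration, action, feature, MSE)."""
    rows = []
    for i, (action, feat, m) in enumerate(state.history):
        prov = columns[feat] if (columns is not None and feat >= 0) else None
        rows.append({
            "iteration": i, "action": action, "feature_index": feat,
            "modality": prov[0] if prov else "",
            "cluster": prov[1] if prov else -1,
            "validation_mse": m,
        })
    return pd.DataFrame(rows)
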
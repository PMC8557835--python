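"""Exhaustive constrained linear-model search over regulator subsets.

A regulator model is a subset S of the 10 features (5 biomarkers + their
5 integral regulators) with per-class, per-trajectory weights fitted by
intercept-free least squares on standardized data.  Models containing
both a regulator and its own integral are excluded — a regulator acts
either directly or indirectly, not both — which caps the model size at
5 and yields 10/40/80/80/32 admissible subsets of sizes 1..5 (242 in
total).  The loss of the empty model on a standardized trajectory is 1,
an absolute yardstick for goodness of fit.

Feature importance is summarized by mean absolute Shapley values over
the 32 admissible 5-feature models; for a linear model whose coalition
predictions are obtained by dropping terms, the Shapley decomposition
reduces exactly to phi_j(t_i) = beta_j zbar_j(t_i).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .preprocess import FEATURES, RegulatorPanel
from .residuals import ResidualTrajectory

__all__ = [
    "N_FEATURES",
    "enumerate_models",
    "fit_model",
    "fit_many",
    "total_error",
    "shapley_pipeline",
    "shapley_exact",
    "ShapleyTable",
    "dominant_term",
    "nested_f_test",
    "cv_check",
    "screen_hypothesis",
]

N_FEATURES = 10


def _admissible(subset: tuple[int, ...]) -> bool:
    s = set(subset)
    return not any(j in s and j + 5 in s for j in range(5))


def enumerate_models(max_terms: int = 5) -> list[tuple[int, ...]]:
    """All admissible feature subsets of size 1..max_terms, lexicographic.

    Admissibility forbids pairs {j, j+5} (a regulator together with its
    integral), so no admissible subset exceeds 5 features.
    """
    if not 1 <= max_terms <= 5:
        raise ValueError("max_terms must lie in 1..5 (direct/integral "
                         "exclusion caps model size at 5)")
    out = []
    for r in range(1, max_terms + 1):
        out.extend(s for s in itertools.combinations(range(N_FEATURES), r)
                   if _admissible(s))
    return out


def _as_matrix(trajectories) -> np.ndarray:
    """Stack trajectories (list of ResidualTrajectory or arrays) to (n, N-1)."""
    rows = [t.values if isinstance(t, ResidualTrajectory) else np.asarray(t, float)
            for t in trajectories]
    return np.vstack(rows)


def fit_model(subset: Sequence[int], X: np.ndarray, y: np.ndarray
              ) -> tuple[np.ndarray, float]:
    """Intercept-free OLS of one trajectory on the feature subset.

    Returns (weights, mean-squared loss).  The empty subset returns the
    empty-model loss mean(y^2) — equal to 1 for standardized y.  A
    rank-deficient design falls back to the minimum-norm solution with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    subset = tuple(subset)
    if len(subset) == 0:
        return np.empty(0), float(np.mean(y ** 2))
    A = np.asarray(X, dtype=float)[:, list(subset)]
    beta, _res, rank, _sv = np.linalg.lstsq(A, y, rcond=None)
    if rank < len(subset):
        warnings.warn("rank-deficient design; minimum-norm solution returned")
    r = y - A @ beta
    return beta, float(np.mean(r ** 2))


def fit_many(subset: Sequence[int], X: np.ndarray, Y: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized intercept-free OLS of many trajectories on one subset.

    Y is (n_traj, N-1).  Returns (betas (n_traj, |S|), losses (n_traj,)).
    """
    Y = np.asarray(Y, dtype=float)
    subset = tuple(subset)
    if len(subset) == 0:
        return np.empty((Y.shape[0], 0)), np.mean(Y ** 2, axis=1)
    A = np.asarray(X, dtype=float)[:, list(subset)]
    betas = (np.linalg.pinv(A) @ Y.T).T
    R = Y - betas @ A.T
    return betas, np.mean(R ** 2, axis=1)


def _design(panel: RegulatorPanel | np.ndarray, n_points: int) -> np.ndarray:
    V = panel.values if isinstance(panel, RegulatorPanel) else np.asarray(panel)
    return V[:n_points]


def total_error(subset: Sequence[int],
                panels: Mapping[int, RegulatorPanel | np.ndarray],
                ensembles: Mapping[int, Sequence]) -> float:
    """Total error E: mean minimized loss over classes and trajectories."""
    if set(panels) != set(ensembles):
        raise ValueError("panels and ensembles must cover the same classes")
    sizes = {len(ensembles[c]) for c in ensembles}
    if len(sizes) != 1:
        raise ValueError("equal n per class required")
    losses = []
    for c in sorted(ensembles):
        Y = _as_matrix(ensembles[c])
        X = _design(panels[c], Y.shape[1])
        _, l = fit_many(subset, X, Y)
        losses.append(l)
    return float(np.mean(np.concatenate(losses)))


@dataclass
class ShapleyTable:
    """Mean absolute Shapley value per feature with ensemble spread."""

    gene: str
    phi_mean: np.ndarray          # (10,)
    phi_sd: np.ndarray            # (10,) sd across (trajectory, class, subset)
    subsets: list[tuple[int, ...]]
    feature_names: tuple[str, ...] = FEATURES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": list(self.feature_names),
                             "phi_mean": self.phi_mean, "phi_sd": self.phi_sd,
                             "rank": (-self.phi_mean).argsort().argsort() + 1})

    def ranking(self) -> list[str]:
        return [self.feature_names[j] for j in np.argsort(-self.phi_mean)]


def shapley_pipeline(panels: Mapping[int, RegulatorPanel],
                     ensembles: Mapping[int, Sequence], gene: str = ""
                     ) -> ShapleyTable:
    """Mean absolute Shapley values over all admissible 5-feature models.

    For every admissible 5-set, every class and every trajectory, the
    model is fitted and each member feature receives
    phi_j(t_i) = beta_j zbar_j(t_i) (the exact linear decomposition);
    the absolute value is averaged over time points, then pooled over
    trajectories, classes and the 16 subsets containing the feature.
    """
    five_sets = [s for s in enumerate_models(5) if len(s) == 5]
    pools: list[list[float]] = [[] for _ in range(N_FEATURES)]
    for S in five_sets:
        for c in sorted(ensembles):
            Y = _as_matrix(ensembles[c])
            X = _design(panels[c], Y.shape[1])
            betas, _ = fit_many(S, X, Y)
            zabs = np.mean(np.abs(X[:, list(S)]), axis=0)    # (|S|,)
            phi = np.abs(betas) * zabs                       # (n, |S|)
            for k, j in enumerate(S):
                pools[j].extend(phi[:, k])
    phi_mean = np.array([np.mean(p) if p else 0.0 for p in pools])
    phi_sd = np.array([np.std(p) if p else 0.0 for p in pools])
    return ShapleyTable(gene, phi_mean, phi_sd, five_sets)


def shapley_exact(subset: Sequence[int], weights: Mapping[int, float],
                  X: np.ndarray, j: int) -> np.ndarray:
    """Shapley value of feature j by explicit coalition enumeration.

    The value of a coalition T is the prediction of the fitted model
    restricted to T (terms outside T dropped):
    v_T(t) = sum_{l in T} beta_l zbar_l(t).  phi_j(t_i) is the
    Shapley-weighted average of v_{T+j} - v_T over all T within the
    model's feature set.  Serves as the brute-force oracle for the
    linear shortcut phi_j = beta_j zbar_j.
    """
    subset = tuple(subset)
    if j not in subset:
        raise ValueError("feature j must belong to the subset")
    others = [l for l in subset if l != j]
    nf = len(subset)
    X = np.asarray(X, dtype=float)
    phi = np.zeros(X.shape[0])
    for r in range(len(others) + 1):
        for T in itertools.combinations(others, r):
            w = (math.factorial(len(T)) * math.factorial(nf - len(T) - 1)
                 / math.factorial(nf))
            v_T = sum(weights[l] * X[:, l] for l in T) if T else 0.0
            v_Tj = v_T + weights[j] * X[:, j]
            phi += w * (v_Tj - v_T)
    return phi


def dominant_term(subset: Sequence[int],
                  betas_by_class: Mapping[int, np.ndarray]) -> int:
    """Feature of a fitted model with the largest mean absolute weight.

    The mean runs over classes and trajectories; ties are broken toward
    the lower feature index (with a warning).
    """
    subset = tuple(subset)
    stacked = np.vstack([np.asarray(b, float) for b in betas_by_class.values()])
    score = np.mean(np.abs(stacked), axis=0)
    best = float(np.max(score))
    winners = [k for k, s in enumerate(score) if s == best]
    if len(winners) > 1:
        warnings.warn("dominant-term tie; returning the lowest feature index")
    return subset[winners[0]]


def nested_f_test(subset_small: Sequence[int], subset_large: Sequence[int],
                  losses_small: np.ndarray, losses_large: np.ndarray,
                  n_points: int) -> dict:
    """Per-trajectory F-test of a nested model pair.

    The losses are mean-squared residuals on n_points learning samples.
    Because the trajectories of an ensemble are not independent
    replicates, no pooled p-value is computed; the summary reports the
    median p and the fraction below 0.05.
    """
    s, l = set(subset_small), set(subset_large)
    if s == l:
        raise ValueError("models are identical; F-test undefined")
    if not s < l:
        raise ValueError("models are not nested")
    df1 = len(l) - len(s)
    df2 = n_points - len(l)
    if df2 <= 0:
        raise ValueError("not enough learning samples for the large model")
    rss_s = np.asarray(losses_small, float) * n_points
    rss_l = np.asarray(losses_large, float) * n_points
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_s - rss_l) / df1) / (rss_l / df2)
    p = f_dist.sf(F, df1, df2)
    p = np.where(rss_l == 0, 0.0, p)
    return {"p_values": p, "median_p": float(np.median(p)),
            "frac_significant": float(np.mean(p < 0.05)),
            "df": (df1, df2)}


def cv_check(subset: Sequence[int],
             panels: Mapping[int, RegulatorPanel | np.ndarray],
             ensembles: Mapping[int, Sequence], folds: int = 4,
             seed: int = 0) -> tuple[float, float]:
    """Shuffled-timepoint k-fold cross-validation (overfitting check).

    Per trajectory, time points are shuffled and split into folds; the
    model is refitted on the training folds and evaluated on the
    held-out fold.  Returns (mean train loss, mean test loss).
    """
    rng = np.random.default_rng(seed)
    subset = tuple(subset)
    train_losses, test_losses = [], []
    for c in sorted(ensembles):
        Y = _as_matrix(ensembles[c])
        n_pts = Y.shape[1]
        if n_pts < folds:
            raise ValueError("fewer time points than folds")
        X = _design(panels[c], n_pts)
        for y in Y:
            order = rng.permutation(n_pts)
            for fold in range(folds):
                test_idx = order[fold::folds]
                train_idx = np.setdiff1d(order, test_idx)
                beta, tr_loss = fit_model(subset, X[train_idx], y[train_idx])
                if len(subset):
                    pred = X[test_idx][:, list(subset)] @ beta
                else:
                    pred = 0.0
                test_losses.append(float(np.mean((y[test_idx] - pred) ** 2)))
                train_losses.append(tr_loss)
    return float(np.mean(train_losses)), float(np.mean(test_losses))


def screen_hypothesis(panels: Mapping[int, RegulatorPanel],
                      ensembles: Mapping[int, Sequence],
                      max_terms: int = 5, threshold: float = 0.15,
                      judge_size: int = 2) -> dict:
    """Best model per size, elbow position and accept/reject verdict.

    The elbow is the model size reached by the steepest drop in total
    error between consecutive sizes (1-term to 2-term, 2- to 3-term,
    ...); the drop from the empty model to 1 term is not considered, as
    it is almost always the largest.  The verdict accepts the hypothesis
    iff the best model of ``judge_size`` terms (2 by default: the
    complexity the slope analysis singles out for regulator models, a
    good balance of degrees of freedom and goodness of fit) beats the
    total-error threshold.  A forcing mechanism that only fits with many
    terms, or not at all, is rejected at this complexity.
    """
    best: dict[int, dict] = {}
    for S in enumerate_models(max_terms):
        E = total_error(S, panels, ensembles)
        r = len(S)
        if r not in best or E < best[r]["E"]:
            best[r] = {"subset": S, "E": E}
    sizes = sorted(best)
    errors = [best[r]["E"] for r in sizes]
    if len(sizes) > 1:
        drops = -np.diff(errors)
        elbow_size = sizes[int(np.argmax(drops)) + 1]
    else:
        elbow_size = sizes[0]
    judge = best[min(judge_size, max(sizes))]
    verdict = "accept" if judge["E"] <= threshold else "reject"
    return {"best_by_size": best, "elbow_size": elbow_size,
            "verdict": verdict, "threshold": threshold,
            "judge_size": judge_size, "E_at_judge": judge["E"],
            "E_at_elbow": best[elbow_size]["E"]}
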
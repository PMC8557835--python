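"""Class-difference statistics on fitted regulator weights.

The four mouse classes form a 2x2 sex-by-strain design.  Treating the
per-trajectory best-fit weights of one regulator model as realizations
of a random variable, the module quantifies class effects by two-way
fixed-effects ANOVA (with interaction), summarizes the weight
distributions by kernel-density estimates, checks practical
identifiability of the fitted weights by profile likelihood, and
re-optimizes models under a same-sign-across-classes constraint to ask
whether classwise opposite regulator action is genuinely required by
the data.

Caveat carried through the outputs: trajectories of an ensemble are
pseudo-replicates, not independent animals, so ANOVA p-values describe
the ensemble, not population-level inference.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import nnls
from scipy.signal import argrelmax
from scipy.stats import chi2, gaussian_kde

from .preprocess import FEATURES, RegulatorPanel
from .synthetic_data import CLASS_DESIGN

__all__ = [
    "weight_frame",
    "anova_weights",
    "weight_density",
    "profile_likelihood",
    "constrained_refit",
]


def weight_frame(subset: Sequence[int],
                 betas_by_class: Mapping[int, np.ndarray]) -> pd.DataFrame:
    """Tidy per-trajectory weight table with sex/strain labels."""
    rows = []
    for cid, B in betas_by_class.items():
        B = np.atleast_2d(np.asarray(B, float))
        sex, strain = CLASS_DESIGN[int(cid)]
        for k, j in enumerate(subset):
            rows.append(pd.DataFrame({
                "class_id": cid, "sex": sex, "strain": strain,
                "feature": FEATURES[j], "feature_index": j,
                "trajectory": np.arange(B.shape[0]), "weight": B[:, k],
            }))
    return pd.concat(rows, ignore_index=True)


def anova_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (sex, strain, interaction) per feature.

    ``weights`` is the tidy frame from :func:`weight_frame`.  Returns a
    table with one row per (feature, factor) carrying F and p.  The
    returned frame's ``attrs['pseudo_replicates']`` flags that
    trajectories are not independent replicates.
    """
    needed = {"sex", "strain", "weight", "feature"}
    if not needed <= set(weights.columns):
        raise ValueError(f"weight frame must contain columns {sorted(needed)}")
    out = []
    for feat, sub in weights.groupby("feature", sort=False):
        cells = sub.groupby(["sex", "strain"]).size()
        if len(cells) < 4 or (cells < 2).any():
            raise ValueError(f"feature {feat}: empty or degenerate design cell")
        model = smf.ols("weight ~ C(sex) * C(strain)", data=sub).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for factor, label in (("C(sex)", "sex"), ("C(strain)", "strain"),
                              ("C(sex):C(strain)", "interaction")):
            out.append({"feature": feat, "factor": label,
                        "F": float(table.loc[factor, "F"]),
                        "p": float(table.loc[factor, "PR(>F)"]),
                        "df": float(table.loc[factor, "df"])})
    res = pd.DataFrame(out)
    res.attrs["pseudo_replicates"] = True
    return res


def weight_density(weights: pd.DataFrame, feature: str,
                   n_grid: int = 256) -> dict[int, dict]:
    """Gaussian-KDE weight distributions per class, with modes.

    Scott's rule-of-thumb bandwidth.  Returns class -> {grid, density,
    modes}; requires at least 10 samples per class.
    """
    sub = weights[weights["feature"] == feature]
    if sub.empty:
        raise ValueError(f"no samples for feature {feature!r}")
    out = {}
    for cid, g in sub.groupby("class_id"):
        x = g["weight"].to_numpy(float)
        if len(x) < 10:
            raise ValueError(f"class {cid}: need >= 10 samples for a KDE")
        if np.std(x) == 0:
            grid = np.linspace(x[0] - 1.0, x[0] + 1.0, n_grid)
            dens = np.zeros(n_grid)
            dens[np.argmin(np.abs(grid - x[0]))] = 1.0 / (grid[1] - grid[0])
            out[int(cid)] = {"grid": grid, "density": dens, "modes": [float(x[0])]}
            continue
        kde = gaussian_kde(x)
        lo, hi = x.min() - 3 * kde.factor * x.std(), x.max() + 3 * kde.factor * x.std()
        grid = np.linspace(lo, hi, n_grid)
        dens = kde(grid)
        mode_idx = argrelmax(dens)[0]
        modes = sorted(float(grid[i]) for i in mode_idx) or [float(grid[np.argmax(dens)])]
        out[int(cid)] = {"grid": grid, "density": dens, "modes": modes}
    return out


def profile_likelihood(subset: Sequence[int], X: np.ndarray, y: np.ndarray,
                       feature: int, grid: np.ndarray | None = None,
                       n_grid: int = 41, span_se: float = 5.0,
                       alpha: float = 0.95) -> dict:
    """Profile of the loss over one fixed weight, with identifiability verdict.

    For each fixed value of beta_j the remaining weights are re-optimized
    and the mean-squared loss recorded.  Under the Gaussian-error
    mapping, the profile crosses loss_min * (1 + chi2_1(alpha)/dof) at
    the ends of an approximate confidence interval; the weight is
    declared identifiable iff the profile crosses that threshold on both
    sides within the grid, 'inconclusive' if the grid is too narrow.
    """
    subset = tuple(subset)
    if feature not in subset:
        raise ValueError("feature must belong to the subset")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = X[:, list(subset)]
    beta_hat, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta_hat
    n, k = A.shape
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough samples to profile")
    loss_min = float(np.mean(resid ** 2))
    pos = subset.index(feature)
    if grid is None:
        sigma2 = max(np.sum(resid ** 2) / dof, 1e-300)
        cov = sigma2 * np.linalg.pinv(A.T @ A)
        se = float(np.sqrt(max(cov[pos, pos], 1e-300)))
        grid = beta_hat[pos] + np.linspace(-span_se * se, span_se * se, n_grid)
    others = [l for l in subset if l != feature]
    Xo = X[:, others] if others else None
    profile = []
    for v in grid:
        resid_v = y - v * X[:, feature]
        if Xo is not None and Xo.size:
            b, *_ = np.linalg.lstsq(Xo, resid_v, rcond=None)
            resid_v = resid_v - Xo @ b
        profile.append(float(np.mean(resid_v ** 2)))
    profile = np.array(profile)
    threshold = loss_min * (1.0 + chi2.ppf(alpha, 1) / dof)
    left = bool(np.any(profile[grid < beta_hat[pos]] > threshold))
    right = bool(np.any(profile[grid > beta_hat[pos]] > threshold))
    if left and right:
        verdict = "identifiable"
    elif np.ptp(profile) < 1e-12 * max(loss_min, 1.0):
        verdict = "non-identifiable"
    else:
        verdict = "inconclusive"
    return {"grid": np.asarray(grid, float), "profile": profile,
            "loss_min": loss_min, "beta_hat": float(beta_hat[pos]),
            "threshold": threshold, "verdict": verdict}


def _sign_template(subset, panels, ensembles) -> np.ndarray:
    """Majority-vote sign per feature from the unconstrained fits."""
    from .model_search import fit_many, _as_matrix, _design
    total = np.zeros(len(subset))
    for c in sorted(ensembles):
        Y = _as_matrix(ensembles[c])
        X = _design(panels[c], Y.shape[1])
        betas, _ = fit_many(subset, X, Y)
        total += np.sum(np.sign(betas), axis=0)
    template = np.where(total >= 0, 1.0, -1.0)
    return template


def constrained_refit(subset: Sequence[int],
                      panels: Mapping[int, RegulatorPanel],
                      ensembles: Mapping[int, Sequence],
                      template: Sequence[float] | None = None) -> dict:
    """Refit with regulator weight signs forced equal across classes.

    ``template`` gives the enforced sign (+1/-1) per feature; if None, a
    majority vote over the unconstrained fits decides.  Solved per
    trajectory by non-negative least squares on sign-flipped columns.
    Returns constrained/unconstrained total errors and their ratio.
    """
    from .model_search import fit_many, total_error, _as_matrix, _design
    subset = tuple(subset)
    if template is None:
        template = _sign_template(subset, panels, ensembles)
    template = np.asarray(template, dtype=float)
    if template.shape != (len(subset),) or np.any(np.abs(template) != 1):
        raise ValueError("sign template must be +/-1 per feature")
    e_unc = total_error(subset, panels, ensembles)
    losses = []
    betas_by_class = {}
    for c in sorted(ensembles):
        Y = _as_matrix(ensembles[c])
        X = _design(panels[c], Y.shape[1])
        A = X[:, list(subset)] * template
        B = []
        for y in Y:
            b, _ = nnls(A, y)
            r = y - A @ b
            losses.append(float(np.mean(r ** 2)))
            B.append(template * b)
        betas_by_class[c] = np.array(B)
    e_con = float(np.mean(losses))
    return {"E_unconstrained": e_unc, "E_constrained": e_con,
            "ratio": e_con / e_unc if e_unc > 0 else np.inf,
            "template": template, "betas_by_class": betas_by_class}
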
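"""Smoothing, rhythm validation and regulator-panel construction.

Raw replicate time series of the five systemic biomarkers (rest-activity,
body temperature, food intake, corticosterone, melatonin) are smoothed
into mean functions on a common circadian grid with a Gaussian process
whose kernel is 24 h-periodic.  Rhythmicity is validated by cosinor
regression (single 24 h harmonic, F-test against the constant model).
The regulator panel stacks the five smoothed biomarkers with their five
*integral regulators* — cumulative integrals of the mean-centred signals
that stand in for unobserved intermediate species produced linearly by
each regulator — and standardizes every column to zero mean and unit
standard deviation, keeping the record needed to invert the transform.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import f as f_dist
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, ExpSineSquared, WhiteKernel

__all__ = [
    "BIOMARKERS",
    "FEATURES",
    "SmoothSeries",
    "RegulatorPanel",
    "CosinorFit",
    "fit_periodic_gp",
    "cosinor_test",
    "integral_regulator",
    "build_panel",
    "default_grid",
]

#: canonical biomarker order; the feature vector is these five followed by
#: their integral counterparts, giving the fixed 10-feature ordering used
#: throughout the model search (feature j+5 is the integral of feature j)
BIOMARKERS = ("activity", "temperature", "food_intake", "corticosterone", "melatonin")
FEATURES = BIOMARKERS + tuple(f"int_{b}" for b in BIOMARKERS)


def default_grid(n: int = 24) -> np.ndarray:
    """Hourly circadian grid over one cycle, [0, 24) h with N points."""
    return np.arange(n, dtype=float) * (24.0 / n)


@dataclass
class SmoothSeries:
    """GP posterior mean of one biomarker/gene on a circadian grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if len(self.grid) < 8:
            raise ValueError("grid must have at least 8 points")
        if self.mean.shape != self.grid.shape or self.sd.shape != self.grid.shape:
            raise ValueError("mean/sd must match the grid")


def fit_periodic_gp(times_h: np.ndarray, values: np.ndarray,
                    grid: np.ndarray | None = None, n_restarts: int = 5,
                    seed: int = 0, label: str = "",
                    log_space: bool = False) -> SmoothSeries:
    """Smooth replicate observations with a 24 h-periodic GP.

    Replicates are first collapsed to per-time means; the GP kernel is
    constant * periodic(24 h) + white noise, with hyperparameters set by
    maximum marginal likelihood (multi-restart, seeded).  The posterior
    mean is 24 h-periodic by construction of the kernel.

    ``log_space=True`` fits the GP to log-values and exponentiates the
    posterior mean — appropriate for strictly positive signals such as
    mRNA concentrations whose replicate scatter is multiplicative; it
    keeps the relative (rather than absolute) error uniform, which
    matters near deep troughs.

    Requires at least 8 (time, value) pairs spanning at least 24 h.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if log_space:
        if np.any(v <= 0):
            raise ValueError("log-space smoothing requires positive values")
        out = fit_periodic_gp(t, np.log(v), grid=grid, n_restarts=n_restarts,
                              seed=seed, label=label, log_space=False)
        mean = np.exp(out.mean)
        return SmoothSeries(out.grid, mean, mean * out.sd, label)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if len(t) < 8:
        raise ValueError("need at least 8 observations to smooth")
    if t.max() - t.min() < 24.0 - 1e-9:
        raise ValueError("observations must span at least 24 h")
    if len(np.unique(t)) < 2:
        raise ValueError("degenerate input: a single distinct time point")
    if grid is None:
        grid = default_grid()
    # collapse replicates to per-time means (noise is carried by the
    # white-noise kernel term; keeps the GP solve tractable for dense
    # sensor data)
    df = pd.DataFrame({"t": t, "v": v}).groupby("t", as_index=False).mean()
    tm, vm = df["t"].to_numpy(), df["v"].to_numpy()
    if np.std(vm) == 0.0:
        c = float(vm[0])
        return SmoothSeries(grid, np.full_like(grid, c), np.zeros_like(grid), label)
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * ExpSineSquared(length_scale=1.0, periodicity=24.0,
                               length_scale_bounds=(0.1, 20.0),
                               periodicity_bounds="fixed")
              + WhiteKernel(1e-2, (1e-10, 1e1)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=n_restarts,
                                  random_state=seed)
    gp.fit(tm[:, None], vm)
    mean, sd = gp.predict(np.asarray(grid)[:, None], return_std=True)
    return SmoothSeries(np.asarray(grid, dtype=float), mean, sd, label)


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_h: float
    p_value: float


def cosinor_test(times_h: np.ndarray, values: np.ndarray,
                 period_h: float = 24.0) -> CosinorFit:
    """Single-harmonic cosinor fit with an F-test for rhythmicity.

    Fits M + A cos(2 pi (t - phi)/24) by least squares via the linear
    parametrization a cos + b sin; the p-value tests the two rhythmic
    terms against the constant model.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(t)
    if n < 4:
        raise ValueError("cosinor needs at least 4 observations")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((v - v.mean()) ** 2))
    mesor, a, b = coef
    amplitude = float(np.hypot(a, b))
    acrophase = float((np.arctan2(b, a) / w) % period_h)
    df2 = n - 3
    if rss1 <= 1e-300 * max(rss0, 1.0):
        p = 0.0
    else:
        F = ((rss0 - rss1) / 2.0) / (rss1 / df2)
        p = float(f_dist.sf(F, 2, df2))
    return CosinorFit(float(mesor), amplitude, acrophase, p)


def integral_regulator(series: SmoothSeries | None = None, *,
                       grid: np.ndarray | None = None,
                       values: np.ndarray | None = None,
                       center: bool = True) -> np.ndarray:
    """Cumulative trapezoidal integral of a (mean-centred) signal.

    The centring makes the integral of a periodic regulator periodic as
    well — the raw integral of a positive biomarker is an unbounded ramp
    that no periodic residual trajectory could match.  ``center=False``
    gives the literal running integral.  Z(t_0) = 0 by convention.
    """
    if series is not None:
        grid, values = series.grid, series.mean
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    z = values - values.mean() if center else values
    return cumulative_trapezoid(z, grid, initial=0.0)


@dataclass
class RegulatorPanel:
    """Standardized N x 10 matrix of direct + integral regulators."""

    grid: np.ndarray
    values: np.ndarray                        # standardized, (N, 10)
    means: np.ndarray                         # per-column pre-standardization
    sds: np.ndarray
    feature_names: tuple[str, ...] = FEATURES
    class_id: int | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid), len(self.feature_names)):
            raise ValueError("panel shape mismatch")

    def column(self, feature: int | str) -> np.ndarray:
        j = (self.feature_names.index(feature)
             if isinstance(feature, str) else int(feature))
        return self.values[:, j]

    def design(self, subset: Sequence[int], n_rows: int | None = None) -> np.ndarray:
        """Design matrix restricted to a feature subset (first n_rows rows)."""
        rows = slice(None) if n_rows is None else slice(0, n_rows)
        return self.values[rows][:, list(subset)]

    def inverse_transform(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.sds + self.means

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "time_h", self.grid)
        df.to_csv(path, index=False, float_format="%.12g")
        rec = {"means": self.means.tolist(), "sds": self.sds.tolist(),
               "feature_names": list(self.feature_names),
               "class_id": self.class_id}
        Path(str(path) + ".json").write_text(json.dumps(rec, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegulatorPanel":
        df = pd.read_csv(path)
        rec = json.loads(Path(str(path) + ".json").read_text())
        return cls(grid=df["time_h"].to_numpy(),
                   values=df[rec["feature_names"]].to_numpy(),
                   means=np.array(rec["means"]), sds=np.array(rec["sds"]),
                   feature_names=tuple(rec["feature_names"]),
                   class_id=rec["class_id"])


def build_panel(smooth: Mapping[str, SmoothSeries],
                class_id: int | None = None) -> RegulatorPanel:
    """Assemble the 10-column regulator panel from five smoothed biomarkers.

    Columns 0-4 are the smoothed biomarkers in canonical order, columns
    5-9 their integral regulators (computed before standardization);
    every column is then standardized to mean 0, sd 1 on the grid.
    """
    missing = set(BIOMARKERS) - set(smooth)
    if missing:
        raise ValueError(f"missing biomarkers: {sorted(missing)}")
    grid = smooth[BIOMARKERS[0]].grid
    for b in BIOMARKERS:
        if not np.array_equal(smooth[b].grid, grid):
            raise ValueError(f"grid mismatch for biomarker {b!r}")
    cols = [smooth[b].mean for b in BIOMARKERS]
    cols += [integral_regulator(smooth[b]) for b in BIOMARKERS]
    raw = np.column_stack(cols)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    if np.any(sds == 0):
        flat = [FEATURES[j] for j in np.where(sds == 0)[0]]
        raise ValueError(f"constant regulator column(s), cannot standardize: {flat}")
    return RegulatorPanel(grid=grid, values=(raw - means) / sds,
                          means=means, sds=sds, class_id=class_id)
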
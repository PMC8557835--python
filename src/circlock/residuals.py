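"""Residual trajectories: inverting the clock ODE into a forcing signal.

Given smoothed in vivo mRNA data x(t_i) of one clock gene and a
(possibly parameter-perturbed) simulation of the unforced clock, the
gene's ODE is solved algebraically for the multiplicative forcing f that
systemic regulators would have to exert on its transcription (H1)

    y(t_i) = (dx/dt + alpha x) / Transc(M, gamma)

or on its mRNA degradation (H2)

    y(t_i) = (Vmax Transc(M, gamma) - dx/dt) / x,

with dx/dt the forward difference on the circadian grid, so y is defined
on the first N-1 grid points.  Each y is a *residual trajectory*.

Robustness to the unreliability of in-vitro-fitted parameters in vivo is
obtained by sampling an ensemble: parameters are perturbed with additive
Gaussian noise proportional to their value (H3), the perturbed clock is
re-simulated, kept only if it still looks like a realistic circadian
clock (period within 20-28 h, relative amplitude above 5 %, antagonist
species more than 6 h apart), and the residual is computed from the
perturbed model.  This repeats until n trajectories per mouse class are
accepted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clock_model import (
    CONSTITUTIVE_STATES,
    MODULATORS,
    STATES,
    ClockParams,
    ClockTrajectory,
    circular_distance,
    default_sobol_set,
    gene_kinetic_params,
    limit_cycle,
    rhythm_metrics,
    simulate,
    transcription_rate,
    _HILL_NAMES,
)

__all__ = [
    "PerturbationSpec",
    "ResidualTrajectory",
    "perturb_params",
    "accept_clock",
    "residual_h1",
    "residual_h2",
    "generate_ensemble",
]


@dataclass
class PerturbationSpec:
    """H3 perturbation law and realistic-clock acceptance thresholds.

    The perturbation adds Gaussian noise with standard deviation
    ``theta_j * sigma_eff`` to every selected coordinate.  ``sigma`` is
    the nominal scaling factor of the noise law; by default it is read
    as an inverse scale (sigma_eff = 1/sigma = 0.1), because a literal
    10-fold standard deviation would leave essentially no perturbed
    clock passing the realism filter.  Set ``literal=True`` to use
    sigma_eff = sigma verbatim.
    """

    sigma: float = 10.0
    literal: bool = False
    n: int = 2000
    period_band: tuple[float, float] = (20.0, 28.0)
    min_rel_amp: float = 0.05
    min_phase_sep_h: float = 6.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.min_rel_amp <= 0 or self.min_phase_sep_h <= 0:
            raise ValueError("acceptance thresholds must be positive")
        if self.period_band[0] <= 0 or self.period_band[1] <= self.period_band[0]:
            raise ValueError("invalid period band")

    @property
    def sigma_eff(self) -> float:
        return self.sigma if self.literal else 1.0 / self.sigma


def perturb_params(theta: ClockParams, coords: Sequence[str],
                   sigma_eff: float, rng: np.random.Generator) -> ClockParams:
    """Additive Gaussian perturbation of selected parameter coordinates.

    theta_j -> theta_j + eps, eps ~ N(0, (theta_j * sigma_eff)^2),
    resampled (up to 1000 times) until the coordinate is admissible
    (positive; >= 1 for Hill coefficients).  Unselected coordinates are
    untouched.
    """
    new = dict(theta)
    for name in coords:
        if name not in new:
            raise KeyError(f"unknown parameter {name!r}")
        base = new[name]
        sd = base * sigma_eff
        if sd == 0:
            continue
        lo = 1.0 if name in _HILL_NAMES else 0.0
        for _ in range(1000):
            candidate = base + rng.normal(0.0, sd)
            if candidate > lo or (lo == 1.0 and candidate >= lo):
                new[name] = candidate
                break
        else:
            raise RuntimeError(
                f"could not draw an admissible value for {name} "
                f"(base {base}, sd {sd})")
    return ClockParams(new)


def accept_clock(traj: ClockTrajectory,
                 spec: PerturbationSpec | None = None) -> tuple[bool, dict]:
    """Realistic-clock filter for a simulated trajectory.

    Accepts iff every (non-constitutive) state variable is rhythmic with
    period inside the band and relative amplitude strictly above the
    threshold, AND the circular phase separations REV-ERB vs ROR and
    PER/CRY vs CLOCK/BMAL both strictly exceed the minimum (antagonist
    species must not peak together).  Returns (ok, diagnostics).
    """
    if spec is None:
        spec = PerturbationSpec()
    diag: dict = {"failures": []}
    mets = {}
    for name in traj.state_names:
        if name in CONSTITUTIVE_STATES:
            continue
        m = rhythm_metrics(traj, name)
        mets[name] = m
        if not m.rhythmic:
            diag["failures"].append((name, "non-rhythmic"))
            continue
        if not (spec.period_band[0] <= m.period_h <= spec.period_band[1]):
            diag["failures"].append((name, f"period {m.period_h:.2f}"))
        if not m.relative_amplitude > spec.min_rel_amp:
            diag["failures"].append((name, f"amplitude {m.relative_amplitude:.4f}"))
    for a, b in (("rev_erb", "ror_p"), ("per_cry_n", "clock_bmal_n")):
        ma, mb = mets.get(a), mets.get(b)
        if ma is None or mb is None or not (ma.rhythmic and mb.rhythmic):
            continue
        period = 0.5 * (ma.period_h + mb.period_h)
        sep = circular_distance(ma.phase_h, mb.phase_h, period)
        diag[f"sep_{a}_{b}"] = sep
        if not sep > spec.min_phase_sep_h:
            diag["failures"].append((f"{a}/{b}", f"phase separation {sep:.2f}"))
    diag["metrics"] = mets
    return (len(diag["failures"]) == 0), diag


@dataclass
class ResidualTrajectory:
    """One realization of the inverted forcing y(t_i), i = 1..N-1."""

    gene: str
    hypothesis: str
    class_id: int
    values: np.ndarray                     # standardized y, length N-1
    raw: np.ndarray                        # pre-standardization y
    grid: np.ndarray                       # the N-1 grid times
    provenance: dict = field(default_factory=dict)
    standardized: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("residual trajectory contains non-finite values")


def _standardize(y: np.ndarray) -> np.ndarray:
    sd = y.std()
    if sd == 0:
        raise ValueError("constant residual trajectory cannot be standardized")
    return (y - y.mean()) / sd


def _finite_diff(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.diff(x) / np.diff(grid)


def _midpoints(values: np.ndarray, grid: np.ndarray,
               periodic: bool = True) -> np.ndarray:
    """Values at interval midpoints (periodic interpolation over 24 h).

    The forward difference approximates the derivative at the interval
    midpoint to second order; evaluating the algebraic terms of the
    inversion at the same points keeps the discretization consistent,
    which matters for sharply peaked mRNA profiles.
    """
    tmid = grid[:-1] + np.diff(grid) / 2.0
    if periodic:
        return np.interp(tmid % 24.0, grid, values, period=24.0)
    return np.interp(tmid, grid, values)


def residual_h1(gene: str, x_vivo: np.ndarray, grid: np.ndarray,
                M: Mapping[str, np.ndarray], theta: ClockParams,
                class_id: int = 0, standardize: bool = True,
                provenance: dict | None = None) -> ResidualTrajectory:
    """Residual trajectory under H1 (forcing on transcription).

    y(t_i) = (dx/dt + alpha x) / Transc(M, gamma) over the first N-1
    learning samples, then standardized.  The forward difference dx/dt
    is second-order accurate at the interval midpoint, so the algebraic
    terms (alpha x and the transcription multiplier) are evaluated there
    too.  A non-positive transcription multiplier anywhere invalidates
    the perturbed clock for this use.
    """
    gene = gene.lower()
    x = np.asarray(x_vivo, dtype=float)
    grid = np.asarray(grid, dtype=float)
    transc = np.asarray(transcription_rate(gene, M, theta), dtype=float)
    if np.any(transc <= 0):
        raise ValueError("non-positive transcription multiplier on the grid")
    alpha = theta[f"deg_{gene}"]
    x_mid = 0.5 * (x[:-1] + x[1:])
    t_mid = _midpoints(transc, grid)
    y = (_finite_diff(x, grid) + alpha * x_mid) / t_mid
    vals = _standardize(y) if standardize else y
    return ResidualTrajectory(gene, "H1", class_id, vals, y, grid[:-1],
                              provenance or {}, standardize)


def residual_h2(gene: str, x_vivo: np.ndarray, grid: np.ndarray,
                M: Mapping[str, np.ndarray], theta: ClockParams,
                class_id: int = 0, standardize: bool = True,
                provenance: dict | None = None) -> ResidualTrajectory:
    """Residual trajectory under H2 (forcing on mRNA degradation).

    y(t_i) = (Vmax Transc(M, gamma) - dx/dt) / x over the first N-1
    learning samples, with the algebraic terms evaluated at the interval
    midpoints (consistent with the forward difference).  Division by
    near-zero mRNA levels can produce sharp spikes; they are genuine
    features of this hypothesis and are preserved.
    """
    gene = gene.lower()
    x = np.asarray(x_vivo, dtype=float)
    grid = np.asarray(grid, dtype=float)
    x_mid = 0.5 * (x[:-1] + x[1:])
    if np.any(x_mid == 0):
        raise ValueError("zero mRNA level on the grid; H2 residual undefined")
    transc = np.asarray(transcription_rate(gene, M, theta), dtype=float)
    vmax = theta[f"vmax_{gene}"]
    y = (vmax * _midpoints(transc, grid) - _finite_diff(x, grid)) / x_mid
    vals = _standardize(y) if standardize else y
    return ResidualTrajectory(gene, "H2", class_id, vals, y, grid[:-1],
                              provenance or {}, standardize)


def generate_ensemble(gene: str, hypothesis: str,
                      x_vivo_by_class: Mapping[int, np.ndarray],
                      grid: np.ndarray, base_thetas: Sequence[ClockParams],
                      spec: PerturbationSpec | None = None, seed: int = 0,
                      coords: Sequence[str] | None = None,
                      sim_kwargs: dict | None = None,
                      ) -> dict[int, list[ResidualTrajectory]]:
    """Ensemble of n accepted residual trajectories per mouse class.

    Each attempt draws a base parameter set (round-robin over the
    calibrated fits), perturbs the selected coordinates (the target
    gene's Vmax/alpha/gamma plus the Sobol-selected modulator-sensitive
    set by default), re-simulates, applies the realistic-clock filter
    and — if accepted — computes one residual per class from the
    anchored limit-cycle modulator profiles.  A draw whose residual
    computation fails for any class (non-positive transcription
    multiplier) counts as rejected for all classes, keeping n equal
    across classes.
    """
    if spec is None:
        spec = PerturbationSpec()
    if hypothesis not in ("H1", "H2"):
        raise ValueError("hypothesis must be 'H1' or 'H2'")
    if len(base_thetas) == 0:
        raise ValueError("need at least one base parameter set")
    if coords is None:
        coords = tuple(dict.fromkeys(
            list(gene_kinetic_params(gene)) + list(default_sobol_set())))
    rng = np.random.default_rng(seed)
    resid_fn = residual_h1 if hypothesis == "H1" else residual_h2
    sim_kwargs = dict(sim_kwargs or {})
    out: dict[int, list[ResidualTrajectory]] = {c: [] for c in x_vivo_by_class}
    n_accept = 0
    attempts = 0
    while n_accept < spec.n:
        attempts += 1
        if attempts > 100_000 and n_accept / attempts < 1e-3:
            raise RuntimeError(
                f"acceptance rate {n_accept}/{attempts} below 0.1%; "
                "check perturbation scale and thresholds")
        base_idx = (attempts - 1) % len(base_thetas)
        theta = perturb_params(base_thetas[base_idx], coords,
                               spec.sigma_eff, rng)
        try:
            traj = simulate(theta, **sim_kwargs)
        except RuntimeError:
            continue
        ok, _diag = accept_clock(traj, spec)
        if not ok:
            continue
        try:
            prof, period = limit_cycle(traj, grid=grid)
        except ValueError:
            continue
        M = {m: prof[m] for m in MODULATORS}
        prov = {"base_index": base_idx, "attempt": attempts,
                "period_h": period, "theta": dict(theta)}
        drawn = {}
        try:
            for cid, x in x_vivo_by_class.items():
                drawn[cid] = resid_fn(gene, x, grid, M, theta, class_id=cid,
                                      provenance=prov)
        except ValueError:
            continue
        for cid, r in drawn.items():
            out[cid].append(r)
        n_accept += 1
    for c in out:
        assert len(out[c]) == spec.n
    return out
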
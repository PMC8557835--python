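"""Synthetic circadian data for four mouse classes with known ground truth.

Three generators mirror the structure of the kind of mouse dataset the
pipeline is designed for:

* ``generate_biomarkers`` — cosinor-shaped 24 h rhythms of the five
  systemic biomarkers (rest-activity, body temperature, food intake,
  corticosterone, melatonin) with class-specific mesor/amplitude/phase
  and replicate noise.  Classes 1/2 are female/male of one strain,
  classes 3/4 female/male of another; the default specs encode the
  qualitative contrasts expected of such data (sex differences in
  activity mesor and relative amplitude, near-identical temperature,
  classwise-preserved phases, weak food-intake rhythms in classes 3/4).
  Melatonin is generated like every other biomarker: downstream it acts
  as the pipeline's negative control, so it must be present.
* ``generate_invitro_expression`` — limit-cycle mRNA profiles of the six
  clock genes from the unforced clock model, for calibration.
* ``generate_invivo_expression`` — clock-gene profiles in which ONE
  target gene is forced by a known linear combination of the class's
  regulators acting multiplicatively on its transcription (H1) or mRNA
  degradation (H2); the remaining genes follow the unforced model.  This
  provides end-to-end recovery targets for the inference layer.

All default numeric values are synthetic placeholders chosen to be
biologically plausible in their units; they are not measurements.
Every generator is deterministic given its seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .clock_model import (
    GENES,
    ClockParams,
    limit_cycle,
    reference_params,
    simulate,
    transcription_rate,
)
from .preprocess import BIOMARKERS, RegulatorPanel

__all__ = [
    "BiomarkerSpec",
    "ClassSpec",
    "GroundTruth",
    "default_class_specs",
    "generate_biomarkers",
    "generate_invitro_expression",
    "generate_invivo_expression",
]

#: class -> (sex, strain) layout of the 2x2 design
CLASS_DESIGN = {
    1: ("F", "strainA"),
    2: ("M", "strainA"),
    3: ("F", "strainB"),
    4: ("M", "strainB"),
}


@dataclass
class BiomarkerSpec:
    """Cosinor parameters and sampling design of one biomarker."""

    mesor: float
    amplitude: float
    acrophase_h: float
    noise_sd: float
    step_h: float
    duration_h: float
    n_replicates: int
    interval: bool = False   # True: value is consumption over [t, t+step]

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 <= self.acrophase_h < 24):
            raise ValueError("acrophase_h must lie in [0, 24)")
        if self.noise_sd < 0:
            raise ValueError("replicate noise sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class ClassSpec:
    """One mouse class (sex x strain) with per-biomarker rhythm specs."""

    class_id: int
    sex: str
    strain: str
    biomarkers: dict[str, BiomarkerSpec]

    def __post_init__(self):
        missing = set(BIOMARKERS) - set(self.biomarkers)
        if missing:
            raise ValueError(f"class {self.class_id}: missing biomarkers {sorted(missing)}")


def _spec(mesor, amp, phase, noise, step, dur, reps, interval=False):
    return BiomarkerSpec(mesor, amp, phase, noise, step, dur, reps, interval)


def default_class_specs() -> dict[int, ClassSpec]:
    """Synthetic default specs for the four classes (placeholder values).

    Contrasts encoded: females (classes 1, 3) have higher activity mesor
    and relative amplitude than males; temperature is virtually identical
    across classes; food intake is robustly rhythmic in classes 1-2 and
    weakly rhythmic in classes 3-4; corticosterone is damped in class 2;
    acrophases are preserved classwise for every biomarker.  Sensor
    signals (activity, temperature): 10-min step over 72 h, 8 replicates;
    hormones: 3 h step over 24 h, 3 replicates; food intake: 4 h
    weighing intervals over 48 h, 3 replicates.
    """
    specs = {}
    for cid, (sex, strain) in CLASS_DESIGN.items():
        female = sex == "F"
        strain_a = strain == "strainA"
        # activity onset precedes the body-temperature peak by ~1.5 h;
        # identical acrophases would make the two integral regulators
        # numerically indistinguishable
        act = _spec(12.0 if female else 8.0, 8.0 if female else 4.5,
                    17.0, 2.0, 1 / 6, 72.0, 8)
        temp = _spec(36.5, 0.8, 18.5, 0.25, 1 / 6, 72.0, 8)
        food = _spec(2.0, 1.2 if strain_a else 0.3, 20.0,
                     0.3, 4.0, 48.0, 3, interval=True)
        cort = _spec(60.0, 25.0 if cid == 2 else 45.0, 12.0,
                     18.0 if cid == 2 else 12.0, 3.0, 24.0, 3)
        mel = _spec(20.0, 15.0, 2.0, 4.0, 3.0, 24.0, 3)
        specs[cid] = ClassSpec(cid, sex, strain, {
            "activity": act, "temperature": temp, "food_intake": food,
            "corticosterone": cort, "melatonin": mel,
        })
    return specs


def _cosinor(t, mesor, amp, phase):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / 24.0)


def _cosinor_interval(t0, t1, mesor, amp, phase):
    """Integral of the cosinor rate over [t0, t1] (consumed amount)."""
    w = 2 * np.pi / 24.0
    prim = lambda t: mesor * t + amp / w * np.sin(w * (t - phase))
    return prim(t1) - prim(t0)


def generate_biomarkers(spec: ClassSpec, seed: int = 0) -> pd.DataFrame:
    """Raw biomarker table (long format) for one class.

    Point-sampled biomarkers get values mesor + A cos(2 pi (t - phi)/24)
    + Gaussian replicate noise at each design time.  Interval biomarkers
    (food intake) get the consumption over each weighing interval, i.e.
    the integral of the cosinor rate over the bin, recorded at the bin
    start — a step signal, like differenced cage-food weights.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in BIOMARKERS:
        b = spec.biomarkers[name]
        if b.interval:
            # mesor/amplitude are per-bin consumption; integrate the
            # corresponding rate over each weighing interval
            starts = np.arange(0.0, b.duration_h - 1e-9, b.step_h)
            base = _cosinor_interval(starts, starts + b.step_h,
                                     b.mesor / b.step_h, b.amplitude / b.step_h,
                                     b.acrophase_h)
            times = starts
        else:
            times = np.arange(0.0, b.duration_h + 1e-9, b.step_h)
            base = _cosinor(times, b.mesor, b.amplitude, b.acrophase_h)
        for rep in range(1, b.n_replicates + 1):
            noise = rng.normal(0.0, b.noise_sd, size=len(times))
            rows.append(pd.DataFrame({
                "class": spec.class_id, "biomarker": name,
                "time_h": times, "replicate": rep, "value": base + noise,
            }))
    return pd.concat(rows, ignore_index=True)


def generate_invitro_expression(clock: ClockParams | None = None,
                                noise_sd: float = 0.05, seed: int = 0,
                                step_h: float = 2.0, duration_h: float = 48.0,
                                n_replicates: int = 1) -> pd.DataFrame:
    """Six-gene mRNA time series from the unforced clock limit cycle.

    Observation noise is multiplicative log-normal with log-sd
    ``noise_sd`` (approximately the coefficient of variation), the usual
    error structure of expression measurements.  Profiles are anchored
    at the Bmal1 mRNA peak (circadian time 0).
    """
    if clock is None:
        clock = reference_params()
    rng = np.random.default_rng(seed)
    traj = simulate(clock)
    fine = np.arange(0.0, 24.0, 0.25)
    prof, _period = limit_cycle(traj, grid=fine)
    times = np.arange(0.0, duration_h + 1e-9, step_h)
    rows = []
    for g in GENES:
        clean = np.interp(times % 24.0, fine, prof[g], period=24.0)
        for rep in range(1, n_replicates + 1):
            vals = clean * np.exp(rng.normal(0.0, noise_sd, size=len(times)))
            rows.append(pd.DataFrame({
                "gene": g, "time_h": times, "replicate": rep, "value": vals,
            }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class GroundTruth:
    """Known regulator model used to force the target gene's ODE."""

    target_gene: str
    hypothesis: str                      # "H1" (transcription) or "H2" (degradation)
    features: tuple[int, ...]            # indices into the 10-feature panel
    beta_true: dict[int, np.ndarray]     # class -> weights, one per feature
    noise_sd: float = 0.05               # log-sd of multiplicative noise (~CV)

    def __post_init__(self):
        self.target_gene = self.target_gene.lower()
        if self.target_gene not in ("bmal1", "per2", "reverb"):
            raise ValueError("target gene must be one of bmal1, per2, reverb")
        if self.hypothesis not in ("H1", "H2"):
            raise ValueError("hypothesis must be 'H1' or 'H2'")
        feats = tuple(int(j) for j in self.features)
        if len(feats) > 5:
            raise ValueError("at most 5 features")
        if len(set(feats)) != len(feats):
            raise ValueError("duplicate features")
        for j in feats:
            if not 0 <= j <= 9:
                raise ValueError("feature indices must lie in 0..9")
            if (j + 5 if j < 5 else j - 5) in feats:
                raise ValueError(
                    "a regulator and its integral regulator cannot both act")
        self.features = feats
        self.beta_true = {int(c): np.asarray(v, dtype=float)
                          for c, v in dict(self.beta_true).items()}
        for c, v in self.beta_true.items():
            if v.shape != (len(feats),):
                raise ValueError(f"class {c}: beta length != number of features")

    def to_json(self, path: str | Path) -> None:
        d = {"target_gene": self.target_gene, "hypothesis": self.hypothesis,
             "features": list(self.features),
             "beta_true": {str(c): v.tolist() for c, v in self.beta_true.items()},
             "noise_sd": self.noise_sd}
        Path(path).write_text(json.dumps(d, indent=1))


def generate_invivo_expression(truth: GroundTruth,
                               panels: Mapping[int, RegulatorPanel],
                               clock: ClockParams | None = None,
                               seed: int = 0, eps_scale: float = 0.3,
                               step_h: float = 2.0, duration_h: float = 24.0,
                               n_replicates: int = 3,
                               ) -> tuple[pd.DataFrame, dict]:
    """Clock-gene expression with the target gene forced per ground truth.

    The forcing multiplier is f(t) = 1 + eps_scale * s(t)/sd(s) with
    s(t) = sum_j beta_j zbar_j(t) over the class panel: the raw linear
    combination is centred/scaled so that the multiplier stays positive
    while remaining an affine image of the true signal.  The per-class
    scale sd(s) is returned so recovered weights can be mapped back to
    the ground-truth scale.  The target mRNA ODE is integrated with the
    modulators held on the unforced limit cycle (non-target genes follow
    the unforced model exactly).

    Returns (long table: class, gene, time_h, replicate, value; info dict
    with per-class forcing scale and minimum multiplier).
    """
    if clock is None:
        clock = reference_params()
    rng = np.random.default_rng(seed)
    traj = simulate(clock)
    fine = np.arange(0.0, 24.0, 0.25)
    prof, _period = limit_cycle(traj, grid=fine)
    gene = truth.target_gene
    alpha = clock[f"deg_{gene}"]
    vmax = clock[f"vmax_{gene}"]
    M = {m: prof[m] for m in ("rev_erb", "ror_p", "clock_bmal_n", "per_cry_n")}
    transc_fine = np.asarray(transcription_rate(gene, M, clock), dtype=float)

    times = np.arange(0.0, duration_h + 1e-9, step_h)
    rows = []
    info: dict = {"eps_scale": eps_scale, "classes": {}}
    for cid, panel in panels.items():
        beta = truth.beta_true[cid]
        s = panel.design(truth.features) @ beta
        scale = float(np.std(s))
        f_grid = np.ones_like(s) if scale == 0 else 1.0 + eps_scale * s / scale
        if np.min(f_grid) <= 0:
            raise ValueError(
                f"class {cid}: forcing multiplier non-positive "
                f"(min {np.min(f_grid):.3f}); reduce eps_scale")
        pg = panel.grid

        def f_of_t(t):
            return np.interp(t % 24.0, pg, f_grid, period=24.0)

        def transc_of_t(t):
            return np.interp(t % 24.0, fine, transc_fine, period=24.0)

        if truth.hypothesis == "H1":
            rhs = lambda t, x: f_of_t(t) * vmax * transc_of_t(t) - alpha * x
        else:
            rhs = lambda t, x: vmax * transc_of_t(t) - f_of_t(t) * alpha * x
        x0 = float(np.interp(0.0, fine, prof[gene]))
        sol = solve_ivp(rhs, (0.0, 264.0), [x0], method="LSODA",
                        t_eval=240.0 + np.arange(0.0, 24.0, 0.25),
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"forced integration failed: {sol.message}")
        forced = sol.y[0]
        info["classes"][cid] = {"scale": scale, "f_min": float(np.min(f_grid))}
        for g in ("bmal1", "per2", "reverb"):
            clean_fine = forced if g == gene else prof[g]
            clean = np.interp(times % 24.0, fine, clean_fine, period=24.0)
            for rep in range(1, n_replicates + 1):
                vals = clean * np.exp(rng.normal(0.0, truth.noise_sd,
                                                 size=len(times)))
                rows.append(pd.DataFrame({
                    "class": cid, "gene": g, "time_h": times,
                    "replicate": rep, "value": vals,
                }))
    return pd.concat(rows, ignore_index=True), info
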
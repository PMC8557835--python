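"""ODE model of the mammalian liver cellular circadian clock.

The model captures the canonical architecture of the peripheral clock:
the CLOCK/BMAL nuclear dimer activates transcription of *Rev-Erbα*,
*Rorγ*, *Per2* and *Cry1*; the PER/CRY complex inhibits that activation;
REV-ERB represses *Bmal1* and *Cry1*; ROR activates *Bmal1*.  Every mRNA
obeys

    dx/dt = Vmax * Transc(M, gamma) - alpha * x

with Hill-type transcription multipliers ``Transc`` driven by the
modulator species M = {REV-ERB, ROR, CLOCK/BMAL_N, PER/CRY_N}, constant
degradation ``alpha`` and basal transcription level ``Vmax``.  Proteins
are produced from their mRNAs, form complexes (CLOCK/BMAL in the
nucleus, PER/CRY via a cytoplasmic intermediate) and are degraded
linearly.  *Clock* mRNA is constitutive by default.

The module also provides rhythm metrics (period, relative amplitude,
phase), multi-start calibration against in vitro expression data, and a
variance-based (Sobol) sensitivity screen used to pick the parameters
that matter most for the modulator time profiles.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.stats import qmc

__all__ = [
    "GENES",
    "STATES",
    "MODULATORS",
    "ClockParams",
    "ClockTrajectory",
    "RhythmMetrics",
    "reference_params",
    "transcription_rate",
    "simulate",
    "limit_cycle",
    "rhythm_metrics",
    "fit_invitro",
    "sobol_first_order",
    "sobol_select",
    "default_sobol_set",
]

GENES = ("bmal1", "per2", "cry1", "reverb", "ror", "clock")

#: state ordering: six mRNAs then proteins/complexes
STATES = (
    "bmal1", "per2", "cry1", "reverb", "ror", "clock",
    "clock_c", "bmal_c", "clock_bmal_n",
    "per_c", "cry_c", "per_cry_c", "per_cry_n",
    "rev_erb", "ror_p",
)

#: modulator species entering the transcription multipliers
MODULATORS = ("rev_erb", "ror_p", "clock_bmal_n", "per_cry_n")

#: states exempt from rhythmicity criteria when Clock is constitutive
CONSTITUTIVE_STATES = ("clock",)

_IDX = {name: i for i, name in enumerate(STATES)}

# Reference parameter set, hand-tuned to oscillate with a ~24 h period
# and the antagonist phase structure expected of the liver clock
# (REV-ERB vs ROR and PER/CRY vs CLOCK/BMAL out of phase by > 6 h).
# Units: vmax_* conc/h, deg_* 1/h, K_* conc, hill coefficients
# dimensionless, protein production p_* 1/h (bilinear k_assoc 1/(conc h)).
_REFERENCE = {
    # transcription level and mRNA degradation, per gene
    "vmax_bmal1": 1.984, "deg_bmal1": 0.4961,
    "vmax_per2": 1.225, "deg_per2": 0.2681,
    "vmax_cry1": 0.919, "deg_cry1": 0.2298,
    "vmax_reverb": 1.532, "deg_reverb": 0.4978,
    "vmax_ror": 0.6892, "deg_ror": 0.0536,
    "vmax_clock": 0.6126, "deg_clock": 0.2298,
    # Bmal1 transcription: fold activation by ROR, repression by REV-ERB
    "fold_bmal1": 8.0, "K_ror_bmal1": 7.0, "h_ror_bmal1": 3.0,
    "K_rev_bmal1": 0.26, "h_rev_bmal1": 3.0,
    # CLOCK/BMAL-activated genes: fold, activation K and Hill,
    # PER/CRY repression K and Hill
    "fold_per2": 8.0, "K_cb_per2": 2.337, "h_cb_per2": 2.0,
    "K_pc_per2": 0.08221, "h_pc_per2": 4.0,
    "fold_cry1": 8.0, "K_cb_cry1": 2.337, "h_cb_cry1": 2.0,
    "K_pc_cry1": 0.08221, "h_pc_cry1": 4.0,
    "K_rev_cry1": 1.048, "h_rev_cry1": 2.0,
    "fold_reverb": 8.0, "K_cb_reverb": 2.337, "h_cb_reverb": 2.0,
    "K_pc_reverb": 0.08221, "h_pc_reverb": 4.0,
    "fold_ror": 8.0, "K_cb_ror": 2.337, "h_cb_ror": 2.0,
    "K_pc_ror": 0.08221, "h_pc_ror": 4.0,
    # protein production / transport / degradation
    "p_clock_c": 0.3064, "deg_clock_c": 0.7658,
    "p_bmal_c": 0.3064, "deg_bmal_c": 0.3064,
    "k_assoc": 0.02298, "deg_cb_n": 0.3829,
    "p_per": 0.3064, "deg_per_c": 0.1149,
    "p_cry": 0.3064, "deg_cry_c": 0.1149,
    "k_complex": 0.2298, "deg_pc_c": 0.07658, "k_pc_import": 0.1532,
    "deg_pc_n": 0.2298,
    "p_rev": 0.3829, "deg_rev": 0.4212,
    "p_ror": 0.2298, "deg_ror_p": 0.04595,
}

_HILL_NAMES = frozenset(n for n in _REFERENCE if n.startswith("h_"))

PARAM_NAMES = tuple(_REFERENCE)


class ClockParams(dict):
    """Named, strictly positive parameter vector of the clock model.

    Behaves as a ``dict`` (name -> value) with validation and JSON IO.
    Hill coefficients must be >= 1, everything else > 0.
    """

    def __init__(self, values: Mapping[str, float]):
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown clock parameters: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(values)
        if missing:
            raise ValueError(f"missing clock parameters: {sorted(missing)}")
        super().__init__({k: float(values[k]) for k in PARAM_NAMES})
        self.validate()

    def validate(self) -> None:
        for name, v in self.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {v}")
            if name in _HILL_NAMES and v < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1, got {v}")

    def replace(self, **updates: float) -> "ClockParams":
        d = dict(self)
        d.update(updates)
        return ClockParams(d)

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = PARAM_NAMES if names is None else names
        return np.array([self[n] for n in names], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, names: Sequence[str] | None = None,
                   base: "ClockParams | None" = None) -> "ClockParams":
        names = PARAM_NAMES if names is None else names
        d = dict(base) if base is not None else {}
        d.update(dict(zip(names, map(float, values))))
        return cls(d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockParams":
        return cls(json.loads(Path(path).read_text()))


def reference_params() -> ClockParams:
    """Hand-tuned reference parameter set (versioned fixture)."""
    return ClockParams(_REFERENCE)


def gene_kinetic_params(gene: str) -> tuple[str, ...]:
    """Names of Vmax, alpha and the Hill parameters of one gene's mRNA ODE."""
    gene = gene.lower()
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}")
    names = [f"vmax_{gene}", f"deg_{gene}"]
    if gene == "bmal1":
        names += ["fold_bmal1", "K_ror_bmal1", "h_ror_bmal1",
                  "K_rev_bmal1", "h_rev_bmal1"]
    elif gene in ("per2", "cry1", "reverb", "ror"):
        names += [f"fold_{gene}", f"K_cb_{gene}", f"h_cb_{gene}",
                  f"K_pc_{gene}", f"h_pc_{gene}"]
        if gene == "cry1":
            names += ["K_rev_cry1", "h_rev_cry1"]
    return tuple(names)


# ---------------------------------------------------------------------------
# transcription kinetics
# ---------------------------------------------------------------------------

def transcription_rate(gene: str, M: Mapping[str, float | np.ndarray],
                       params: Mapping[str, float]):
    """Dimensionless transcription multiplier Transc(M, gamma) of one gene.

    For *Bmal1*: activation by ROR with counter-inhibition by REV-ERB,

        (1 + g1 (ROR/g2)^g3) / (1 + (REV/g4)^g5 + (ROR/g2)^g3).

    For the CLOCK/BMAL-activated genes the same Hill family is used:
    activation by CLOCK/BMAL_N times a PER/CRY repression factor that
    inhibits the activated complex; *Cry1* carries an additional REV-ERB
    repression factor.  *Clock* is constitutive
    (multiplier 1).  Accepts scalars or arrays in ``M``.
    """
    gene = gene.lower()
    p = params
    for name in MODULATORS:
        if name in M and np.any(np.asarray(M[name]) < 0):
            raise ValueError(f"negative concentration for modulator {name}")
    if gene == "clock":
        shape = np.broadcast(*[np.asarray(M[m]) for m in M]).shape if M else ()
        return np.ones(shape) if shape else 1.0
    if gene == "bmal1":
        ror = np.asarray(M["ror_p"], dtype=float)
        rev = np.asarray(M["rev_erb"], dtype=float)
        u = (ror / p["K_ror_bmal1"]) ** p["h_ror_bmal1"]
        w = (rev / p["K_rev_bmal1"]) ** p["h_rev_bmal1"]
        out = (1.0 + p["fold_bmal1"] * u) / (1.0 + w + u)
        return float(out) if out.ndim == 0 else out
    if gene in ("per2", "cry1", "reverb", "ror"):
        cb = np.asarray(M["clock_bmal_n"], dtype=float)
        pc = np.asarray(M["per_cry_n"], dtype=float)
        u = (cb / p[f"K_cb_{gene}"]) ** p[f"h_cb_{gene}"]
        inh = 1.0 + (pc / p[f"K_pc_{gene}"]) ** p[f"h_pc_{gene}"]
        out = (1.0 + p[f"fold_{gene}"] * u) / ((1.0 + u) * inh)
        if gene == "cry1":
            rev = np.asarray(M["rev_erb"], dtype=float)
            out = out / (1.0 + (rev / p["K_rev_cry1"]) ** p["h_rev_cry1"])
        return float(out) if out.ndim == 0 else out
    raise ValueError(f"unknown gene {gene!r}")


def _make_rhs(p: Mapping[str, float],
              forcing: Callable[[float], float] | None = None,
              target_gene: str | None = None,
              hypothesis: str | None = None) -> Callable:
    """Build the ODE right-hand side; optionally force one gene's mRNA.

    Under H1 the forcing multiplies the target's transcription term,
    under H2 its degradation term.
    """
    i = _IDX
    if forcing is not None:
        target_gene = target_gene.lower()
        if target_gene not in GENES:
            raise ValueError(f"unknown target gene {target_gene!r}")
        if hypothesis not in ("H1", "H2"):
            raise ValueError("hypothesis must be 'H1' or 'H2'")

    # pre-extract every parameter into locals: the RHS is the hot path
    v_b, a_b = p["vmax_bmal1"], p["deg_bmal1"]
    v_p, a_p = p["vmax_per2"], p["deg_per2"]
    v_c, a_c = p["vmax_cry1"], p["deg_cry1"]
    v_r, a_r = p["vmax_reverb"], p["deg_reverb"]
    v_o, a_o = p["vmax_ror"], p["deg_ror"]
    v_k, a_k = p["vmax_clock"], p["deg_clock"]
    fb, Kor, hor = p["fold_bmal1"], p["K_ror_bmal1"], p["h_ror_bmal1"]
    Krv, hrv = p["K_rev_bmal1"], p["h_rev_bmal1"]
    act_par = tuple((p[f"fold_{g}"], p[f"K_cb_{g}"], p[f"h_cb_{g}"],
                     p[f"K_pc_{g}"], p[f"h_pc_{g}"])
                    for g in ("per2", "cry1", "reverb", "ror"))
    Krc, hrc = p["K_rev_cry1"], p["h_rev_cry1"]
    p_cc, d_cc = p["p_clock_c"], p["deg_clock_c"]
    p_bc, d_bc = p["p_bmal_c"], p["deg_bmal_c"]
    k_as, d_cb = p["k_assoc"], p["deg_cb_n"]
    p_pe, d_pe = p["p_per"], p["deg_per_c"]
    p_cr, d_cr = p["p_cry"], p["deg_cry_c"]
    k_cx, d_pcc, k_imp = p["k_complex"], p["deg_pc_c"], p["k_pc_import"]
    d_pcn = p["deg_pc_n"]
    p_rv, d_rv = p["p_rev"], p["deg_rev"]
    p_or, d_or = p["p_ror"], p["deg_ror_p"]
    h1 = hypothesis == "H1"
    tgt = {"bmal1": 0, "per2": 1, "cry1": 2, "reverb": 3,
           "ror": 4, "clock": 5}.get(target_gene, -1) if forcing else -1

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        s = np.maximum(s, 0.0)  # guard fractional powers near 0
        (x_b, x_p, x_c, x_r, x_o, x_k,
         cc, bc, cb, pe, cr, pcc, pcn, rev, ror) = s
        u_b = (ror / Kor) ** hor
        w_b = (rev / Krv) ** hrv
        T = [(1.0 + fb * u_b) / (1.0 + w_b + u_b), 0.0, 0.0, 0.0, 0.0, 1.0]
        for gi in (1, 2, 3, 4):
            F, Kcb, hcb, Kpc, hpc = act_par[gi - 1]
            u = (cb / Kcb) ** hcb
            T[gi] = (1.0 + F * u) / ((1.0 + u) * (1.0 + (pcn / Kpc) ** hpc))
        T[2] /= 1.0 + (rev / Krc) ** hrc
        prod = [v_b * T[0], v_p * T[1], v_c * T[2], v_r * T[3],
                v_o * T[4], v_k * T[5]]
        dec = [a_b * x_b, a_p * x_p, a_c * x_c, a_r * x_r, a_o * x_o, a_k * x_k]
        if tgt >= 0:
            f = forcing(t)
            if h1:
                prod[tgt] *= f
            else:
                dec[tgt] *= f
        assoc = k_as * cc * bc
        pc_form = k_cx * pe * cr
        return np.array([
            prod[0] - dec[0], prod[1] - dec[1], prod[2] - dec[2],
            prod[3] - dec[3], prod[4] - dec[4], prod[5] - dec[5],
            p_cc * x_k - d_cc * cc - assoc,
            p_bc * x_b - d_bc * bc - assoc,
            assoc - d_cb * cb,
            p_pe * x_p - d_pe * pe - pc_form,
            p_cr * x_c - d_cr * cr - pc_form,
            pc_form - (d_pcc + k_imp) * pcc,
            k_imp * pcc - d_pcn * pcn,
            p_rv * x_r - d_rv * rev,
            p_or * x_o - d_or * ror,
        ])

    return rhs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class ClockTrajectory:
    """Simulated clock time course after burn-in."""

    times: np.ndarray                 # h
    states: np.ndarray                # (len(times), len(STATES))
    state_names: tuple[str, ...] = STATES

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.times), len(self.state_names)):
            raise ValueError("states shape does not match times/state names")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def modulators(self) -> dict[str, np.ndarray]:
        return {m: self[m] for m in MODULATORS}

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "time_h", self.times)
        return df


_Y0 = np.full(len(STATES), 0.2)


def simulate(params: Mapping[str, float], t_span_h: float = 72.0,
             burn_in_h: float = 240.0, dt_out: float = 0.25,
             forcing: Callable[[float], float] | None = None,
             target_gene: str | None = None, hypothesis: str | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             y0: np.ndarray | None = None) -> ClockTrajectory:
    """Integrate the clock ODEs; discard ``burn_in_h`` and return the rest.

    Stiff-capable (LSODA).  Deterministic given parameters, grid and
    tolerances.  Output times are relative to the end of the burn-in.
    """
    rhs = _make_rhs(params, forcing, target_gene, hypothesis)
    t_out = np.arange(0.0, t_span_h + 1e-9, dt_out) + burn_in_h
    y0 = _Y0 if y0 is None else np.asarray(y0, dtype=float)
    sol = solve_ivp(rhs, (0.0, burn_in_h + t_span_h), y0, method="LSODA",
                    t_eval=t_out, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"clock integration failed: {sol.message}; params={dict(params)}")
    states = sol.y.T
    if not np.all(np.isfinite(states)) or np.nanmax(states) > 1e6:
        raise RuntimeError(f"clock integration diverged; params={dict(params)}")
    return ClockTrajectory(times=sol.t - burn_in_h, states=np.maximum(states, 0.0))


def limit_cycle(traj: ClockTrajectory, grid: np.ndarray | None = None,
                anchor: str = "bmal1") -> tuple[dict[str, np.ndarray], float]:
    """Extract one anchored cycle of every state, mapped to circadian time.

    Circadian time 0 is defined as the peak of the anchor variable
    (Bmal1 mRNA by default).  The last full cycle between successive
    anchor peaks is linearly rescaled onto ``grid`` in [0, 24) h.
    Returns (profiles, period_h).
    """
    if grid is None:
        grid = np.arange(0.0, 24.0, 1.0)
    x = traj[anchor]
    prominence = 0.05 * max(np.ptp(x), 1e-12)
    peaks, _ = find_peaks(x, prominence=prominence)
    if len(peaks) < 2:
        raise ValueError("fewer than two anchor peaks: no limit cycle to extract")
    t1, t2 = traj.times[peaks[-2]], traj.times[peaks[-1]]
    period = t2 - t1
    t_query = t1 + np.asarray(grid) / 24.0 * period
    profiles = {
        name: np.interp(t_query, traj.times, traj[name])
        for name in traj.state_names
    }
    return profiles, float(period)


# ---------------------------------------------------------------------------
# rhythm metrics
# ---------------------------------------------------------------------------

@dataclass
class RhythmMetrics:
    """Period / amplitude / phase summary of one oscillating variable."""

    period_h: float
    relative_amplitude: float   # (max - min) / mean over one period
    phase_h: float              # time of maximum within the last cycle
    circadian_mean: float
    rhythmic: bool = True


def rhythm_metrics(traj: ClockTrajectory, variable: str) -> RhythmMetrics:
    """Period from successive maxima, amplitude/phase on the last cycle.

    Non-oscillatory signals (relative amplitude < 1e-6 or fewer than two
    maxima) are flagged ``rhythmic=False`` with NaN period/phase.
    """
    x = traj[variable]
    t = traj.times
    mean_all = float(np.mean(x))
    span = float(np.ptp(x))
    if mean_all <= 0 or span / max(abs(mean_all), 1e-300) < 1e-6:
        return RhythmMetrics(np.nan, 0.0 if mean_all else np.nan, np.nan,
                             mean_all, rhythmic=False)
    peaks, _ = find_peaks(x, prominence=0.05 * span)
    if len(peaks) < 2:
        return RhythmMetrics(np.nan, span / mean_all, np.nan, mean_all,
                             rhythmic=False)
    period = float(np.mean(np.diff(t[peaks])))
    # last full cycle
    lo = t[peaks[-1]] - period
    mask = (t >= lo) & (t <= t[peaks[-1]])
    xc, tc = x[mask], t[mask]
    mean_c = float(np.mean(xc))
    rel_amp = float((xc.max() - xc.min()) / mean_c)
    # peak time on the shared simulation time axis, folded by the period
    phase = float(t[peaks[-1]] % period)
    return RhythmMetrics(period, rel_amp, phase, mean_c, rhythmic=True)


def circular_distance(a: float, b: float, period: float) -> float:
    """Shortest distance between two phases on a circle of given period."""
    d = abs(a - b) % period
    return min(d, period - d)


# ---------------------------------------------------------------------------
# in vitro calibration
# ---------------------------------------------------------------------------

_DEFAULT_FREE = tuple(f"vmax_{g}" for g in GENES) + tuple(f"deg_{g}" for g in GENES)


def _oscillates(params: ClockParams, period_band=(20.0, 28.0),
                min_rel_amp: float = 0.05, fast: bool = True) -> bool:
    try:
        traj = simulate(params, t_span_h=72.0, burn_in_h=120.0 if fast else 240.0,
                        rtol=1e-6, atol=1e-8)
    except RuntimeError:
        return False
    for g in GENES:
        if g in CONSTITUTIVE_STATES:
            continue
        m = rhythm_metrics(traj, g)
        if not m.rhythmic or not (period_band[0] <= m.period_h <= period_band[1]):
            return False
        if m.relative_amplitude <= min_rel_amp:
            return False
    return True


def fit_invitro(theta0: ClockParams, data, n_starts: int = 40,
                n_best: int = 10, free: Sequence[str] | None = None,
                seed: int = 0, spread: float = 3.0,
                max_nfev: int = 60) -> list[tuple[ClockParams, float]]:
    """Multi-start weighted least-squares calibration to in vitro data.

    ``data`` is a long table (columns gene, time_h, value; replicates
    allowed) of the six clock-gene mRNAs, assumed phase-anchored at the
    Bmal1 mRNA peak.  Optimization runs in log-parameter space over the
    ``free`` coordinates (per-gene Vmax and degradation rates by
    default), starting from log-uniform draws within a factor ``spread``
    of ``theta0``.  Returns the ``n_best`` oscillatory fits sorted by
    cost, as (params, cost) pairs.
    """
    import pandas as pd

    if n_starts < n_best:
        raise ValueError("n_starts must be >= n_best")
    free = list(_DEFAULT_FREE) if free is None else list(free)
    df = pd.DataFrame(data)
    obs = {g: (sub["time_h"].to_numpy(float), sub["value"].to_numpy(float))
           for g, sub in df.groupby("gene")}
    scales = {g: max(float(np.mean(v)), 1e-12) for g, (_, v) in obs.items()}
    rng = np.random.default_rng(seed)
    log0 = np.log(theta0.as_array(free))

    def residual_vec(logx: np.ndarray) -> np.ndarray:
        params = ClockParams.from_array(np.exp(logx), free, base=theta0)
        try:
            traj = simulate(params, t_span_h=72.0, burn_in_h=120.0,
                            rtol=1e-6, atol=1e-8)
            grid = np.arange(0.0, 24.0, 0.5)
            prof, _ = limit_cycle(traj, grid=grid)
        except (RuntimeError, ValueError):
            return np.full(sum(len(t) for t, _ in obs.values()), 1e3)
        res = []
        for g, (t, v) in obs.items():
            sim = np.interp(np.asarray(t) % 24.0, grid, prof[g], period=24.0)
            res.append((sim - v) / scales[g])
        return np.concatenate(res)

    fits: list[tuple[ClockParams, float]] = []
    for k in range(n_starts):
        start = log0 if k == 0 else log0 + rng.uniform(
            -np.log(spread), np.log(spread), size=len(free))
        try:
            sol = least_squares(residual_vec, start, method="trf",
                                bounds=(log0 - np.log(10.0), log0 + np.log(10.0)),
                                max_nfev=max_nfev, diff_step=1e-4)
        except Exception:
            continue
        params = ClockParams.from_array(np.exp(sol.x), free, base=theta0)
        cost = float(np.mean(sol.fun ** 2))
        if _oscillates(params):
            fits.append((params, cost))
    fits.sort(key=lambda pc: pc[1])
    if len(fits) < n_best:
        raise RuntimeError(
            f"only {len(fits)} oscillatory optima found (need {n_best}); "
            "increase n_starts")
    return fits[:n_best]


# ---------------------------------------------------------------------------
# Sobol sensitivity screen
# ---------------------------------------------------------------------------

def sobol_first_order(func: Callable[[np.ndarray], np.ndarray],
                      bounds: np.ndarray, n_samples: int = 256,
                      seed: int = 0) -> np.ndarray:
    """First-order Sobol indices by the Saltelli pick-freeze estimator.

    ``func`` maps a parameter vector to an output vector; ``bounds`` is
    (d, 2).  Uses two scrambled Sobol matrices A, B and the radial
    design A_B^(i); S1_i = mean(f_B (f_ABi - f_A)) / Var.  Samples whose
    output contains NaN are dropped pairwise.  Returns (d, n_out).
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    base = sampler.random(n_samples)
    A = qmc.scale(base[:, :d], bounds[:, 0], bounds[:, 1])
    B = qmc.scale(base[:, d:], bounds[:, 0], bounds[:, 1])
    fA = np.array([func(x) for x in A], dtype=float)
    fB = np.array([func(x) for x in B], dtype=float)
    n_out = fA.shape[1]
    S1 = np.zeros((d, n_out))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.array([func(x) for x in ABi], dtype=float)
        for j in range(n_out):
            ok = np.isfinite(fA[:, j]) & np.isfinite(fB[:, j]) & np.isfinite(fABi[:, j])
            if ok.sum() < 8:
                S1[i, j] = np.nan
                continue
            allf = np.concatenate([fA[ok, j], fB[ok, j]])
            var = np.var(allf)
            if var <= 0:
                S1[i, j] = 0.0
                continue
            S1[i, j] = np.mean(fB[ok, j] * (fABi[ok, j] - fA[ok, j])) / var
    return S1


_CHARACTERISTICS = ("mean", "amplitude", "phase")


def _modulator_outputs(theta_vec: np.ndarray, names: Sequence[str],
                       base: ClockParams) -> np.ndarray:
    """12-vector: (mean, amplitude, phase) of each modulator species."""
    try:
        params = ClockParams.from_array(theta_vec, names, base=base)
        traj = simulate(params, t_span_h=72.0, burn_in_h=120.0,
                        rtol=1e-6, atol=1e-8)
    except (ValueError, RuntimeError):
        return np.full(len(MODULATORS) * len(_CHARACTERISTICS), np.nan)
    out = []
    for m in MODULATORS:
        met = rhythm_metrics(traj, m)
        if not met.rhythmic:
            out += [np.nan] * 3
        else:
            out += [met.circadian_mean, met.relative_amplitude, met.phase_h]
    return np.array(out)


def sobol_select(theta: ClockParams, candidates: Sequence[str] | None = None,
                 n_samples: int = 256, seed: int = 0, target_size: int = 5,
                 rel_bounds: float = 0.5) -> dict:
    """Pick the parameters that dominate the modulator time profiles.

    For every modulator m and characteristic l in {circadian mean,
    relative amplitude, phase}, first-order Sobol indices are computed
    over a +/-``rel_bounds`` hypercube around ``theta``.  P_{m,l} is the
    set of the p largest-index parameters; the returned set is the
    intersection over all (m, l), with p raised until the intersection
    reaches ``target_size`` (or the largest p keeping it below).

    Returns a dict with keys ``selected`` (parameter names), ``p``,
    ``indices`` (parameter x output matrix) and ``outputs`` labels.
    """
    names = list(PARAM_NAMES) if candidates is None else list(candidates)
    vec = theta.as_array(names)
    bounds = np.stack([vec * (1 - rel_bounds), vec * (1 + rel_bounds)], axis=1)
    # keep Hill coefficients >= 1
    for i, n in enumerate(names):
        if n in _HILL_NAMES:
            bounds[i, 0] = max(bounds[i, 0], 1.0)
    S1 = sobol_first_order(
        lambda x: _modulator_outputs(x, names, theta), bounds,
        n_samples=n_samples, seed=seed)
    labels = [f"{m}:{c}" for m in MODULATORS for c in _CHARACTERISTICS]
    order = np.argsort(-np.nan_to_num(S1, nan=-np.inf), axis=0)  # per output
    best: tuple[list[str], int] | None = None
    for p in range(1, len(names) + 1):
        sel = set(names)
        for j in range(S1.shape[1]):
            sel &= {names[k] for k in order[:p, j]}
        if len(sel) <= target_size:
            best = (sorted(sel), p)
        if len(sel) >= target_size:
            break
    if best is None or len(best[0]) < target_size:
        warnings.warn(
            "Sobol intersection never reached the target size; returning the "
            "largest achievable set")
        if best is None:
            best = ([], 0)
    return {"selected": best[0], "p": best[1], "indices": S1,
            "outputs": labels, "parameters": names}


def default_sobol_set() -> list[str]:
    """Precomputed Sobol parameter set for the reference clock (fixture)."""
    path = Path(__file__).parent / "data" / "sobol_set.json"
    return json.loads(path.read_text())["selected"]
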
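"""End-to-end orchestration: synth -> preprocess -> calibrate -> residuals
-> model search -> class statistics, with one config and one seed.

Every stage writes its outputs under the run directory; a manifest
records the configuration, the per-stage seeds (derived from the master
seed by stable name hashing) and SHA-256 hashes of every output file,
so a rerun with the same config and seed is bit-identical.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, class_stats, clock_model, model_search, preprocess
from . import residuals as resid_mod
from . import synthetic_data as synth

log = logging.getLogger("circlock")

__all__ = ["DEFAULT_CONFIG", "stage_seed", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "grid_n": 24,
    "n_trajectories": 50,
    "sigma": 10.0,
    "hypotheses": ["H1", "H2"],
    "threshold": 0.15,
    "eps_scale": 0.3,
    "gp_restarts": 2,
    "calibration": {"enabled": False, "n_starts": 12, "n_best": 10},
    "truth": {
        "target_gene": "bmal1",
        "hypothesis": "H1",
        "features": [6, 2],          # integral temperature + food intake
        "beta": {"1": [1.0, -0.6], "2": [0.8, -0.8],
                 "3": [-0.9, 0.7], "4": [-0.7, 0.9]},
        "noise_sd": 0.05,
    },
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by name hashing."""
    return (int(master_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: Mapping | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: Mapping | None = None, out_dir: str | Path = "run",
                 seed: int = 0) -> dict:
    """Execute the full inference pipeline on synthetic data.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
        return p

    def save_json(obj, name: str) -> Path:
        p = out / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        written.append(p)
        return p

    grid = preprocess.default_grid(cfg["grid_n"])

    # 1. synthetic biomarkers
    log.info("stage synth: generating biomarkers for 4 classes")
    specs = synth.default_class_specs()
    bio = pd.concat(
        [synth.generate_biomarkers(spec, seed=stage_seed(seed, f"synth{cid}"))
         for cid, spec in specs.items()], ignore_index=True)
    save_csv(bio, "biomarkers.csv")

    # 2. preprocessing into panels
    log.info("stage preprocess: GP smoothing and panel construction")
    panels = {}
    cosinor_rows = []
    for cid, sub in bio.groupby("class"):
        smooth = {}
        for bm, ss in sub.groupby("biomarker"):
            fit = preprocess.cosinor_test(ss["time_h"], ss["value"])
            cosinor_rows.append({"class": cid, "biomarker": bm,
                                 "mesor": fit.mesor, "amplitude": fit.amplitude,
                                 "acrophase_h": fit.acrophase_h, "p": fit.p_value})
            smooth[bm] = preprocess.fit_periodic_gp(
                ss["time_h"].to_numpy(), ss["value"].to_numpy(), grid=grid,
                n_restarts=cfg["gp_restarts"],
                seed=stage_seed(seed, f"gp{cid}{bm}"), label=bm)
        panels[cid] = preprocess.build_panel(smooth, class_id=cid)
        panels[cid].to_csv(out / f"panel_class{cid}.csv")
        written += [out / f"panel_class{cid}.csv", out / f"panel_class{cid}.csv.json"]
    save_csv(pd.DataFrame(cosinor_rows), "cosinor.csv")

    # 3. calibration (multi-start in vitro fit) or the reference clock
    theta_ref = clock_model.reference_params()
    if cfg["calibration"]["enabled"]:
        log.info("stage calibrate: multi-start in vitro fitting")
        vitro = synth.generate_invitro_expression(
            theta_ref, seed=stage_seed(seed, "invitro"))
        save_csv(vitro, "invitro_expression.csv")
        fits = clock_model.fit_invitro(
            theta_ref, vitro, n_starts=cfg["calibration"]["n_starts"],
            n_best=cfg["calibration"]["n_best"],
            seed=stage_seed(seed, "calibrate"))
        base_thetas = [p for p, _c in fits]
        save_json([dict(p) for p in base_thetas], "calibrated_params.json")
    else:
        base_thetas = [theta_ref]

    # 4. in vivo expression under the ground-truth regulator model
    log.info("stage invivo: forced expression generation")
    tcfg = cfg["truth"]
    truth = synth.GroundTruth(
        target_gene=tcfg["target_gene"], hypothesis=tcfg["hypothesis"],
        features=tuple(tcfg["features"]),
        beta_true={int(c): np.asarray(v, float)
                   for c, v in tcfg["beta"].items()},
        noise_sd=tcfg["noise_sd"])
    expr, force_info = synth.generate_invivo_expression(
        truth, panels, clock=theta_ref, seed=stage_seed(seed, "invivo"),
        eps_scale=cfg["eps_scale"])
    save_csv(expr, "invivo_expression.csv")
    save_json({"truth": {"target_gene": truth.target_gene,
                         "hypothesis": truth.hypothesis,
                         "features": list(truth.features),
                         "beta_true": {c: v.tolist()
                                       for c, v in truth.beta_true.items()},
                         "noise_sd": truth.noise_sd},
               "forcing": force_info}, "ground_truth.json")

    # 5. smooth the target gene's expression per class
    gene = truth.target_gene
    x_by_class = {}
    for cid, sub in expr[expr["gene"] == gene].groupby("class"):
        ss = preprocess.fit_periodic_gp(
            sub["time_h"].to_numpy(), sub["value"].to_numpy(), grid=grid,
            n_restarts=cfg["gp_restarts"], log_space=True,
            seed=stage_seed(seed, f"gpx{cid}"), label=gene)
        x_by_class[cid] = ss.mean

    # 6. residual ensembles + 7. model search, per hypothesis
    results = {}
    pspec = resid_mod.PerturbationSpec(sigma=cfg["sigma"],
                                       n=cfg["n_trajectories"])
    for hyp in cfg["hypotheses"]:
        log.info("stage residuals: gene=%s hypothesis=%s n=%d",
                 gene, hyp, pspec.n)
        ens = resid_mod.generate_ensemble(
            gene, hyp, x_by_class, grid, base_thetas, pspec,
            seed=stage_seed(seed, f"resid{hyp}"))
        rows = []
        for cid, trajs in ens.items():
            for k, t in enumerate(trajs):
                rows.append(pd.DataFrame({
                    "class": cid, "trajectory_id": k,
                    "time_h": t.grid, "y": t.values}))
        save_csv(pd.concat(rows, ignore_index=True),
                 f"residuals_{gene}_{hyp}.csv")
        screen = model_search.screen_hypothesis(
            panels, ens, threshold=cfg["threshold"])
        results[hyp] = {"screen": {
            "verdict": screen["verdict"], "elbow_size": screen["elbow_size"],
            "E_at_elbow": screen["E_at_elbow"],
            "best_by_size": {r: {"subset": list(v["subset"]), "E": v["E"]}
                             for r, v in screen["best_by_size"].items()}}}
        if hyp == truth.hypothesis:
            shap = model_search.shapley_pipeline(panels, ens, gene)
            save_csv(shap.to_frame(), f"shapley_{gene}_{hyp}.csv")
            best2 = screen["best_by_size"][2]["subset"]
            betas = {}
            for cid, trajs in ens.items():
                Y = np.vstack([t.values for t in trajs])
                X = panels[cid].values[: Y.shape[1]]
                b, _ = model_search.fit_many(best2, X, Y)
                betas[cid] = b
            wf = class_stats.weight_frame(best2, betas)
            save_csv(wf, f"weights_{gene}_{hyp}.csv")
            anova = class_stats.anova_weights(wf)
            save_csv(anova, f"anova_{gene}_{hyp}.csv")
            refit = class_stats.constrained_refit(best2, panels, ens)
            results[hyp]["best2"] = {
                "subset": list(best2),
                "dominant": model_search.dominant_term(best2, betas),
                "cv": model_search.cv_check(best2, panels, ens,
                                            seed=stage_seed(seed, "cv")),
                "constrained_ratio": refit["ratio"],
            }
    save_json(results, "results.json")

    manifest = {
        "version": __version__, "seed": seed, "config": cfg,
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
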
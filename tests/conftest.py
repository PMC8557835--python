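import numpy as np
import pytest

from circlock import clock_model as cm
from circlock import preprocess as pp
from circlock import synthetic_data as sd


@pytest.fixture(scope="session")
def grid24():
    return pp.default_grid(24)


@pytest.fixture(scope="session")
def reference_traj():
    """One long simulation of the reference clock (shared, read-only)."""
    return cm.simulate(cm.reference_params(), t_span_h=120.0)


@pytest.fixture(scope="session")
def reference_cycle(reference_traj, grid24):
    """Anchored limit-cycle profiles of the reference clock on the grid."""
    prof, period = cm.limit_cycle(reference_traj, grid=grid24)
    return prof, period


@pytest.fixture(scope="session")
def panels(grid24):
    """GP-smoothed regulator panels for the four default classes."""
    specs = sd.default_class_specs()
    out = {}
    for cid, spec in specs.items():
        bio = sd.generate_biomarkers(spec, seed=100 + cid)
        smooth = {
            bm: pp.fit_periodic_gp(sub["time_h"].to_numpy(),
                                   sub["value"].to_numpy(), grid=grid24,
                                   n_restarts=2, seed=cid, label=bm)
            for bm, sub in bio.groupby("biomarker")
        }
        out[cid] = pp.build_panel(smooth, class_id=cid)
    return out


@pytest.fixture(scope="session")
def ground_truth():
    """Known 2-feature transcription-forcing model used across tests."""
    return sd.GroundTruth(
        target_gene="bmal1", hypothesis="H1", features=(6, 2),
        beta_true={1: [1.0, -0.6], 2: [0.8, -0.8],
                   3: [-0.9, 0.7], 4: [-0.7, 0.9]},
        noise_sd=0.05)


@pytest.fixture(scope="session")
def smoothed_invivo(panels, ground_truth, grid24):
    """Forced in vivo expression, GP-smoothed per class (target gene)."""
    expr, info = sd.generate_invivo_expression(
        ground_truth, panels, seed=7)
    x_by_class = {}
    gene = ground_truth.target_gene
    for cid, sub in expr[expr["gene"] == gene].groupby("class"):
        ss = pp.fit_periodic_gp(sub["time_h"].to_numpy(),
                                sub["value"].to_numpy(), grid=grid24,
                                n_restarts=5, seed=cid, log_space=True)
        x_by_class[cid] = ss.mean
    return x_by_class, info
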
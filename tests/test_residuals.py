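import numpy as np
import pytest

from circlock import clock_model as cm
from circlock import preprocess as pp
from circlock import residuals as rmod


@pytest.fixture(scope="module")
def theta():
    return cm.reference_params()


class TestPerturbParams:
    def test_zero_scale_is_identity(self, theta):
        rng = np.random.default_rng(0)
        out = rmod.perturb_params(theta, list(theta), 0.0, rng)
        assert out == theta

    def test_unselected_coordinates_untouched(self, theta):
        rng = np.random.default_rng(0)
        out = rmod.perturb_params(theta, ["vmax_bmal1"], 0.2, rng)
        changed = {k for k in theta if out[k] != theta[k]}
        assert changed == {"vmax_bmal1"}

    def test_results_remain_admissible(self, theta):
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = rmod.perturb_params(theta, list(theta), 0.5, rng)
            out.validate()

    def test_empirical_sd_matches_noise_law(self, theta):
        rng = np.random.default_rng(2)
        draws = np.array([rmod.perturb_params(theta, ["vmax_per2"], 0.1, rng)["vmax_per2"]
                          for _ in range(4000)])
        target = theta["vmax_per2"] * 0.1
        assert np.std(draws - theta["vmax_per2"]) == pytest.approx(target, rel=0.05)


def _cosine_traj(phases: dict, t_end=96.0):
    t = np.arange(0.0, t_end, 0.25)
    cols = []
    for i, name in enumerate(cm.STATES):
        ph = phases.get(name, (3 * i) % 24)
        cols.append(2.0 + np.cos(2 * np.pi * (t - ph) / 24.0))
    return cm.ClockTrajectory(times=t, states=np.column_stack(cols))


class TestAcceptClock:
    def test_reference_model_accepted(self, reference_traj):
        ok, diag = rmod.accept_clock(reference_traj)
        assert ok, diag["failures"]

    def test_damped_clock_rejected_on_amplitude(self, theta):
        damped = theta.replace(**{f"deg_{g}": theta[f"deg_{g}"] * 10
                                  for g in cm.GENES})
        traj = cm.simulate(damped, t_span_h=96.0)
        ok, diag = rmod.accept_clock(traj)
        assert not ok
        assert any("amplitude" in reason or "non-rhythmic" in reason
                   for _v, reason in diag["failures"])

    def test_exactly_six_hour_antagonist_separation_rejected(self):
        # strict inequality: equality at the threshold must fail
        traj = _cosine_traj({"rev_erb": 0.0, "ror_p": 6.0,
                             "per_cry_n": 0.0, "clock_bmal_n": 12.0})
        ok, diag = rmod.accept_clock(traj)
        assert not ok
        assert any("rev_erb/ror_p" in v for v, _r in diag["failures"])

    def test_seven_hour_separation_on_both_pairs_accepted(self):
        traj = _cosine_traj({"rev_erb": 0.0, "ror_p": 7.0,
                             "per_cry_n": 2.0, "clock_bmal_n": 12.0})
        ok, diag = rmod.accept_clock(traj)
        assert ok, diag["failures"]


class TestResidualH1:
    def test_self_consistency_recovers_vmax_for_every_gene(self, theta,
                                                           reference_traj):
        # inverting the unforced model's own output must return the
        # constant Vmax, up to discretization error
        for n, tol in ((24, 0.05), (48, 0.015)):
            grid = pp.default_grid(n)
            prof, _ = cm.limit_cycle(reference_traj, grid=grid)
            M = {m: prof[m] for m in cm.MODULATORS}
            for g in cm.GENES:
                r = rmod.residual_h1(g, prof[g], grid, M, theta,
                                     standardize=False)
                rel = np.abs(r.raw - theta[f"vmax_{g}"]) / theta[f"vmax_{g}"]
                assert np.max(rel) < tol, (g, n)

    def test_zero_degradation_constant_input_gives_zero(self, theta, grid24):
        tiny = theta.replace(deg_bmal1=1e-12)
        M = {m: np.full(24, 0.5) for m in cm.MODULATORS}
        r = rmod.residual_h1("bmal1", np.full(24, 3.0), grid24, M, tiny,
                             standardize=False)
        assert np.allclose(r.raw, 0.0, atol=1e-9)

    def test_learning_sample_count_is_grid_minus_one(self, theta, grid24,
                                                     reference_cycle):
        prof, _ = reference_cycle
        M = {m: prof[m] for m in cm.MODULATORS}
        r = rmod.residual_h1("bmal1", prof["bmal1"], grid24, M, theta)
        assert len(r.values) == len(grid24) - 1

    def test_standardized_output(self, theta, grid24, reference_cycle):
        prof, _ = reference_cycle
        M = {m: prof[m] for m in cm.MODULATORS}
        r = rmod.residual_h1("per2", prof["per2"], grid24, M, theta)
        assert abs(r.values.mean()) < 1e-10
        assert abs(r.values.std() - 1) < 1e-10


class TestResidualH2:
    def test_steady_state_returns_degradation_rate(self, theta, grid24):
        M = {m: np.full(24, 0.4) for m in cm.MODULATORS}
        transc = cm.transcription_rate("per2", {k: v[0] for k, v in M.items()},
                                       theta)
        x_ss = theta["vmax_per2"] * transc / theta["deg_per2"]
        r = rmod.residual_h2("per2", np.full(24, x_ss), grid24, M, theta,
                             standardize=False)
        assert np.allclose(r.raw, theta["deg_per2"], rtol=1e-10)

    def test_zero_mrna_rejected(self, theta, grid24):
        M = {m: np.full(24, 0.4) for m in cm.MODULATORS}
        with pytest.raises(ValueError, match="zero mRNA"):
            rmod.residual_h2("per2", np.zeros(24), grid24, M, theta)

    def test_slope_sign_flip_mirrors_residual(self, theta, grid24):
        M = {m: np.full(24, 0.4) for m in cm.MODULATORS}
        x_up = 2.0 + 0.5 * grid24 / 24.0
        x_dn = 2.0 + 0.5 * (24.0 - grid24) / 24.0
        r_up = rmod.residual_h2("per2", x_up, grid24, M, theta, standardize=False)
        r_dn = rmod.residual_h2("per2", x_dn, grid24, M, theta, standardize=False)
        transc = cm.transcription_rate("per2", {k: v[:1] for k, v in M.items()}, theta)
        centre_up = theta["vmax_per2"] * transc / (0.5 * (x_up[:-1] + x_up[1:]))
        centre_dn = theta["vmax_per2"] * transc / (0.5 * (x_dn[:-1] + x_dn[1:]))
        # the slope term flips the residual around Vmax*Transc/x
        assert np.all(r_up.raw < centre_up)
        assert np.all(r_dn.raw > centre_dn)

    def test_degradation_residuals_spikier_than_transcription(
            self, theta, grid24, smoothed_invivo):
        x_by_class, _ = smoothed_invivo
        prof, _ = cm.limit_cycle(cm.simulate(theta), grid=grid24)
        M = {m: prof[m] for m in cm.MODULATORS}
        cv = {}
        for hyp, fn in (("H1", rmod.residual_h1), ("H2", rmod.residual_h2)):
            vals = [fn("bmal1", x, grid24, M, theta, standardize=False).raw
                    for x in x_by_class.values()]
            v = np.concatenate(vals)
            cv[hyp] = np.std(v) / abs(np.mean(v))
        assert cv["H2"] > cv["H1"]


class TestFiniteDifference:
    def test_forward_difference_converges_to_derivative(self):
        errs = []
        for n in (24, 48):
            t = np.arange(n) * 24.0 / n
            x = 2.0 + np.cos(2 * np.pi * t / 24.0)
            fd = rmod._finite_diff(x, t)
            mid = t[:-1] + np.diff(t) / 2
            exact = -2 * np.pi / 24.0 * np.sin(2 * np.pi * mid / 24.0)
            errs.append(np.max(np.abs(fd - exact)))
        assert errs[0] < 0.02
        assert errs[1] < errs[0] / 3  # second-order at the midpoint


class TestEnsemble:
    def test_reproducible_and_standardized(self, theta, grid24, reference_cycle):
        prof, _ = reference_cycle
        x_by_class = {1: prof["bmal1"], 2: prof["bmal1"] * 1.1}
        spec = rmod.PerturbationSpec(n=5)
        a = rmod.generate_ensemble("bmal1", "H1", x_by_class, grid24, [theta],
                                   spec, seed=3)
        b = rmod.generate_ensemble("bmal1", "H1", x_by_class, grid24, [theta],
                                   spec, seed=3)
        for cid in x_by_class:
            assert len(a[cid]) == 5
            for ra, rb in zip(a[cid], b[cid]):
                assert np.array_equal(ra.values, rb.values)
                assert abs(ra.values.mean()) < 1e-10
                assert abs(ra.values.std() - 1) < 1e-10

    def test_accepted_provenance_passes_filter_when_resimulated(
            self, theta, grid24, reference_cycle):
        prof, _ = reference_cycle
        spec = rmod.PerturbationSpec(n=2)
        ens = rmod.generate_ensemble("bmal1", "H1", {1: prof["bmal1"]}, grid24,
                                     [theta], spec, seed=8)
        for r in ens[1]:
            traj = cm.simulate(cm.ClockParams(r.provenance["theta"]))
            ok, diag = rmod.accept_clock(traj, spec)
            assert ok, diag["failures"]

    def test_zero_sigma_yields_identical_trajectories(self, grid24, theta,
                                                      reference_cycle):
        prof, _ = reference_cycle
        spec = rmod.PerturbationSpec(sigma=np.inf, n=3)
        assert spec.sigma_eff == 0.0
        ens = rmod.generate_ensemble("bmal1", "H1", {1: prof["bmal1"]}, grid24,
                                     [theta], spec, seed=0)
        first = ens[1][0].values
        for r in ens[1][1:]:
            assert np.array_equal(r.values, first)


class TestPerturbationSpec:
    def test_sigma_interpretation(self):
        spec = rmod.PerturbationSpec(sigma=10.0)
        assert spec.sigma_eff == pytest.approx(0.1)
        literal = rmod.PerturbationSpec(sigma=10.0, literal=True)
        assert literal.sigma_eff == 10.0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            rmod.PerturbationSpec(n=0)
        with pytest.raises(ValueError):
            rmod.PerturbationSpec(min_rel_amp=0.0)
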
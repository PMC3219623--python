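"""Bilinear DCM forward model: neural flow, balloon hemodynamics, BOLD
observation, integration, and dataset simulation."""

import numpy as np
import pytest

from designrisk.dcm import (
    STATES_PER_REGION,
    Dataset,
    DCMSpec,
    DesignSpec,
    HemodynamicParams,
    bold_observation,
    dcm_as_nonlinear_gaussian,
    forward_bold,
    hemodynamic_flow,
    integrate_dcm,
    neural_flow,
    simulate_dataset,
)
from designrisk.models import laplace_predictive


def two_region_chain(a21=0.5, a12=0.0, free=()):
    return DCMSpec(
        A=np.array([[-1.0, a12], [a21, -1.0]]),
        B=[np.zeros((2, 2))],
        C=np.array([[1.0], [0.0]]),
        free_parameters=list(free),
        name="chain",
    )


def box_design(on=10.0, off=30.0, total=60.0, dt=0.1, tr=2.0):
    T = int(round(total / dt))
    u = np.zeros((1, T))
    u[0, int(round(on / dt)): int(round(off / dt))] = 1.0
    return DesignSpec(u=u, dt=dt, tr=tr)


REST = np.array([0.0, 1.0, 1.0, 1.0])  # s, f, v, q


class TestNeuralFlow:
    def test_origin_is_fixed_point(self):
        spec = two_region_chain()
        np.testing.assert_allclose(
            neural_flow(np.zeros(2), np.zeros(1), spec), 0.0, atol=1e-14
        )

    def test_driving_input_enters_targeted_region_only(self):
        spec = two_region_chain()
        dx = neural_flow(np.zeros(2), np.ones(1), spec)
        assert dx[0] != 0.0 and dx[1] == 0.0

    def test_bilinear_term_identity(self, rng):
        """flow(x, u=1) - flow(x, u=0) = B1 x + C for nonzero B1."""
        B1 = np.array([[0.0, 0.0], [0.3, 0.0]])
        spec = DCMSpec(A=np.array([[-1.0, 0.0], [0.4, -1.0]]), B=[B1],
                       C=np.array([[1.0], [0.0]]), name="bilinear")
        x = rng.standard_normal(2)
        diff = neural_flow(x, np.ones(1), spec) - neural_flow(x, np.zeros(1), spec)
        np.testing.assert_allclose(diff, B1 @ x + spec.C[:, 0], atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            neural_flow(np.zeros(3), np.zeros(1), two_region_chain())


class TestHemodynamics:
    def test_rest_is_fixed_point(self):
        d = hemodynamic_flow(REST, 0.0, HemodynamicParams())
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_sustained_neural_input_raises_inflow(self):
        h = HemodynamicParams()
        d = hemodynamic_flow(REST, 1.0, h)
        assert d[0] > 0  # vasodilatory signal rises first
        # one small Euler step later, inflow increases
        state = REST + 0.1 * d
        assert hemodynamic_flow(state, 1.0, h)[1] > 0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hemodynamic_flow(np.array([0.0, 1.0, -0.1, 1.0]), 0.0,
                             HemodynamicParams())

    def test_return_to_rest_after_stimulus(self):
        """All states within 1% of rest 60 s after input offset."""
        spec = two_region_chain()
        design = box_design(on=5.0, off=21.0, total=85.0)
        path = integrate_dcm(spec, design)
        final = path.trajectory[:, -1]
        rest = np.tile([0.0, 0.0, 1.0, 1.0, 1.0], 2)
        assert np.abs(final - rest).max() < 0.01


class TestBoldObservation:
    def test_rest_reads_zero(self):
        assert bold_observation(REST, HemodynamicParams()) == pytest.approx(0.0)

    def test_lower_dhb_gives_positive_signal(self):
        state = np.array([0.0, 1.0, 1.0, 0.9])
        assert bold_observation(state, HemodynamicParams()) > 0

    def test_response_peak_delayed_after_onset(self):
        """Hemodynamic delay: the BOLD peak trails the 16 s input block
        onset by several seconds."""
        spec = two_region_chain()
        design = box_design(on=10.0, off=26.0, total=70.0, tr=0.5)
        y = forward_bold(spec, design)
        t_peak = design.scan_indices[np.argmax(y[0])] * design.dt
        assert t_peak > 12.0  # well after onset


class TestIntegration:
    def test_zero_input_stays_at_rest(self):
        spec = two_region_chain()
        T = 300
        design = DesignSpec(u=np.zeros((1, T)), dt=0.1, tr=2.0)
        path = integrate_dcm(spec, design)
        rest = np.tile([0.0, 0.0, 1.0, 1.0, 1.0], 2)
        assert np.abs(path.trajectory - rest[:, None]).max() < 1e-12

    def test_five_states_per_region(self):
        spec = two_region_chain()
        path = integrate_dcm(spec, box_design())
        assert path.trajectory.shape[0] == STATES_PER_REGION * 2

    def test_self_convergence_on_dt_halving(self):
        """Halving dt changes the BOLD output by < 0.1% RMS."""
        spec = two_region_chain()

        def run(dt):
            T = int(round(60.0 / dt))
            u = np.zeros((1, T))
            u[0, int(10 / dt): int(26 / dt)] = 1.0
            return forward_bold(spec, DesignSpec(u=u, dt=dt, tr=2.0))

        y1, y2 = run(0.1), run(0.05)
        rms_change = np.sqrt(np.mean((y1 - y2) ** 2)) / np.sqrt(np.mean(y2**2))
        assert rms_change < 1e-3

    def test_downstream_region_lags_driven_region(self):
        spec = two_region_chain(a21=0.6)
        design = box_design(on=5.0, off=21.0, total=60.0, tr=0.5)
        y = forward_bold(spec, design)
        lag = np.argmax(y[1]) - np.argmax(y[0])
        assert lag > 0

    def test_weak_input_linearity_in_c(self):
        """Doubling C doubles the peak neural response within 5% in the
        weak-signal regime."""
        design = box_design(on=5.0, off=15.0, total=30.0)
        peaks = []
        for gain in (0.05, 0.1):
            spec = DCMSpec(A=np.array([[-1.0]]), B=[np.zeros((1, 1))],
                           C=np.array([[gain]]), name="one")
            path = integrate_dcm(spec, design)
            peaks.append(path.neural.max())
        assert peaks[1] / peaks[0] == pytest.approx(2.0, rel=0.05)

    def test_hemodynamic_refractoriness(self):
        """Two 1 s pulses 2 s apart: the second BOLD peak is smaller."""
        dt = 0.05
        T = int(round(40.0 / dt))
        u = np.zeros((1, T))
        u[0, int(2 / dt): int(3 / dt)] = 1.0
        u[0, int(5 / dt): int(6 / dt)] = 1.0
        spec = two_region_chain()
        design = DesignSpec(u=u, dt=dt, tr=0.25)
        y = forward_bold(spec, design)[0]
        t = design.scan_indices * dt
        first = y[(t > 2) & (t <= 9)].max()
        second = y[(t > 9) & (t < 20)].max()
        assert second < first

    def test_divergence_raises_instability_error(self):
        from designrisk.dcm import InstabilityError

        with pytest.warns(RuntimeWarning, match="unstable"):
            spec = DCMSpec(A=np.array([[-1.0, 2.0], [2.0, -1.0]]),
                           B=[np.zeros((2, 2))], C=np.array([[5.0], [0.0]]),
                           name="explosive")
        with pytest.raises(InstabilityError):
            integrate_dcm(spec, box_design(on=1.0, off=59.0, total=60.0))


class TestCompiledModel:
    def test_mapping_at_prior_mean_equals_forward(self):
        spec = two_region_chain(free=[("A", 1, 0), ("C", 0, 0)])
        design = box_design()
        model = dcm_as_nonlinear_gaussian(spec, design)
        y = model.evaluate(model.prior_mean, design)
        np.testing.assert_allclose(
            y, forward_bold(spec, design).ravel(), atol=1e-12
        )
        assert y.size == 2 * design.n_scans

    def test_fd_and_complex_step_jacobians_agree(self):
        """Finite-difference and complex-step routes through the full
        forward mapping agree to relative 1e-4."""
        spec = two_region_chain(free=[("A", 1, 0), ("C", 0, 0)])
        design = box_design(total=40.0)
        model = dcm_as_nonlinear_gaussian(spec, design)
        p_fd = laplace_predictive(model, design, jacobian_method="finite-difference")
        p_cs = laplace_predictive(model, design, jacobian_method="complex-step")
        np.testing.assert_allclose(p_fd.mean, p_cs.mean, atol=1e-12)
        scale = np.abs(p_cs.cov).max()
        np.testing.assert_allclose(p_fd.cov, p_cs.cov, atol=1e-4 * scale)

    def test_feedback_signature_in_predictive_covariance(self):
        """Adding a feedback connection increases the internode correlation
        during the return to steady state (end of block)."""
        design = box_design(on=4.0, off=20.0, total=50.0, tr=1.0)
        preds = {}
        for name, a12 in (("fbk-", 0.0), ("fbk+", 0.6)):
            free = [("A", 1, 0), ("C", 0, 0)] + ([("A", 0, 1)] if a12 else [])
            spec = two_region_chain(a21=0.6, a12=a12, free=free)
            model = dcm_as_nonlinear_gaussian(spec, design)
            preds[name] = laplace_predictive(model, design)

        def internode_corr(pred):
            n = design.n_scans
            sd = np.sqrt(np.diag(pred.cov))
            corr = pred.cov / np.outer(sd, sd)
            block = corr[:n, n:]  # node1 x node2
            t = design.scan_indices * design.dt
            post = (t > 20.0) & (t < 40.0)  # after input offset
            return block[np.ix_(post, post)].mean()

        assert internode_corr(preds["fbk+"]) > internode_corr(preds["fbk-"])


class TestSimulate:
    def test_high_precision_recovers_clean_signal(self):
        spec = two_region_chain()
        design = box_design()
        ds = simulate_dataset(spec, design, noise_precision=1e12, seed=0)
        np.testing.assert_allclose(ds.y, forward_bold(spec, design), atol=1e-5)

    def test_residual_variance_matches_precision(self):
        spec = two_region_chain()
        design = box_design()
        clean = forward_bold(spec, design)
        prec = 4.0
        resid = []
        for seed in range(40):
            ds = simulate_dataset(spec, design, noise_precision=prec, seed=seed)
            resid.append((ds.y - clean).ravel())
        var = np.concatenate(resid).var()
        assert var == pytest.approx(1.0 / prec, rel=0.05)

    def test_same_seed_reproduces_dataset(self):
        spec = two_region_chain()
        design = box_design()
        d1 = simulate_dataset(spec, design, noise_precision=1.0, seed=7)
        d2 = simulate_dataset(spec, design, noise_precision=1.0, seed=7)
        np.testing.assert_array_equal(d1.y, d2.y)


class TestDatasetIO:
    def test_save_load_round_trip(self, tmp_path):
        spec = two_region_chain()
        design = box_design()
        ds = simulate_dataset(spec, design, noise_precision=2.0, seed=5)
        path = tmp_path / "session.tsv"
        ds.save(path)
        back = Dataset.load(path)
        np.testing.assert_allclose(back.y, ds.y, atol=1e-10)
        assert back.tr == ds.tr
        assert back.seed == 5
        assert back.noise_precision == 2.0

    def test_predictive_export(self, tmp_path):
        spec = two_region_chain(free=[("A", 1, 0)])
        design = box_design(total=30.0)
        model = dcm_as_nonlinear_gaussian(spec, design)
        pred = laplace_predictive(model, design)
        out = tmp_path / "pred.tsv"
        pred.to_delimited(out)
        data = np.loadtxt(out, delimiter="\t", skiprows=1)
        np.testing.assert_allclose(data[0], pred.mean, atol=1e-12)
        np.testing.assert_allclose(data[1:], pred.cov, atol=1e-12)
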
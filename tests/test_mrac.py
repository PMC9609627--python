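import numpy as np
import pytest
from scipy.linalg import eigvals

from conftest import rms_error
from fibermech.mrac import (
    AdaptiveState,
    ChebyshevBasis,
    LoadingCommand,
    adaptive_step,
    build_reference_model,
    design_controller,
    design_lqr,
    design_observer,
    max_tracking_error,
    run_closed_loop,
)
from fibermech.presets import GELMA_5P5PCT, GELMA_7PCT
from fibermech.sls import NoiseSpec, SLSParameters, StateSpaceModel, to_state_space


def make_model(A, C=None, params=GELMA_7PCT):
    A = np.asarray(A, float)
    return StateSpaceModel(
        A=A,
        B=np.array([1.0, 1.0]),
        B_ref=np.array([-1.0, 0.0]),
        C=np.eye(2) if C is None else np.asarray(C, float),
        D=np.array([0.0, 0.0]),
        params=params,
    )


class TestObserver:
    def test_plant_eigenvalues_need_no_correction(self):
        m = to_state_space(GELMA_7PCT)
        L = design_observer(m, np.sort_complex(eigvals(m.A)))
        assert np.allclose(L, 0.0)

    def test_pole_placement_eigenvalue_oracle(self):
        m = to_state_space(GELMA_5P5PCT)
        poles = [-1.0, -1.5]
        L = design_observer(m, poles)
        achieved = np.sort(eigvals(m.A - L @ m.C).real)
        assert np.allclose(achieved, sorted(poles), atol=1e-8)

    def test_unobservable_pair_rejected(self):
        m = make_model(np.diag([-1.0, -2.0]), C=[[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="unobservable"):
            design_observer(m, [-3.0, -4.0])


class TestLQR:
    def test_riccati_residual(self):
        from scipy.linalg import solve_continuous_are

        m = to_state_space(GELMA_7PCT)
        Q, R = np.diag([10.0, 1.0]), 1.0
        K = design_lqr(m, Q, R)
        B = m.B.reshape(2, 1)
        P = solve_continuous_are(m.A, B, Q, np.array([[R]]))
        resid = m.A.T @ P + P @ m.A - P @ B @ B.T @ P / R + Q
        assert np.max(np.abs(resid)) < 1e-8
        assert np.allclose(K, (B.T @ P).ravel() / R)

    def test_cheaper_control_with_larger_R(self):
        m = to_state_space(GELMA_5P5PCT)
        Q = np.diag([10.0, 1.0])
        K1 = design_lqr(m, Q, 1.0)
        K100 = design_lqr(m, Q, 100.0)
        assert np.linalg.norm(K100) < np.linalg.norm(K1)

    @pytest.mark.parametrize("p", [GELMA_7PCT, GELMA_5P5PCT], ids=["7pct", "5.5pct"])
    def test_closed_loop_hurwitz(self, p):
        m = to_state_space(p)
        K = design_lqr(m, np.diag([10.0, 1.0]), 1.0)
        assert np.all(eigvals(m.A - np.outer(m.B, K)).real < 0)

    def test_invalid_weights_rejected(self):
        m = to_state_space(GELMA_7PCT)
        with pytest.raises(ValueError):
            design_lqr(m, np.diag([-1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            design_lqr(m, np.eye(2), 0.0)


class TestReferenceModel:
    def test_lyapunov_solution_properties(self, design7):
        P = design7.P_ref
        assert np.allclose(P, P.T)
        assert np.all(np.linalg.eigvalsh(P) > 0)
        resid = design7.A_ref.T @ P + P @ design7.A_ref + design7.Q_ref
        assert np.max(np.abs(resid)) < 1e-9

    def test_matches_kronecker_vectorized_solve(self):
        # independent vec-trick solution of A^T P + P A = -Q
        m = to_state_space(GELMA_5P5PCT)
        L = design_observer(m, [-5 / 56.2, -6 / 56.2])
        K = design_lqr(m, np.diag([10.0, 1.0]), 1.0)
        A_ref, _, P = build_reference_model(m, L, K, np.eye(2))
        I2 = np.eye(2)
        M = np.kron(I2, A_ref.T) + np.kron(A_ref.T, I2)
        P_vec = np.linalg.solve(M, -np.eye(2).ravel())
        assert np.allclose(P, P_vec.reshape(2, 2), atol=1e-9)

    def test_zero_gains_identity(self):
        m = make_model(np.diag([-1.0, -2.0]))
        A_ref, C_ref, _ = build_reference_model(m, np.zeros((2, 2)), np.zeros(2))
        assert np.array_equal(A_ref, m.A)
        assert np.array_equal(C_ref, m.C)

    def test_unstable_reference_rejected(self):
        m = make_model(np.diag([1.0, -2.0]))  # open-loop unstable mode
        with pytest.raises(RuntimeError, match="Hurwitz"):
            build_reference_model(m, np.zeros((2, 2)), np.zeros(2))


class TestAdaptiveStep:
    def setup_method(self):
        self.design = design_controller(GELMA_7PCT, leak_sigma=0.0)
        self.basis = ChebyshevBasis(self.design.basis_order)

    def test_zero_error_no_update(self):
        theta = np.ones(self.basis.dim)
        state = AdaptiveState(theta.copy(), np.zeros(2), np.zeros(2))
        out = adaptive_step(state, np.zeros(2), self.basis(np.zeros(2)), self.design, 0.1)
        assert np.array_equal(out.Theta_hat, theta)

    def test_vanishing_gain_freezes_adaptation(self):
        design = design_controller(GELMA_7PCT, gamma=1e-15, leak_sigma=0.0)
        state = AdaptiveState(np.zeros(7), np.zeros(2), np.zeros(2))
        out = adaptive_step(
            state, np.array([1.0, 1.0]), self.basis(np.ones(2)), design, 0.1
        )
        assert np.max(np.abs(out.Theta_hat)) < 1e-9

    def test_nonfinite_error_aborts(self):
        state = AdaptiveState(np.zeros(7), np.zeros(2), np.zeros(2))
        with pytest.raises(FloatingPointError):
            adaptive_step(
                state, np.array([np.nan, 0.0]), np.zeros(7), self.design, 0.1
            )

    def test_lyapunov_candidate_nonincreasing_on_constant_uncertainty(self):
        # noise-free run with a constant input disturbance: V along the
        # trajectory must not grow beyond integration tolerance
        f = 0.2
        design = design_controller(GELMA_7PCT, leak_sigma=0.0)
        cmd = LoadingCommand(offset_uN=5.0, amplitude_uN=0.0, n_cycles=2)
        bounds = np.array([[-50.0, 50.0], [-20.0, 20.0]])
        tr = run_closed_loop(
            GELMA_7PCT, design, cmd, None, seed=0,
            extra_uncertainty_f=f, basis_bounds=bounds, keep_internals=True,
        )
        Theta_star = np.zeros(design.Gamma.shape[0])
        Theta_star[0] = -f  # ideal weights: constant feature cancels f
        Ginv = np.linalg.inv(design.Gamma)
        dTh = tr.Theta_hist - Theta_star
        V = (
            np.einsum("ij,jk,ik->i", tr.e_x_hist, design.P_ref, tr.e_x_hist)
            + np.einsum("ij,jk,ik->i", dTh, Ginv, dTh)
        )
        assert V[-1] < V[0]
        assert np.max(np.diff(V)) < 1e-5 * np.max(V)
        # the analytic decrease rate -e^T Q_ref e is non-positive by
        # construction and V follows it
        eQe = np.einsum("ij,jk,ik->i", tr.e_x_hist, design.Q_ref, tr.e_x_hist)
        assert np.all(eQe >= 0)


class TestClosedLoop:
    def test_tracking_within_one_micronewton_7pct(self, trace7_noisy, standard_command):
        err = max_tracking_error(trace7_noisy, after_s=0.5 * standard_command.period_s)
        assert err < 1.0

    def test_tracking_survives_parameter_mismatch(
        self, trace55_noisy, standard_command
    ):
        # controller designed on the 7% model, fiber is 5.5% GelMA
        err = max_tracking_error(trace55_noisy, after_s=0.5 * standard_command.period_s)
        assert err < 1.0

    def test_zero_command_zero_noise_zero_trace(self, design7):
        cmd = LoadingCommand(offset_uN=0.0, amplitude_uN=0.0, n_cycles=1)
        tr = run_closed_loop(GELMA_7PCT, design7, cmd, None, seed=0)
        assert np.all(tr.F_f == 0.0)
        assert np.all(tr.L_m == 0.0)

    def test_deterministic_given_seed(self, design7):
        cmd = LoadingCommand(n_cycles=1, dt_s=0.01)
        tr1 = run_closed_loop(GELMA_7PCT, design7, cmd, NoiseSpec(), seed=42)
        tr2 = run_closed_loop(GELMA_7PCT, design7, cmd, NoiseSpec(), seed=42)
        for name in ("F_f", "F_meas", "L_m", "u_tip", "u_bl", "u_ad"):
            assert np.array_equal(getattr(tr1, name), getattr(tr2, name))

    def test_adaptation_benefit_on_mismatched_plant(self, design7, standard_command):
        # steady-state RMS tracking error with the adaptive term active
        # must not exceed the baseline-only error
        tr_ad = run_closed_loop(
            GELMA_5P5PCT, design7, standard_command, NoiseSpec(), seed=1
        )
        tr_bl = run_closed_loop(
            GELMA_5P5PCT, design7, standard_command, NoiseSpec(), seed=1, adapt=False
        )
        after = standard_command.period_s
        assert rms_error(tr_ad, after) <= rms_error(tr_bl, after)

    def test_bibo_bounded_over_twenty_cycles(self, design7):
        cmd = LoadingCommand(n_cycles=20, dt_s=0.005)
        tr = run_closed_loop(
            GELMA_7PCT, design7, cmd, NoiseSpec(), seed=3, keep_internals=True
        )
        assert np.all(np.isfinite(tr.F_f))
        assert np.max(np.abs(tr.F_f)) < 20.0
        assert np.max(np.abs(tr.L_m)) < 100.0
        assert np.max(np.abs(tr.Theta_hist)) < 10.0

    def test_divergence_detected_for_absurd_adaptation_gain(self):
        from fibermech.mrac import UnstableLoopError

        design = design_controller(GELMA_7PCT, gamma=1e6, leak_sigma=0.0)
        cmd = LoadingCommand(n_cycles=1)
        with pytest.raises(UnstableLoopError):
            run_closed_loop(GELMA_7PCT, design, cmd, NoiseSpec(), seed=0)

    def test_trace_csv_roundtrip(self, tmp_path, design7):
        cmd = LoadingCommand(n_cycles=1, dt_s=0.05)
        tr = run_closed_loop(GELMA_7PCT, design7, cmd, None, seed=0)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        from fibermech.mrac import ClosedLoopTrace

        back = ClosedLoopTrace.from_csv(path)
        assert np.allclose(back.F_f, tr.F_f)
        assert np.allclose(back.L_m, tr.L_m)

    def test_command_validation(self):
        with pytest.raises(ValueError):
            LoadingCommand(offset_uN=2.0, amplitude_uN=5.0)
        with pytest.raises(ValueError):
            LoadingCommand(frequency_Hz=0.0)


class TestChebyshevBasis:
    def test_feature_values_on_known_points(self):
        basis = ChebyshevBasis(3, bounds=np.array([[-1.0, 1.0], [-1.0, 1.0]]))
        feats = basis(np.array([0.5, -0.25]))
        # T_1..T_3 at 0.5: 0.5, -0.5, -1.0; at -0.25: -0.25, -0.875, 0.6875
        assert feats[0] == 1.0
        assert np.allclose(feats[1:4], [0.5, -0.5, -1.0])
        assert np.allclose(feats[4:], [-0.25, -0.875, 0.6875])

    def test_running_normalization_clips_into_domain(self):
        basis = ChebyshevBasis(2)
        basis(np.array([5.0, -3.0]))
        feats = basis(np.array([10.0, 4.0]))
        assert np.all(np.abs(feats) <= 1.0 + 1e-12)
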
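"""Model-reference adaptive force control (MRAC) of the stretched microfiber.

The controller tracks a sinusoidal force command by moving the
manipulating tube.  It is built in four layers:

1. a Luenberger observer reconstructing the augmented plant state
   (integral force error + viscoelastic state) from the measured outputs;
2. a baseline LQR state-feedback gain ``K_x`` designed on the nominal
   plant model;
3. a reference model ``A_ref = A - L_obs C - (B - L_obs D) K_x^T``
   describing the ideal (certainty-equivalent) closed loop, with the
   Lyapunov matrix ``P_ref`` solving ``A_ref^T P + P A_ref = -Q_ref``;
4. an adaptive augmentation ``u_ad = Theta_hat^T Phi(x_ro)`` whose
   coefficients follow the Lyapunov-derived law
   ``dTheta_hat/dt = -Gamma Phi e_x^T P_ref (B - L_obs D)``,
   absorbing parametric mismatch between the design model and the actual
   fiber (e.g. a controller designed for one GelMA concentration driving
   another).

Phi is a Chebyshev polynomial basis of the observer state, each component
normalized to [-1, 1] by a running min/max.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigvals, expm, solve_continuous_are, solve_continuous_lyapunov
from scipy.signal import place_poles

from .sls import NoiseSpec, SLSParameters, StateSpaceModel, to_state_space

__all__ = [
    "ControllerDesign",
    "AdaptiveState",
    "LoadingCommand",
    "ClosedLoopTrace",
    "ChebyshevBasis",
    "UnstableLoopError",
    "design_observer",
    "design_lqr",
    "build_reference_model",
    "design_controller",
    "adaptive_step",
    "run_closed_loop",
    "max_tracking_error",
]


class UnstableLoopError(RuntimeError):
    """Raised when the simulated closed loop diverges."""


# ---------------------------------------------------------------------------
# basis


class ChebyshevBasis:
    """Chebyshev features of the 2-dim observer state.

    Phi(x) = [1, T_1..T_order(x1n), T_1..T_order(x2n)] where x1n, x2n are
    the state components mapped to [-1, 1] by a running min/max (updated
    on every evaluation unless frozen bounds are supplied).  The shared
    constant term lets the adaptive law absorb constant input
    disturbances exactly.
    """

    def __init__(self, order: int = 3, bounds: np.ndarray | None = None):
        if order < 1:
            raise ValueError("order must be >= 1")
        self.order = order
        self.dim = 1 + 2 * order
        self._frozen = bounds is not None
        # bounds[i] = (lo, hi) per state component
        self._bounds = (
            np.asarray(bounds, float) if bounds is not None
            else np.array([[-1.0, 1.0], [-1.0, 1.0]])
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if not self._frozen:
            self._bounds[:, 0] = np.minimum(self._bounds[:, 0], x)
            self._bounds[:, 1] = np.maximum(self._bounds[:, 1], x)
        lo, hi = self._bounds[:, 0], self._bounds[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        xn = np.clip(2.0 * (x - lo) / span - 1.0, -1.0, 1.0)
        feats = np.empty(self.dim)
        feats[0] = 1.0
        for i in (0, 1):
            # T_1..T_order by the three-term recurrence
            z = xn[i]
            tkm1, tk = 1.0, z
            base = 1 + i * self.order
            feats[base] = z
            for j in range(1, self.order):
                tkm1, tk = tk, 2.0 * z * tk - tkm1
                feats[base + j] = tk
        return feats


# ---------------------------------------------------------------------------
# design types


@dataclass(frozen=True)
class ControllerDesign:
    """Frozen output of the observer/LQR/reference-model design stage."""

    model: StateSpaceModel
    L_obs: np.ndarray  # 2x2 observer gain
    K_x: np.ndarray  # 2-vector state-feedback gain
    A_ref: np.ndarray
    C_ref: np.ndarray
    Q_ref: np.ndarray
    P_ref: np.ndarray
    Gamma: np.ndarray  # adaptation-rate matrix, (dim x dim) SPD
    basis_order: int = 3
    leak_sigma: float = 0.01  # sigma-modification rate (1/s) bounding Theta_hat drift

    @property
    def B_eff(self) -> np.ndarray:
        """Effective input direction B - L_obs @ D of the error dynamics."""
        return self.model.B - self.L_obs @ self.model.D

    def to_json(self, path: str | Path) -> None:
        d = {
            "L_obs": self.L_obs.tolist(),
            "K_x": self.K_x.tolist(),
            "A_ref": self.A_ref.tolist(),
            "C_ref": self.C_ref.tolist(),
            "Q_ref": self.Q_ref.tolist(),
            "P_ref": self.P_ref.tolist(),
            "Gamma": self.Gamma.tolist(),
            "basis_order": self.basis_order,
            "plant": {
                "lambda1": self.model.params.lambda1,
                "lambda2": self.model.params.lambda2,
                "tau": self.model.params.tau,
            },
        }
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class AdaptiveState:
    """Mutable state of the adaptive augmentation."""

    Theta_hat: np.ndarray
    x_ro: np.ndarray
    x_bar: np.ndarray

    def check_finite(self) -> None:
        for name in ("Theta_hat", "x_ro", "x_bar"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise FloatingPointError(f"non-finite {name}: {getattr(self, name)}")


@dataclass(frozen=True)
class LoadingCommand:
    """Sinusoidal force command F_cmd(t) = offset + amplitude sin(2 pi f t)."""

    offset_uN: float = 5.0
    amplitude_uN: float = 5.0
    frequency_Hz: float = 0.01
    n_cycles: int = 3
    dt_s: float | None = None  # default: min(tau/100, period/200)

    def __post_init__(self) -> None:
        if self.frequency_Hz <= 0:
            raise ValueError("frequency must be > 0")
        if not (self.offset_uN >= self.amplitude_uN >= 0):
            raise ValueError(
                "need offset >= amplitude >= 0 so the fiber is never pushed"
            )

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_Hz

    def __call__(self, t):
        return self.offset_uN + self.amplitude_uN * np.sin(
            2.0 * np.pi * self.frequency_Hz * np.asarray(t, float)
        )


@dataclass
class ClosedLoopTrace:
    """Time series from a closed-loop run.

    F_f is the force actually applied to the fiber; F_meas is the
    vision-derived (noise-corrupted) force the controller sees; u_tip is
    the measured sensing-tube tip deflection F_meas / tube_K; L_m is the
    manipulator displacement (fiber elongation + true tube deflection).
    """

    t: np.ndarray
    F_cmd: np.ndarray
    F_f: np.ndarray
    F_meas: np.ndarray
    L_m: np.ndarray
    u_tip: np.ndarray
    u_bl: np.ndarray
    u_ad: np.ndarray
    Theta_hist: np.ndarray | None = None
    e_x_hist: np.ndarray | None = None
    x_ro_hist: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("F_cmd", "F_f", "F_meas", "L_m", "u_tip", "u_bl", "u_ad"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t_s": self.t,
                "F_cmd_uN": self.F_cmd,
                "F_f_uN": self.F_f,
                "L_m_um": self.L_m,
                "u_tip_um": self.u_tip,
                "u_bl": self.u_bl,
                "u_ad": self.u_ad,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClosedLoopTrace":
        df = pd.read_csv(path)
        required = ["t_s", "F_cmd_uN", "F_f_uN", "L_m_um", "u_tip_um", "u_bl", "u_ad"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trace file missing columns: {missing}")
        return cls(
            t=df["t_s"].to_numpy(),
            F_cmd=df["F_cmd_uN"].to_numpy(),
            F_f=df["F_f_uN"].to_numpy(),
            F_meas=df["F_f_uN"].to_numpy(),
            L_m=df["L_m_um"].to_numpy(),
            u_tip=df["u_tip_um"].to_numpy(),
            u_bl=df["u_bl"].to_numpy(),
            u_ad=df["u_ad"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# design stages


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, float)
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.linalg.eigvalsh(M) <= 0):
        raise ValueError(f"{name} must be positive definite")
    return M


def design_observer(m: StateSpaceModel, poles) -> np.ndarray:
    """Observer gain L_obs placing eig(A - L_obs C) at the given poles."""
    poles = np.sort_complex(np.asarray(poles, complex))
    A, C = m.A, m.C
    obs = np.vstack([C, C @ A])
    rank = np.linalg.matrix_rank(obs)
    if rank < A.shape[0]:
        # name the mode that never reaches the output
        _, _, vh = np.linalg.svd(obs)
        raise ValueError(
            f"(A, C) unobservable: rank {rank} < {A.shape[0]}; "
            f"deficient mode direction {vh[-1]}"
        )
    if np.allclose(poles, np.sort_complex(eigvals(A)), atol=1e-10):
        return np.zeros_like(A)
    res = place_poles(A.T, C.T, poles)
    L = res.gain_matrix.T
    achieved = np.sort_complex(eigvals(A - L @ C))
    if not np.allclose(achieved, poles, atol=1e-8):
        raise RuntimeError(f"pole placement failed: wanted {poles}, got {achieved}")
    return L


def design_lqr(m: StateSpaceModel, Q, R: float) -> np.ndarray:
    """LQR state-feedback gain K_x (2-vector) from the Riccati equation."""
    Q = _check_spd(Q, "Q")
    if not np.isscalar(R) or R <= 0:
        raise ValueError("R must be a positive scalar")
    B = m.B.reshape(2, 1)
    P = solve_continuous_are(m.A, B, Q, np.array([[float(R)]]))
    K = (B.T @ P / float(R)).ravel()
    cl = eigvals(m.A - np.outer(m.B, K))
    if np.any(cl.real >= 0):
        raise RuntimeError(f"LQR closed loop not Hurwitz: {cl}")
    return K


def build_reference_model(
    m: StateSpaceModel,
    L_obs: np.ndarray,
    K_x: np.ndarray,
    Q_ref=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference-model matrices (A_ref, C_ref, P_ref).

    A_ref = A - L_obs C - (B - L_obs D) K_x^T must be Hurwitz; P_ref is
    the SPD solution of A_ref^T P + P A_ref = -Q_ref.
    """
    Q_ref = np.eye(2) if Q_ref is None else _check_spd(Q_ref, "Q_ref")
    L_obs = np.asarray(L_obs, float)
    K_x = np.asarray(K_x, float).reshape(2)
    A_ref = m.A - L_obs @ m.C - np.outer(m.B - L_obs @ m.D, K_x)
    C_ref = m.C - np.outer(m.D, K_x)
    ev = eigvals(A_ref)
    if np.any(ev.real >= 0):
        raise RuntimeError(f"A_ref not Hurwitz (eigenvalues {ev}); redesign gains")
    P_ref = solve_continuous_lyapunov(A_ref.T, -Q_ref)
    P_ref = 0.5 * (P_ref + P_ref.T)
    resid = np.max(np.abs(A_ref.T @ P_ref + P_ref @ A_ref + Q_ref))
    if resid > 1e-9 * max(1.0, np.max(np.abs(Q_ref))):
        raise RuntimeError(f"Lyapunov residual too large: {resid}")
    return A_ref, C_ref, P_ref


def design_controller(
    p: SLSParameters,
    Q=None,
    R: float = 1.0,
    Q_ref=None,
    gamma: float | np.ndarray = 1e-3,
    observer_poles=None,
    basis_order: int = 3,
    leak_sigma: float = 0.01,
) -> ControllerDesign:
    """One-call design on the nominal plant model.

    Defaults: Q = diag(10, 1) (weights the integral-of-force-error state
    so the command is tracked tightly), R = 1, Q_ref = I, observer poles
    5x and 6x faster than the plant's relaxation pole, Gamma = gamma * I
    with gamma = 1e-3.  The adaptation rate is small in absolute terms
    because P_ref inherits the slow reference dynamics (entries of order
    1e4), making the effective Lyapunov-gradient gain of order ten.
    """
    m = to_state_space(p)
    Q = np.diag([10.0, 1.0]) if Q is None else np.asarray(Q, float)
    if observer_poles is None:
        observer_poles = [-5.0 / p.tau, -6.0 / p.tau]
    L_obs = design_observer(m, observer_poles)
    K_x = design_lqr(m, Q, R)
    A_ref, C_ref, P_ref = build_reference_model(m, L_obs, K_x, Q_ref)
    dim = 1 + 2 * basis_order
    Gamma = gamma * np.eye(dim) if np.isscalar(gamma) else np.asarray(gamma, float)
    _check_spd(Gamma, "Gamma")
    return ControllerDesign(
        model=m,
        L_obs=L_obs,
        K_x=K_x,
        A_ref=A_ref,
        C_ref=C_ref,
        Q_ref=np.eye(2) if Q_ref is None else np.asarray(Q_ref, float),
        P_ref=P_ref,
        Gamma=Gamma,
        basis_order=basis_order,
        leak_sigma=leak_sigma,
    )


# ---------------------------------------------------------------------------
# adaptation and simulation


def _closed_loop_spectral_radius(
    p_true: SLSParameters, design: ControllerDesign
) -> float:
    """Largest |eigenvalue| of the ideal baseline loop on the true plant.

    States are [e_yI, x_p, x_ro(2)] under u = -K_x x_ro with noise-free
    measurements; used only to pick a stable sampling step.
    """
    l1, l2, tau = p_true.lambda1, p_true.lambda2, p_true.tau
    d = l1 + l2
    K = design.K_x
    L = design.L_obs
    A = np.zeros((4, 4))
    A[0, 1] = 1.0
    A[0, 2:] = -d * K
    A[1, 1] = -1.0 / tau
    A[1, 2:] = (l2 / tau) * K
    # x_ro' = A_ref x_ro + L y; y = [e_yI, x_p - d K x_ro]
    A[2:, 2:] = design.A_ref - np.outer(L[:, 1], d * K)
    A[2:, 0] = L[:, 0]
    A[2:, 1] = L[:, 1]
    return float(np.max(np.abs(eigvals(A))))


def adaptive_step(
    state: AdaptiveState,
    e_x: np.ndarray,
    phi: np.ndarray,
    design: ControllerDesign,
    dt: float,
) -> AdaptiveState:
    """Explicit-Euler update of the adaptive coefficients.

    dTheta_hat/dt = -Gamma (Phi * e_x^T P_ref (B - L_obs D) + leak_sigma * Theta_hat).

    With u_ad = Theta_hat^T Phi entering the state-error dynamics through
    +(B - L_obs D), completing the squares in dV/dt of the quadratic
    Lyapunov candidate V = e_x^T P_ref e_x + tr(Theta_tilde^T Gamma^-1
    Theta_tilde) yields this sign; the opposite one is exponentially
    destabilizing.  The sigma-modification (leakage) term keeps the
    coefficients bounded when the state error is dominated by measurement
    noise; with leak_sigma = 0 the update reduces to the pure Lyapunov
    law.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e_x = np.asarray(e_x, float)
    if not np.all(np.isfinite(e_x)):
        raise FloatingPointError(f"non-finite state error {e_x}")
    scal = float(e_x @ design.P_ref @ design.B_eff)
    grad = -phi * scal - design.leak_sigma * state.Theta_hat
    theta = state.Theta_hat + dt * (design.Gamma @ grad)
    return replace(state, Theta_hat=theta)


def run_closed_loop(
    p_true: SLSParameters,
    design: ControllerDesign,
    cmd: LoadingCommand,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
    tube_K_uN_per_um: float = 5.0,
    adapt: bool = True,
    extra_uncertainty_f: float = 0.0,
    basis_bounds: np.ndarray | None = None,
    keep_internals: bool = False,
) -> ClosedLoopTrace:
    """Simulate the full MRAC loop against an SLS fiber.

    ``p_true`` parameterizes the simulated fiber; ``design`` may have been
    built for a different parameter set (the adaptive law then absorbs
    the mismatch).  Measurement noise corrupts only the vision-derived
    force fed back to the controller, not the physical force.
    ``extra_uncertainty_f`` adds a constant input-matched disturbance
    (um) to exercise the adaptive law.  Deterministic for a fixed seed.
    """
    m_true = to_state_space(p_true)
    m_des = design.model
    period = cmd.period_s
    if cmd.dt_s is not None:
        dt = cmd.dt_s
    else:
        # resolve the fastest mode of the sampled loop: the feedthrough
        # path gives a pole near -(lambda1+lambda2)_true * K_x[0], so the
        # step must satisfy rho * dt << 1 for the true plant
        rho = _closed_loop_spectral_radius(p_true, design)
        dt = min(p_true.tau / 100.0, period / 200.0, 0.2 / rho)
    n = int(round(cmd.n_cycles * period / dt)) + 1
    t = np.arange(n) * dt

    rng = np.random.default_rng(seed)
    noise_seq = (
        noise.draw(rng, n) if noise is not None and noise.mean_abs_uN > 0 else np.zeros(n)
    )

    basis = ChebyshevBasis(design.basis_order, bounds=basis_bounds)
    l1t, l2t, taut = p_true.lambda1, p_true.lambda2, p_true.tau
    d_true = l1t + l2t

    x_p = 0.0  # true viscoelastic state (uN)
    e_yI = 0.0  # controller-side integral of measured force error (uN s)
    x_ro = np.zeros(2)
    theta = np.zeros(basis.dim)

    F_cmd = cmd(t)
    F_f = np.empty(n)
    F_meas = np.empty(n)
    L_m = np.empty(n)
    u_tip = np.empty(n)
    u_bl_a = np.empty(n)
    u_ad_a = np.empty(n)
    theta_hist = np.empty((n, basis.dim)) if keep_internals else None
    ex_hist = np.empty((n, 2)) if keep_internals else None
    xro_hist = np.empty((n, 2)) if keep_internals else None

    # The observer-like reference model x_ro evolves closed on the
    # baseline law only, x_ro' = A_ref x_ro + B_ref F_cmd + L_obs y, so
    # that u_ad enters the state-error dynamics the adaptive law acts on.
    # Linear with inputs held over each step: exact ZOH update
    # x' = Ad x + M @ const with M = A_ref^{-1} (Ad - I).
    Ad_ref = expm(design.A_ref * dt)
    M_ref = np.linalg.solve(design.A_ref, Ad_ref - np.eye(2))
    L_obs = design.L_obs
    K_x = design.K_x
    PB = design.P_ref @ design.B_eff
    limit = 100.0 * max(cmd.amplitude_uN + cmd.offset_uN, 1.0)

    state = AdaptiveState(Theta_hat=theta, x_ro=x_ro, x_bar=np.array([e_yI, x_p]))

    for k in range(n):
        phi = basis(state.x_ro)
        u_bl = -float(design.K_x @ state.x_ro)
        u_ad = float(state.Theta_hat @ phi) if adapt else 0.0
        u = u_bl + u_ad
        u_plant = u + extra_uncertainty_f

        F_true = x_p + d_true * u_plant
        F_m = F_true + noise_seq[k]

        F_f[k] = F_true
        F_meas[k] = F_m
        u_tip[k] = F_m / tube_K_uN_per_um
        L_m[k] = u + F_true / tube_K_uN_per_um
        u_bl_a[k] = u_bl
        u_ad_a[k] = u_ad
        if keep_internals:
            theta_hist[k] = state.Theta_hat
            xro_hist[k] = state.x_ro
            ex_hist[k] = np.array([e_yI, x_p]) - state.x_ro

        if abs(F_true) > limit or not np.isfinite(F_true):
            raise UnstableLoopError(
                f"closed loop diverged at t={t[k]:.2f}s (|F_f|={abs(F_true):.3g} uN)"
            )
        if k == n - 1:
            break

        # adaptation (explicit Euler, slow relative to the loop dynamics);
        # inlined form of adaptive_step for the hot loop
        if adapt:
            e_x = np.array([e_yI, x_p]) - state.x_ro
            scal = float(e_x @ PB)
            state.Theta_hat = state.Theta_hat + dt * (
                design.Gamma @ (-phi * scal - design.leak_sigma * state.Theta_hat)
            )

        # reference model: inputs held over the step, exact ZOH update
        y_meas = np.array([e_yI, F_m])
        const = m_des.B_ref * F_cmd[k] + L_obs @ y_meas
        state.x_ro = Ad_ref @ state.x_ro + M_ref @ const

        # true plant state (exact scalar ZOH step for the linear SLS pole)
        xinf = -l2t * u_plant
        x_p = xinf + (x_p - xinf) * np.exp(-dt / taut)

        # controller-side integral of the measured tracking error
        e_yI = e_yI + dt * (F_m - F_cmd[k])
        state.x_bar = np.array([e_yI, x_p])

    return ClosedLoopTrace(
        t=t,
        F_cmd=F_cmd,
        F_f=F_f,
        F_meas=F_meas,
        L_m=L_m,
        u_tip=u_tip,
        u_bl=u_bl_a,
        u_ad=u_ad_a,
        Theta_hist=theta_hist,
        e_x_hist=ex_hist,
        x_ro_hist=xro_hist,
    )


def simulate_ramp_loading(
    p: SLSParameters,
    rate_um_per_s: float = 10e3 / 60.0,  # 10 mm/min manipulating-tube speed
    t_ramp_s: float = 20.0,
    t_hold_s: float = 20.0,
    dt_s: float = 0.2,
    tube_K_uN_per_um: float = 5.0,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
) -> ClosedLoopTrace:
    """Open-loop constant-rate stretch followed by a hold.

    Emulates the classical constant-force-loading measurement: the
    manipulating tube moves at constant speed until ``t_ramp_s`` and
    then stops, while the fiber force keeps relaxing.  Sampled at
    ``dt_s`` (0.2 s by default, the usual vision frame interval).
    Returns a :class:`ClosedLoopTrace` whose F_cmd column is a copy of
    the realized force (there is no command in open loop).
    """
    n = int(round((t_ramp_s + t_hold_s) / dt_s)) + 1
    t = np.arange(n) * dt_s
    u = np.minimum(t, t_ramp_s) * rate_um_per_s

    # substep so that the ZOH staircase approximates the linear ramp
    sub = max(1, int(np.ceil(dt_s / min(p.tau / 100.0, dt_s))))
    h = dt_s / sub
    decay = np.exp(-h / p.tau)
    x_p = 0.0
    F = np.empty(n)
    tcur = 0.0
    for k in range(n):
        ucur = min(tcur, t_ramp_s) * rate_um_per_s
        F[k] = x_p + (p.lambda1 + p.lambda2) * ucur
        for _ in range(sub):
            um = min(tcur + h / 2.0, t_ramp_s) * rate_um_per_s  # midpoint hold
            xinf = -p.lambda2 * um
            x_p = xinf + (x_p - xinf) * decay
            tcur += h
    if noise is not None and noise.mean_abs_uN > 0:
        rng = np.random.default_rng(seed)
        F_meas = F + noise.draw(rng, n)
    else:
        F_meas = F.copy()
    u_tip = F_meas / tube_K_uN_per_um
    return ClosedLoopTrace(
        t=t,
        F_cmd=F.copy(),
        F_f=F,
        F_meas=F_meas,
        L_m=u + F / tube_K_uN_per_um,
        u_tip=u_tip,
        u_bl=np.zeros(n),
        u_ad=np.zeros(n),
    )


def max_tracking_error(
    trace: ClosedLoopTrace, after_s: float, measured: bool = False
) -> float:
    """Max |F_f - F_cmd| (uN) over t >= after_s.

    By default the error of the physical force; set ``measured=True`` for
    the vision-derived signal (which carries the measurement noise).
    """
    mask = trace.t >= after_s
    F = trace.F_meas if measured else trace.F_f
    return float(np.max(np.abs(F[mask] - trace.F_cmd[mask])))
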
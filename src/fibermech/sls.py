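"""Standard-linear-solid (SLS) viscoelastic model of a hydrogel microfiber.

The microfiber is modelled as a three-element standard linear solid: a
spring (stiffness ``K2``) in parallel with a Maxwell arm (spring ``K1`` in
series with a dashpot ``eta``).  For a step elongation ``u0`` the axial
force relaxes as

    F(t) = (lambda1 + lambda2 * exp(-t / tau)) * u0

with the lumped parameters ``lambda1 = S*K2/L0`` (long-time stiffness,
uN/um), ``lambda2 = S*K1/L0`` (relaxing stiffness, uN/um) and
``tau = eta/K1`` (relaxation time, s).  The same model, written as a
transfer function from fiber elongation ``u`` (um) to force ``F`` (uN),

    G(s) = ((lambda1 + lambda2) s + lambda1 / tau) / (s + 1 / tau),

is realized here in state space, augmented with an integral
force-tracking-error state so it can serve as the plant of the adaptive
force controller in :mod:`fibermech.mrac`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit

__all__ = [
    "SLSParameters",
    "StateSpaceModel",
    "NoiseSpec",
    "SLSFitResult",
    "relaxation_force",
    "fit_sls",
    "to_state_space",
    "simulate_plant",
    "dynamic_modulus",
    "discretize",
]


@dataclass(frozen=True)
class SLSParameters:
    """Lumped SLS parameters in force/elongation form.

    lambda1 : long-time (relaxed) stiffness, uN/um
    lambda2 : instantaneously stored extra stiffness, uN/um
    tau     : relaxation time of the Maxwell arm, s
    """

    lambda1: float
    lambda2: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "tau"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_raw(
        cls,
        K1_kPa: float,
        K2_kPa: float,
        eta_kPa_s: float,
        S_um2: float,
        L0_um: float,
    ) -> "SLSParameters":
        """Build from the physical three-element constants.

        K1, K2 in kPa, eta in kPa*s, cross-section S in um^2, rest length
        L0 in um.  1 kPa * um^2 / um = 1e-3 uN/um.
        """
        scale = 1e-3 * S_um2 / L0_um  # kPa -> uN/um
        return cls(
            lambda1=K2_kPa * scale,
            lambda2=K1_kPa * scale,
            tau=eta_kPa_s / K1_kPa,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"lambda1": self.lambda1, "lambda2": self.lambda2, "tau": self.tau},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SLSParameters":
        d = json.loads(Path(path).read_text())
        return cls(d["lambda1"], d["lambda2"], d["tau"])


@dataclass(frozen=True)
class StateSpaceModel:
    """Augmented plant realization with state x = [e_yI, x_p].

    e_yI is the integral of the force tracking error (uN*s) and x_p the
    internal viscoelastic state (uN).  Input u is the fiber elongation
    (um); exogenous input F_cmd enters through B_ref.  Outputs are
    y = [e_yI, F_f].
    """

    A: np.ndarray
    B: np.ndarray
    B_ref: np.ndarray
    C: np.ndarray
    D: np.ndarray
    params: SLSParameters
    state_labels: tuple[str, str] = ("e_yI", "x_p")

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, float))
        object.__setattr__(self, "B", np.asarray(self.B, float).reshape(2))
        object.__setattr__(self, "B_ref", np.asarray(self.B_ref, float).reshape(2))
        object.__setattr__(self, "C", np.asarray(self.C, float))
        object.__setattr__(self, "D", np.asarray(self.D, float).reshape(2))

    @property
    def plant_pole(self) -> float:
        return self.A[1, 1]

    def output(self, x: np.ndarray, u: float) -> np.ndarray:
        return self.C @ x + self.D * u


@dataclass(frozen=True)
class NoiseSpec:
    """Additive measurement noise on the vision-derived force signal.

    ``mean_abs_uN`` is the mean *magnitude* E|n| of the noise (uN).  For
    the Gaussian model sigma = mean_abs * sqrt(pi/2); for the uniform
    model the half-width is 2 * mean_abs.  A zero-mean disturbance is
    used in both cases: a DC offset would bias the tracking error
    symmetric about zero seen in closed-loop runs.
    """

    mean_abs_uN: float = 0.277
    kind: str = "gaussian"  # or "uniform"

    def __post_init__(self) -> None:
        if self.mean_abs_uN < 0:
            raise ValueError("mean_abs_uN must be >= 0")
        if self.kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    @property
    def sigma(self) -> float:
        if self.kind == "gaussian":
            return self.mean_abs_uN * np.sqrt(np.pi / 2.0)
        return 2.0 * self.mean_abs_uN / np.sqrt(3.0)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean_abs_uN == 0:
            return np.zeros(n)
        if self.kind == "gaussian":
            return rng.normal(0.0, self.mean_abs_uN * np.sqrt(np.pi / 2.0), n)
        return rng.uniform(-2.0 * self.mean_abs_uN, 2.0 * self.mean_abs_uN, n)


def relaxation_force(t, p: SLSParameters, u0: float):
    """Stress-relaxation force F(t) = (lambda1 + lambda2 e^{-t/tau}) u0 in uN.

    ``t`` may be a scalar or array of times (s, >= 0); ``u0`` is the step
    elongation in um.
    """
    t = np.asarray(t, float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    out = (p.lambda1 + p.lambda2 * np.exp(-t / p.tau)) * u0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SLSFitResult:
    params: SLSParameters | None
    r2: float
    converged: bool
    tau_identifiable: bool
    message: str = ""


def fit_sls(
    times: np.ndarray,
    forces: np.ndarray,
    u0: float,
    p0: SLSParameters | None = None,
) -> SLSFitResult:
    """Nonlinear least-squares fit of the relaxation model to (t, F) data.

    Requires >= 10 samples at strictly increasing times.  When the fitted
    lambda2 is negligible (< 1e-3 * lambda1) the relaxation time tau is
    unidentifiable and the result is flagged rather than reported as a
    genuine estimate.
    """
    t = np.asarray(times, float)
    F = np.asarray(forces, float)
    if t.size < 10:
        raise ValueError("need at least 10 samples")
    if t.shape != F.shape:
        raise ValueError("times and forces must have matching shapes")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if u0 <= 0:
        raise ValueError("u0 must be > 0")

    if p0 is None:
        f_inf = F[-1] / u0
        f_0 = F[0] / u0
        lam1_0 = max(f_inf, 1e-9)
        lam2_0 = max(f_0 - f_inf, 1e-6 * lam1_0)
        tau_0 = max((t[-1] - t[0]) / 3.0, 1e-6)
    else:
        lam1_0, lam2_0, tau_0 = p0.lambda1, p0.lambda2, p0.tau

    def model(tt, lam1, lam2, tau):
        return (lam1 + lam2 * np.exp(-tt / tau)) * u0

    try:
        popt, _ = curve_fit(
            model,
            t,
            F,
            p0=[lam1_0, lam2_0, tau_0],
            bounds=([1e-12, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return SLSFitResult(None, np.nan, False, False, message=str(exc))

    resid = F - model(t, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((F - F.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)

    lam1, lam2, tau = (float(v) for v in popt)
    tau_ok = lam2 >= 1e-3 * lam1
    params = SLSParameters(lam1, max(lam2, 1e-300), tau)
    msg = "" if tau_ok else "lambda2 ~ 0: tau unidentifiable"
    return SLSFitResult(params, r2, True, tau_ok, message=msg)


def to_state_space(p: SLSParameters) -> StateSpaceModel:
    """Augmented state-space realization of the SLS plant.

    Derived from the relaxation response: the u -> F transfer function is
    G(s) = (lambda1 + lambda2) + (-lambda2/tau)/(s + 1/tau), i.e. a
    single pole at -1/tau with feedthrough lambda1 + lambda2 and DC gain
    lambda1.  The first state integrates the force tracking error,
    de_yI/dt = F_f - F_cmd.
    """
    l1, l2, tau = p.lambda1, p.lambda2, p.tau
    A = np.array([[0.0, 1.0], [0.0, -1.0 / tau]])
    B = np.array([l1 + l2, -l2 / tau])
    B_ref = np.array([-1.0, 0.0])
    C = np.eye(2)
    D = np.array([0.0, l1 + l2])
    return StateSpaceModel(A=A, B=B, B_ref=B_ref, C=C, D=D, params=p)


def dynamic_modulus(p: SLSParameters, omega) -> complex | np.ndarray:
    """Complex stiffness G(i*omega) of the SLS element in uN/um.

    G(iw) = lambda1 + lambda2 * (i w tau) / (1 + i w tau).  The magnitude
    is the force amplitude per unit elongation amplitude under steady
    sinusoidal stretching; the argument is the stress-over-strain phase
    lead.
    """
    omega = np.asarray(omega, float)
    iwt = 1j * omega * p.tau
    G = p.lambda1 + p.lambda2 * iwt / (1.0 + iwt)
    return complex(G) if G.ndim == 0 else G


def discretize(m: StateSpaceModel, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization (Ad, Bd, Bd_ref) via expm."""
    n = 2
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = m.A
    M[:n, n] = m.B
    M[:n, n + 1] = m.B_ref
    E = expm(M * dt)
    return E[:n, :n], E[:n, n], E[:n, n + 1]


def simulate_plant(
    m: StateSpaceModel,
    u_of_t,
    noise: NoiseSpec | None,
    dt: float,
    T: float,
    seed: int | None = 0,
    F_cmd_of_t=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop fixed-step (RK4) simulation of the plant.

    ``u_of_t`` maps time (s) to fiber elongation (um).  Returns
    ``(t, F_f)`` where F_f carries the additive measurement noise if a
    :class:`NoiseSpec` is given.  Deterministic for a fixed seed.
    """
    tau = -1.0 / m.plant_pole
    if dt > tau / 5.0:
        raise ValueError(f"dt={dt} too coarse for tau={tau:.3g} (need dt <= tau/5)")
    if dt > tau / 20.0:
        warnings.warn(f"dt={dt} is coarse relative to tau={tau:.3g}", stacklevel=2)

    n = int(np.floor(T / dt)) + 1
    t = np.arange(n) * dt
    cmd = (lambda tt: 0.0) if F_cmd_of_t is None else F_cmd_of_t

    def deriv(tt, x):
        return m.A @ x + m.B * u_of_t(tt) + m.B_ref * cmd(tt)

    x = np.zeros(2)
    F = np.empty(n)
    for k in range(n):
        F[k] = m.output(x, float(u_of_t(t[k])))[1]
        if k == n - 1:
            break
        h = dt
        k1 = deriv(t[k], x)
        k2 = deriv(t[k] + h / 2, x + h / 2 * k1)
        k3 = deriv(t[k] + h / 2, x + h / 2 * k2)
        k4 = deriv(t[k] + h, x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    if noise is not None and noise.mean_abs_uN > 0:
        rng = np.random.default_rng(seed)
        F = F + noise.draw(rng, n)
    return t, F
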
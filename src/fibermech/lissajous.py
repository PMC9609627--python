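"""Stress-strain analysis of cyclic and ramp loading traces.

Under small-amplitude oscillatory stretching the fiber's stress and
strain are both sinusoids at the command frequency,

    sigma(t) = sigma0 sin(w t + delta),    eps(t) = eps0 sin(w t + phi),

and plotting sigma against eps over a cycle gives an elliptical
Lissajous loop.  The elastic modulus is the amplitude ratio
E_c = sigma0 / eps0 (equivalently the ratio L_y / L_x of the loop's
long-axis projections in amplitude-normalized coordinates), and the
enclosed area, the dissipated energy density per cycle, is
pi sigma0 eps0 |sin(delta - phi)|.

The module also implements the classical constant-rate ramp
("constant-force loading") measurement: an ordinary least-squares slope
of sigma vs eps, with a prefix-window sensitivity report showing how the
slope shrinks as relaxing samples enter the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .mrac import ClosedLoopTrace

__all__ = [
    "FiberSpec",
    "SinusoidFit",
    "LissajousResult",
    "ConstantForceResult",
    "SinusoidFitError",
    "stress_series",
    "strain_series",
    "fit_sinusoid",
    "lissajous_modulus",
    "loop_area_vs_frequency",
    "constant_force_modulus",
    "measure_cyclic",
    "plot_lissajous",
]

_UN_PER_UM2_TO_KPA = 1000.0  # 1 uN/um^2 = 1 MPa


class SinusoidFitError(RuntimeError):
    """Raised for degenerate or non-converged sinusoid fits."""


@dataclass(frozen=True)
class FiberSpec:
    """Fiber cross-section and rest length."""

    cross_section_S_um2: float
    initial_length_L0_um: float

    def __post_init__(self) -> None:
        if self.cross_section_S_um2 <= 0 or self.initial_length_L0_um <= 0:
            raise ValueError("S and L0 must be > 0")

    @classmethod
    def from_diameter(cls, diameter_um: float, L0_um: float) -> "FiberSpec":
        if diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        return cls(np.pi * diameter_um**2 / 4.0, L0_um)


@dataclass(frozen=True)
class SinusoidFit:
    """y(t) = amplitude * sin(2 pi f t + phase) + offset."""

    amplitude: float
    phase_rad: float
    offset: float
    frequency_Hz: float
    rmse: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (-np.pi < self.phase_rad <= np.pi):
            raise ValueError("phase must lie in (-pi, pi]")

    def __call__(self, t):
        return (
            self.amplitude
            * np.sin(2 * np.pi * self.frequency_Hz * np.asarray(t, float) + self.phase_rad)
            + self.offset
        )


@dataclass(frozen=True)
class LissajousResult:
    stress_fit: SinusoidFit
    strain_fit: SinusoidFit
    L_x: float
    L_y: float
    E_c_kPa: float
    loop_area_kPa: float
    phase_lag_rad: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "E_c_kPa": self.E_c_kPa,
                    "loop_area_kPa": self.loop_area_kPa,
                    "phase_lag_rad": self.phase_lag_rad,
                    "L_x": self.L_x,
                    "L_y": self.L_y,
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class ConstantForceResult:
    E_cf_kPa: float
    fit_window: tuple[int, int]
    window_slopes_kPa: tuple[float, ...]  # slope fitted on the first 2, 3, ... samples

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "E_cf_kPa": self.E_cf_kPa,
                    "fit_window": list(self.fit_window),
                    "window_slopes_kPa": list(self.window_slopes_kPa),
                },
                indent=2,
            )
        )


def stress_series(F_f_uN: np.ndarray, fiber: FiberSpec) -> np.ndarray:
    """Engineering stress sigma = F_f / S in kPa."""
    return np.asarray(F_f_uN, float) / fiber.cross_section_S_um2 * _UN_PER_UM2_TO_KPA


def strain_series(
    L_m_um: np.ndarray,
    u_tip_um: np.ndarray | None,
    fiber: FiberSpec,
) -> np.ndarray:
    """Engineering strain eps = (L_m - u_tip) / L0 (dimensionless).

    Passing ``u_tip_um=None`` applies the common approximation of
    equating fiber elongation with manipulator travel (valid when the
    tube deflection is small against the travel).
    """
    L_m = np.asarray(L_m_um, float)
    if u_tip_um is None:
        elong = L_m
    else:
        u_tip = np.asarray(u_tip_um, float)
        if u_tip.shape != L_m.shape:
            raise ValueError("L_m and u_tip must have equal length")
        elong = L_m - u_tip
    return elong / fiber.initial_length_L0_um


def _wrap_phase(phi: float) -> float:
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    return np.pi if phi == -np.pi else phi


def fit_sinusoid(
    t: np.ndarray,
    y: np.ndarray,
    freq_Hz: float | None,
) -> SinusoidFit:
    """Least-squares sinusoid fit.

    With ``freq_Hz`` given the problem is linear in (sin, cos, const)
    coefficients; with ``freq_Hz=None`` the frequency is seeded from the
    periodogram peak and refined by nonlinear least squares.  A signal
    without usable oscillation (amplitude indistinguishable from the
    residual) raises :class:`SinusoidFitError` instead of returning a
    spurious fit.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.shape != y.shape or t.size < 4:
        raise ValueError("need matching t/y arrays with >= 4 samples")

    if freq_Hz is None:
        yc = y - y.mean()
        if np.ptp(yc) < 1e-12 * max(1.0, abs(y.mean())):
            raise SinusoidFitError("constant signal: frequency unidentifiable")
        dt = np.median(np.diff(t))
        freqs = np.fft.rfftfreq(t.size, dt)[1:]
        power = np.abs(np.fft.rfft(yc))[1:]
        k = int(np.argmax(power))
        # parabolic interpolation of the periodogram peak
        if 0 < k < power.size - 1:
            denom = power[k - 1] - 2 * power[k] + power[k + 1]
            shift = 0.5 * (power[k - 1] - power[k + 1]) / denom if denom != 0 else 0.0
            f0 = float(freqs[k] + shift * (freqs[1] - freqs[0]))
        else:
            f0 = float(freqs[k])

        def model(tt, A, f, ph, c):
            return A * np.sin(2 * np.pi * f * tt + ph) + c

        # seed amplitude/phase/offset by the linear solve at f0
        seed_fit = fit_sinusoid(t, y, f0)
        try:
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=[seed_fit.amplitude, f0, seed_fit.phase_rad, seed_fit.offset],
                maxfev=20000,
            )
        except RuntimeError as exc:
            resid = float(np.std(y - y.mean()))
            raise SinusoidFitError(
                f"free-frequency fit did not converge (residual {resid:.3g})"
            ) from exc
        A, f, ph, c = popt
        if A < 0:
            A, ph = -A, ph + np.pi
        resid = y - model(t, A, f, ph, c)
        return SinusoidFit(
            float(A), _wrap_phase(float(ph)), float(c), float(f),
            float(np.sqrt(np.mean(resid**2))),
        )

    w = 2 * np.pi * freq_Hz
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = coef
    A = float(np.hypot(a, b))
    ph = float(np.arctan2(b, a))
    resid = y - X @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SinusoidFit(A, _wrap_phase(ph), float(c), float(freq_Hz), rmse)


def _long_axis_projections(
    sigma0: float, eps0: float, lag: float
) -> tuple[float, float]:
    """Projections (L_x, L_y) of the Lissajous long axis on the axes.

    The loop is traced in amplitude-normalized coordinates
    (sin th, sin(th + lag)); the long-axis endpoint maximizes the
    distance from the loop center and is found numerically, then
    rescaled by the amplitudes.
    """

    def neg_r2(th):
        return -(np.sin(th) ** 2 + np.sin(th + lag) ** 2)

    best = None
    for lo, hi in ((0.0, np.pi / 2), (np.pi / 2, np.pi)):
        res = minimize_scalar(neg_r2, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    th = float(best.x)
    return (
        2.0 * eps0 * abs(np.sin(th)),
        2.0 * sigma0 * abs(np.sin(th + lag)),
    )


def lissajous_modulus(
    stress_fit: SinusoidFit, strain_fit: SinusoidFit
) -> LissajousResult:
    """Elastic modulus and dissipation loop from fitted sinusoids.

    E_c = sigma0 / eps0 (kPa for stress in kPa); the geometric ratio
    L_y / L_x of the normalized-loop long axis is computed as an
    independent cross-check and agrees with the amplitude ratio to
    numerical precision.  Loop area is pi sigma0 eps0 |sin(lag)|.
    """
    if strain_fit.amplitude <= 0:
        raise ValueError("strain amplitude must be > 0")
    f1, f2 = stress_fit.frequency_Hz, strain_fit.frequency_Hz
    if abs(f1 - f2) > 1e-6 * max(f1, f2):
        raise ValueError(f"stress ({f1} Hz) and strain ({f2} Hz) fits disagree")
    lag = _wrap_phase(stress_fit.phase_rad - strain_fit.phase_rad)
    s0, e0 = stress_fit.amplitude, strain_fit.amplitude
    L_x, L_y = _long_axis_projections(s0, e0, lag)
    E_c = s0 / e0
    if not np.isclose(L_y / L_x, E_c, rtol=1e-6):
        raise AssertionError("long-axis projection ratio deviates from sigma0/eps0")
    area = np.pi * s0 * e0 * abs(np.sin(lag))
    return LissajousResult(
        stress_fit=stress_fit,
        strain_fit=strain_fit,
        L_x=L_x,
        L_y=L_y,
        E_c_kPa=E_c,
        loop_area_kPa=area,
        phase_lag_rad=lag,
    )


def loop_area_vs_frequency(
    results: Sequence[LissajousResult], amp_rtol: float = 0.05
) -> dict:
    """Order dissipation-loop areas by frequency.

    All results must share the stress amplitude (within ``amp_rtol``);
    for an SLS fiber below its corner frequency the areas increase with
    frequency (more energy dissipated per cycle).
    """
    if len(results) < 2:
        raise ValueError("need results at >= 2 frequencies")
    amps = np.array([r.stress_fit.amplitude for r in results])
    if np.ptp(amps) > amp_rtol * amps.mean():
        raise ValueError("mixed stress amplitudes; compare equal-amplitude loops")
    order = np.argsort([r.stress_fit.frequency_Hz for r in results])
    freqs = [results[i].stress_fit.frequency_Hz for i in order]
    areas = [results[i].loop_area_kPa for i in order]
    return {
        "frequencies_Hz": freqs,
        "areas_kPa": areas,
        "monotone_nondecreasing": bool(np.all(np.diff(areas) >= 0)),
    }


def constant_force_modulus(
    trace: ClosedLoopTrace,
    fiber: FiberSpec,
    window: tuple[int, int] | None = None,
    use_u_tip: bool = True,
) -> ConstantForceResult:
    """Ramp-loading modulus: OLS slope of stress on strain over a window.

    ``window`` is a (start, stop) sample range; default is the whole
    trace.  The sensitivity report refits the slope on the first 2,
    3, ..., n window samples, mirroring how a slope fitted into the
    relaxing tail under-reports the modulus relative to the early linear
    region.
    """
    sigma = stress_series(trace.F_f, fiber)
    eps = strain_series(trace.L_m, trace.u_tip if use_u_tip else None, fiber)
    i0, i1 = window if window is not None else (0, sigma.size)
    sigma, eps = sigma[i0:i1], eps[i0:i1]
    if sigma.size < 2:
        raise ValueError("fit window must contain >= 2 samples")
    slopes = []
    for k in range(2, sigma.size + 1):
        slope = np.polyfit(eps[:k], sigma[:k], 1)[0]
        slopes.append(float(slope))
    return ConstantForceResult(
        E_cf_kPa=slopes[-1],
        fit_window=(i0, i1),
        window_slopes_kPa=tuple(slopes),
    )


def measure_cyclic(
    trace: ClosedLoopTrace,
    fiber: FiberSpec,
    freq_Hz: float | None = None,
    discard_cycles: float = 1.0,
    use_u_tip: bool = True,
) -> LissajousResult:
    """End-to-end cyclic measurement from a closed-loop trace.

    Discards the first ``discard_cycles`` command periods (transient),
    fits stress and strain sinusoids at the command frequency, and
    returns the Lissajous analysis.
    """
    sigma = stress_series(trace.F_f, fiber)
    eps = strain_series(trace.L_m, trace.u_tip if use_u_tip else None, fiber)
    if freq_Hz is None:
        f_probe = fit_sinusoid(trace.t, sigma, None)
        freq_Hz = f_probe.frequency_Hz
    mask = trace.t >= discard_cycles / freq_Hz
    if mask.sum() < 16:
        raise ValueError("trace too short after discarding the transient")
    sfit = fit_sinusoid(trace.t[mask], sigma[mask], freq_Hz)
    efit = fit_sinusoid(trace.t[mask], eps[mask], freq_Hz)
    return lissajous_modulus(sfit, efit)


def plot_lissajous(result: LissajousResult, path: str | Path) -> None:
    """Save an SVG of the fitted stress-strain loop (normalized axes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    th = np.linspace(0, 2 * np.pi, 400)
    eps = result.strain_fit.amplitude * np.sin(th)
    sig = result.stress_fit.amplitude * np.sin(th + result.phase_lag_rad)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(eps, sig, lw=1.5)
    ax.set_xlabel("strain amplitude component")
    ax.set_ylabel("stress amplitude component (kPa)")
    ax.set_title(
        f"E_c = {result.E_c_kPa:.3g} kPa, "
        f"area = {result.loop_area_kPa:.3g} kPa"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
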
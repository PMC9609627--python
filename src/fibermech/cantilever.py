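"""Euler-Bernoulli model of the sensing tube used as a force transducer.

A thin glass tube clamped at one end acts as a cantilever.  The
microfiber is glued at axial coordinate ``x_a`` (measured from the clamp,
tube length ``L``) and pulls transversally with force ``F``.  The free
tip then deflects by

    u_tip = F * x_a^2 * (3 L - x_a) / (6 E_t I_z),

so a single stiffness constant ``K = F / u_tip`` converts the
vision-measured tip deflection into the stretching force.  Deflections
are stored as magnitudes; the bending direction is tracked separately by
the caller.

Stiffness can also be calibrated against a reference scale: pressing the
tube onto a point support at ``x_a`` gives local stiffness
``K_a = F / u_a``, which refers to the tip as ``K = 2 x_a / (3 L - x_a) * K_a``.
Calibration records at several positions are pooled by fitting the
one-parameter family ``K(x_a) = 6 a / (3 L x_a^2 - x_a^3)`` (``a`` plays
the role of the flexural rigidity E_t I_z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TubeGeometry",
    "TubeStiffness",
    "CalibrationRecord",
    "tip_deflection",
    "stiffness_from_geometry",
    "force_from_tip_deflection",
    "calibrate_stiffness",
    "load_calibration_csv",
]

# unit conversions at the API boundary; internals are SI
_MM = 1e-3
_UN = 1e-6  # uN -> N
_UM = 1e-6  # um -> m


@dataclass(frozen=True)
class TubeGeometry:
    """Sensing-tube geometry and material.

    length_L_mm  : tube length from clamp to free tip
    attach_xa_mm : glue position of the fiber, 0 < x_a <= L
    modulus_Et_Pa: Young's modulus of the tube material
    inertia_Iz_m4: area moment of inertia of the cross-section
    """

    length_L_mm: float
    attach_xa_mm: float
    modulus_Et_Pa: float
    inertia_Iz_m4: float

    def __post_init__(self) -> None:
        for name in ("length_L_mm", "attach_xa_mm", "modulus_Et_Pa", "inertia_Iz_m4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.attach_xa_mm > self.length_L_mm:
            raise ValueError("attach_xa_mm must not exceed length_L_mm")

    @property
    def flexural_rigidity(self) -> float:
        """E_t * I_z in N m^2."""
        return self.modulus_Et_Pa * self.inertia_Iz_m4


@dataclass(frozen=True)
class TubeStiffness:
    K_uN_per_um: float
    fit_param_a: float | None = None
    goodness_R2: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.K_uN_per_um) or self.K_uN_per_um <= 0:
            raise ValueError("K must be finite and > 0")
        if self.goodness_R2 is not None and self.goodness_R2 > 1:
            raise ValueError("R^2 cannot exceed 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "K_uN_per_um": self.K_uN_per_um,
                    "fit_param_a": self.fit_param_a,
                    "r2": self.goodness_R2,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TubeStiffness":
        d = json.loads(Path(path).read_text())
        return cls(d["K_uN_per_um"], d.get("fit_param_a"), d.get("r2"))


@dataclass(frozen=True)
class CalibrationRecord:
    """One point of the reference-scale calibration."""

    x_a_mm: float
    applied_force_uN: float
    deflection_ua_um: float

    def __post_init__(self) -> None:
        if self.x_a_mm <= 0:
            raise ValueError("x_a must be > 0")
        if self.applied_force_uN < 0 or self.deflection_ua_um < 0:
            raise ValueError("force and deflection share a >= 0 sign convention")


def tip_deflection(force_uN: float, geom: TubeGeometry) -> float:
    """Tip deflection magnitude (um) under a point load at the glue position."""
    if not np.isfinite(force_uN) or force_uN < 0:
        raise ValueError(f"force must be finite and >= 0, got {force_uN!r}")
    F = force_uN * _UN
    xa = geom.attach_xa_mm * _MM
    L = geom.length_L_mm * _MM
    u = F * xa**2 * (3.0 * L - xa) / (6.0 * geom.flexural_rigidity)
    return u / _UM


def stiffness_from_geometry(geom: TubeGeometry) -> TubeStiffness:
    """Tip-deflection stiffness K = F / u_tip (uN/um) from geometry alone."""
    u = tip_deflection(1.0, geom)  # um per uN
    return TubeStiffness(K_uN_per_um=1.0 / u, fit_param_a=geom.flexural_rigidity)


def force_from_tip_deflection(
    u_tip_um: float, K_uN_per_um: float
) -> tuple[float, bool]:
    """Force F_f = K * u_tip (uN).

    Returns ``(force, compression_flag)``: negative deflections are
    allowed (tube bent toward the fiber) and flagged rather than
    rejected.
    """
    if not np.isfinite(K_uN_per_um) or K_uN_per_um <= 0:
        raise ValueError("K must be finite and > 0")
    return K_uN_per_um * u_tip_um, u_tip_um < 0


def _family_K(x_a_mm: np.ndarray, a: float, L_mm: float) -> np.ndarray:
    """K(x_a) = 6 a / (3 L x_a^2 - x_a^3), lengths in mm, K in uN/um.

    Reduces exactly to the geometric stiffness when a = E_t I_z expressed
    in the mm/uN-per-um unit system.
    """
    return 6.0 * a / (3.0 * L_mm * x_a_mm**2 - x_a_mm**3)


def calibrate_stiffness(
    records: Sequence[CalibrationRecord],
    geom_L_mm: float,
    x_a_eval_mm: float | None = None,
) -> TubeStiffness:
    """Fit the tip stiffness family to reference-scale calibration data.

    Each record's local stiffness K_a = F / u_a at x_a is referred to the
    tip with the geometric factor 2 x_a / (3 L - x_a), then the single
    parameter ``a`` of K(x_a) = 6 a / (3 L x_a^2 - x_a^3) is fitted by
    least squares.  The returned stiffness is evaluated at
    ``x_a_eval_mm`` (default: the largest calibrated x_a, i.e. the glue
    position closest to the tip).
    """
    if geom_L_mm <= 0:
        raise ValueError("geom_L_mm must be > 0")
    x = np.array([r.x_a_mm for r in records], float)
    F = np.array([r.applied_force_uN for r in records], float)
    ua = np.array([r.deflection_ua_um for r in records], float)
    if np.unique(x).size < 3:
        raise ValueError("need records at >= 3 distinct x_a positions")
    if np.any(F <= 0) or np.any(ua <= 0):
        raise ValueError("calibration requires strictly positive forces/deflections")
    if np.any(x > geom_L_mm):
        raise ValueError("x_a beyond tube length")

    K_tip = (2.0 * x / (3.0 * geom_L_mm - x)) * (F / ua)

    # linear least squares in a: K_i ~ a * h_i, h_i = 6 / (3 L x^2 - x^3)
    h = 6.0 / (3.0 * geom_L_mm * x**2 - x**3)
    a = float((K_tip @ h) / (h @ h))
    resid = K_tip - a * h
    ss_res = float(resid @ resid)
    ss_tot = float(((K_tip - K_tip.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)

    x_eval = float(np.max(x)) if x_a_eval_mm is None else float(x_a_eval_mm)
    if not 0 < x_eval <= geom_L_mm:
        raise ValueError("evaluation position outside (0, L]")
    K_eval = float(_family_K(np.array([x_eval]), a, geom_L_mm)[0])
    return TubeStiffness(K_uN_per_um=K_eval, fit_param_a=a, goodness_R2=r2)


def load_calibration_csv(path: str | Path) -> list[CalibrationRecord]:
    """Read records from CSV with header ``x_a_mm,force_uN,deflection_um``."""
    df = pd.read_csv(path)
    required = ["x_a_mm", "force_uN", "deflection_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"calibration file missing columns: {missing}")
    return [
        CalibrationRecord(r.x_a_mm, r.force_uN, r.deflection_um)
        for r in df.itertuples()
    ]
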
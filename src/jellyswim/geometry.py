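"""Bell geometry: areas, volumes, masses and shape coefficients.

The medusa bell is modeled as an oblate hemiellipsoid of revolution with
semi-axes (d_t/2, d_t/2, h_t); the subumbrellar cavity is a coaxial
hemiellipsoid whose height is reduced by the manubrium tissue height h_j.
All quantities are CGS (cm, g, s; forces in dyn).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Morphology",
    "Environment",
    "subumbrellar_volume",
    "body_volume",
    "projected_area",
    "subumbrellar_area",
    "added_mass_coefficient",
    "fineness_ratio",
    "body_mass",
]


@dataclass(frozen=True)
class Morphology:
    """Relaxed bell geometry and pulse amplitudes of one animal.

    Parameters
    ----------
    d_r : float
        Relaxed bell diameter (cm).
    delta_d : float
        Maximum diameter change from relaxed to contracted state (cm).
    h_r : float
        Relaxed bell height (cm).
    delta_h : float
        Maximum height change from contracted to relaxed state (cm).
    h_j : float
        Manubrium (apical tissue) height reducing cavity depth (cm).
    rho_j : float
        Jellyfish tissue density (g cm^-3). Defaults to seawater density:
        the field system is ballasted neutrally buoyant.
    """

    d_r: float
    delta_d: float
    h_r: float
    delta_h: float
    h_j: float
    rho_j: float = 1.024

    def __post_init__(self) -> None:
        for name in ("d_r", "delta_d", "h_r", "delta_h", "h_j", "rho_j"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.d_r <= 0 or self.h_r <= 0:
            raise ValueError("relaxed bell dimensions must be positive")
        if self.delta_d < 0 or self.delta_h < 0:
            raise ValueError("pulse amplitudes must be non-negative")
        if self.delta_d >= self.d_r:
            raise ValueError("delta_d must be smaller than d_r")
        if self.h_j < 0 or self.h_j >= self.h_r:
            raise ValueError("h_j must satisfy 0 <= h_j < h_r")
        if self.rho_j <= 0:
            raise ValueError("rho_j must be positive")


@dataclass(frozen=True)
class Environment:
    """Ambient fluid properties and drag model constants.

    rho_w is seawater density at 35 ppt, 21 degC; C_d the (Reynolds-number
    fixed) drag coefficient; g_net the net gravitational-minus-buoyant
    acceleration (cm s^-2), zero for a neutrally ballasted system.
    """

    rho_w: float = 1.024
    C_d: float = 0.42
    g_net: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_w <= 0:
            raise ValueError("rho_w must be positive")
        if self.C_d < 0:
            raise ValueError("C_d must be non-negative")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value)
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be positive and finite")


def subumbrellar_volume(h_t, d_t, h_j):
    """Subumbrellar cavity volume V_sub (cm^3).

    Hemiellipsoidal cavity of diameter d_t and height max(h_t - h_j, 0):
    V_sub = (2/3) pi (d_t/2)^2 (h_t - h_j).
    """
    _require_positive(h_t=h_t, d_t=d_t)
    if np.any(np.asarray(h_j) < 0):
        raise ValueError("h_j must be non-negative")
    cavity = np.maximum(np.asarray(h_t) - h_j, 0.0)
    out = (2.0 / 3.0) * np.pi * (np.asarray(d_t) / 2.0) ** 2 * cavity
    return out if out.ndim else float(out)


def body_volume(h_t, d_t):
    """Bell (body) volume V_j = (2/3) pi (d_t/2)^2 h_t (cm^3)."""
    _require_positive(h_t=h_t, d_t=d_t)
    out = (2.0 / 3.0) * np.pi * (np.asarray(d_t) / 2.0) ** 2 * np.asarray(h_t)
    return out if out.ndim else float(out)


def projected_area(d_t):
    """Frontal projected bell area A_j = pi (d_t/2)^2 (cm^2)."""
    _require_positive(d_t=d_t)
    out = np.pi * (np.asarray(d_t) / 2.0) ** 2
    return out if out.ndim else float(out)


def subumbrellar_area(d_t):
    """Subumbrellar orifice area A_sub (cm^2) at the instantaneous diameter.

    The propulsive jet exits through the circular bell opening, so A_sub is
    read as the orifice disc pi (d_t/2)^2 rather than the cavity's curved
    surface.
    """
    _require_positive(d_t=d_t)
    out = np.pi * (np.asarray(d_t) / 2.0) ** 2
    return out if out.ndim else float(out)


def added_mass_coefficient(h_t, d_t):
    """Acceleration-reaction shape coefficient alpha = (2 h_t / d_t)^1.4.

    Equals 1 for a hemisphere (2 h_t = d_t); < 1 for oblate bells.
    """
    _require_positive(h_t=h_t, d_t=d_t)
    out = (2.0 * np.asarray(h_t) / np.asarray(d_t)) ** 1.4
    return out if out.ndim else float(out)


def fineness_ratio(h_t, d_t):
    """Bell fineness ratio h_t / d_t (dimensionless)."""
    _require_positive(h_t=h_t, d_t=d_t)
    out = np.asarray(h_t) / np.asarray(d_t)
    return out if out.ndim else float(out)


def body_mass(rho_j, V_j):
    """Jellyfish mass m_j = rho_j * V_j (g), the inertial mass in the
    momentum balance."""
    _require_positive(rho_j=rho_j, V_j=V_j)
    out = np.asarray(rho_j) * np.asarray(V_j)
    return out if out.ndim else float(out)
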
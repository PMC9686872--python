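"""Logarithmic wind profile and per-internode drag.

Open-terrain logarithmic profile u(z) = u(h0) ln(z/z0) / ln(h0/z0) with the
meteorological reference height h0 = 10 m and roughness length z0 = 0.06 h0.
The profile is clamped to zero below z0, where the logarithm would turn
negative.  Drag on an internode uses its frontal area 2 l r |sin chi| (chi =
angle between internode axis and wind direction):

    F = 1/2 rho_air C_d A u(z)^2

applied as a distributed load F / l along the wind direction.  Leaves carry
weight but no drag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class WindField:
    u_ref: float  # speed at the reference height (m s^-1)
    h0: float = 10.0  # reference height (m)
    z0_ratio: float = 0.06  # roughness length as a fraction of h0
    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    rho_air: float = 1.226  # kg m^-3 (15 degC)
    Cd: float = 0.25  # drag coefficient of stem sections
    # crown drag: leaves reconfigure (streamline) in wind, so their
    # effective drag coefficient is below the bluff-body value; 0 disables
    Cd_leaf: float = 0.2

    def __post_init__(self) -> None:
        if self.u_ref < 0:
            raise ValueError("u_ref must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("wind direction must be a nonzero vector")
        self.direction = d / n
        if self.z0 >= self.h0:
            raise ValueError("roughness length must be below the reference height")

    @property
    def z0(self) -> float:
        return self.z0_ratio * self.h0

    @classmethod
    def from_azimuth(cls, u_ref: float, azimuth_deg: float = 0.0, **kw) -> "WindField":
        phi = math.radians(azimuth_deg)
        return cls(u_ref=u_ref, direction=np.array([math.cos(phi), math.sin(phi), 0.0]), **kw)


def wind_speed_at(z: float, wf: WindField) -> float:
    """Wind speed (m s^-1) at height ``z``; zero at and below the roughness length."""
    if z <= wf.z0:
        return 0.0
    return wf.u_ref * math.log(z / wf.z0) / math.log(wf.h0 / wf.z0)


def wind_speed_profile(z: np.ndarray, wf: WindField) -> np.ndarray:
    """Vectorized ``wind_speed_at``."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    mask = z > wf.z0
    out[mask] = wf.u_ref * np.log(z[mask] / wf.z0) / math.log(wf.h0 / wf.z0)
    return out


def drag_force(
    length: float,
    radius: float,
    axis_direction: np.ndarray,
    mid_height: float,
    wf: WindField,
) -> np.ndarray:
    """Drag force vector (N) on one internode, directed along the wind.

    Invariant under reversal of the internode axis (only |sin chi| enters).
    """
    if length < 0 or radius < 0:
        raise ValueError("length and radius must be >= 0")
    d = np.asarray(axis_direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        return np.zeros(3)
    cos_chi = float(np.dot(d / nd, wf.direction))
    sin_chi = math.sqrt(max(0.0, 1.0 - cos_chi * cos_chi))
    area = 2.0 * length * radius * sin_chi
    u = wind_speed_at(mid_height, wf)
    return 0.5 * wf.rho_air * wf.Cd * area * u * u * wf.direction


def leaf_drag_forces(
    blade_areas_m2: np.ndarray,
    heights: np.ndarray,
    wf: WindField,
) -> np.ndarray:
    """Drag force (N) on the leaf clusters borne at each node.

    Fluttering blades present no fixed angle of attack, so the load uses
    the one-sided blade area scaled by the reconfiguration-reduced
    ``Cd_leaf``, along the wind direction.
    """
    u = wind_speed_profile(heights, wf)
    mag = 0.5 * wf.rho_air * wf.Cd_leaf * blade_areas_m2 * u * u
    return mag[:, None] * wf.direction[None, :]


def drag_forces(
    lengths: np.ndarray,
    radii: np.ndarray,
    dirs: np.ndarray,
    mid_heights: np.ndarray,
    wf: WindField,
) -> np.ndarray:
    """Vectorized drag force (N), one row per internode."""
    cos_chi = dirs @ wf.direction
    sin_chi = np.sqrt(np.clip(1.0 - cos_chi**2, 0.0, None))
    area = 2.0 * lengths * radii * sin_chi
    u = wind_speed_profile(mid_heights, wf)
    mag = 0.5 * wf.rho_air * wf.Cd * area * u * u
    return mag[:, None] * wf.direction[None, :]
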
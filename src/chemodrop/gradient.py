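"""Steady-state transverse gradient in a parallel-flow laminar channel.

Three co-flowing streams (buffer / cells / chemoeffector) merge in a wide,
shallow main channel.  At the Peclet numbers of interest (Pe = v*w/D ~ 180)
axial diffusion is negligible and the steady concentration field obeys the
parabolic transport equation

    u(y) * dc/dx = D * d^2c/dy^2,

i.e. the inlet step profile diffuses transversally as it is advected
downstream, so axial position x plays the role of time.  The solver marches
this equation with an unconditionally stable theta-scheme (Crank-Nicolson
with a short fully-implicit start-up to damp the inlet step) and a
tridiagonal transverse solve per x-step, with no-flux walls.

Depth-averaged 2D (x, y): the gradient of interest is transverse, and
cross-sections are what the device's fluorescence imaging reads out.
Concentrations are normalised to the maximum inlet value; physical units
belong to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "ChannelGeometry",
    "FlowConfig",
    "GradientField",
    "mean_velocity",
    "exposure_displacement",
    "solve_steady_gradient",
    "cross_section_profile",
    "mass_flux",
    "rise_width_10_90",
    "peclet_number",
]

#: diffusivity of fluorescein (MW 372) in water, cm^2/s — the model chemoeffector
FLUORESCEIN_D_CM2_S = 4.9e-6

_UM2_PER_CM2 = 1e8
_UM3_PER_UL = 1e9


@dataclass(frozen=True)
class ChannelGeometry:
    """Main-channel geometry in micrometres.

    Defaults are the sorter described here: a 100 um cell inlet flanked by
    two 1.0 mm buffer inlets merging into a 2.1 mm wide, 100 um deep,
    5 mm long channel.
    """

    width_total: float = 2100.0
    width_middle_inlet: float = 100.0
    width_side_inlet: float = 1000.0
    depth: float = 100.0
    length: float = 5000.0

    def __post_init__(self) -> None:
        for name in ("width_total", "width_middle_inlet", "width_side_inlet", "depth", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isclose(
            2 * self.width_side_inlet + self.width_middle_inlet, self.width_total
        ):
            raise ValueError("inlet widths must sum to the total channel width")


@dataclass(frozen=True)
class FlowConfig:
    """Inlet/outlet volumetric flow rates in uL/min."""

    q_side_each: float = 0.25
    q_middle: float = 0.025
    q_waste_outlet: float = 0.25

    def __post_init__(self) -> None:
        for name in ("q_side_each", "q_middle", "q_waste_outlet"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.q_waste_outlet > self.q_total:
            raise ValueError("waste outlet flow cannot exceed total flow")

    @property
    def q_total(self) -> float:
        return 2 * self.q_side_each + self.q_middle

    @property
    def inlet_fractions(self) -> tuple[float, float, float]:
        """Flow fractions (left, middle, right) — the merged stream widths."""
        q = self.q_total
        return (self.q_side_each / q, self.q_middle / q, self.q_side_each / q)

    @property
    def waste_fraction(self) -> float:
        return self.q_waste_outlet / self.q_total


@dataclass
class GradientField:
    """Solved concentration field c(x, y), normalised to the inlet maximum.

    ``concentration`` has shape (nx, ny); ``y`` holds cell-centre transverse
    positions and ``velocity_profile`` the axial velocity (um/s) at those
    centres.
    """

    concentration: np.ndarray
    x: np.ndarray
    y: np.ndarray
    diffusivity_cm2_s: float
    velocity_profile: np.ndarray
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    flow: FlowConfig = field(default_factory=FlowConfig)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])


def mean_velocity(geom: ChannelGeometry, q_total_ul_min: float) -> float:
    """Cross-section mean axial velocity in um/s for a flow rate in uL/min."""
    if q_total_ul_min < 0:
        raise ValueError("flow rate must be non-negative")
    q_um3_s = q_total_ul_min * _UM3_PER_UL / 60.0
    return q_um3_s / (geom.width_total * geom.depth)


def exposure_displacement(velocity_um_s: float, exposure_ms: float) -> float:
    """Distance (um) a cell is advected during one camera exposure."""
    if velocity_um_s < 0 or exposure_ms < 0:
        raise ValueError("velocity and exposure must be non-negative")
    return velocity_um_s * exposure_ms / 1000.0


def peclet_number(geom: ChannelGeometry, flow: FlowConfig, diffusivity_cm2_s: float) -> float:
    v = mean_velocity(geom, flow.q_total)
    if diffusivity_cm2_s == 0:
        return float("inf")
    return v * geom.width_total / (diffusivity_cm2_s * _UM2_PER_CM2)


def _velocity_profile(geom: ChannelGeometry, v_mean: float, y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "plug":
        return np.full_like(y, v_mean)
    if kind == "laminar":
        # parabolic across the width (side-wall drag); mean preserved
        xi = 2.0 * y / geom.width_total - 1.0
        return 1.5 * v_mean * (1.0 - xi**2)
    raise ValueError(f"unknown velocity profile {kind!r}")


def _inlet_profile(
    flow: FlowConfig, inlet_concentrations: tuple[float, float, float], y: np.ndarray, width: float
) -> np.ndarray:
    # merged stream widths follow the flow split, not the physical inlet widths
    fracs = np.array(flow.inlet_fractions)
    edges = np.concatenate([[0.0], np.cumsum(fracs)]) * width
    c0 = np.empty_like(y)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, 2)
    c0[:] = np.asarray(inlet_concentrations, dtype=float)[idx]
    return c0


def solve_steady_gradient(
    geom: ChannelGeometry | None = None,
    flow: FlowConfig | None = None,
    diffusivity_cm2_s: float = FLUORESCEIN_D_CM2_S,
    inlet_concentrations: tuple[float, float, float] = (0.0, 0.0, 1.0),
    dy: float = 5.0,
    dx: float = 10.0,
    velocity: str = "plug",
    theta: float = 0.5,
    startup_steps: int = 4,
) -> GradientField:
    """March the steady transport equation downstream from the inlet step.

    Parameters
    ----------
    inlet_concentrations:
        Normalised concentration carried by the (left, middle, right) inlet
        streams; the chemoeffector enters on the right by convention.
    dy, dx:
        Grid spacings in um (transverse cells are centre-positioned).
    velocity:
        ``"plug"`` (uniform, the depth-averaged default) or ``"laminar"``
        (parabolic across the width).
    theta:
        Implicitness of the marching scheme; 0.5 is Crank-Nicolson and the
        first ``startup_steps`` steps are taken fully implicit to damp the
        discontinuous inlet profile.
    """
    geom = geom or ChannelGeometry()
    flow = flow or FlowConfig()
    if dy <= 0 or dx <= 0:
        raise ValueError("grid spacings must be positive")
    if not 0.5 <= theta <= 1.0:
        raise ValueError("theta must lie in [0.5, 1] for stability")
    narrowest = min(flow.inlet_fractions) * geom.width_total
    if dy > narrowest:
        raise ValueError(
            f"grid too coarse: dy={dy} um cannot resolve the narrowest merged "
            f"stream ({narrowest:.1f} um); refine dy"
        )
    pe = peclet_number(geom, flow, diffusivity_cm2_s)
    if pe < 10:
        warnings.warn(
            f"Peclet number {pe:.1f} < 10: neglected axial diffusion is not negligible",
            RuntimeWarning,
            stacklevel=2,
        )

    ny = int(round(geom.width_total / dy))
    nx = int(round(geom.length / dx)) + 1
    y = (np.arange(ny) + 0.5) * dy
    x = np.arange(nx) * dx
    v_mean = mean_velocity(geom, flow.q_total)
    u = _velocity_profile(geom, v_mean, y, velocity)
    d_um = diffusivity_cm2_s * _UM2_PER_CM2

    c = np.empty((nx, ny))
    c[0] = _inlet_profile(flow, inlet_concentrations, y, geom.width_total)

    # r_j = D*dx / (u_j*dy^2): the per-step diffusion number seen by stream j
    r = d_um * dx / (u * dy * dy)

    def banded_matrix(th: float) -> np.ndarray:
        ab = np.zeros((3, ny))
        ab[0, 1:] = -th * r[:-1]  # superdiagonal (row j couples to j+1)
        ab[2, :-1] = -th * r[1:]  # subdiagonal
        main = 1.0 + 2.0 * th * r
        main[0] = 1.0 + th * r[0]  # no-flux mirror at the walls
        main[-1] = 1.0 + th * r[-1]
        ab[1] = main
        return ab

    def explicit_part(cn: np.ndarray, th: float) -> np.ndarray:
        w = (1.0 - th) * r
        lapc = np.empty_like(cn)
        lapc[1:-1] = cn[2:] - 2.0 * cn[1:-1] + cn[:-2]
        lapc[0] = cn[1] - cn[0]
        lapc[-1] = cn[-2] - cn[-1]
        return cn + w * lapc

    ab_cn = banded_matrix(theta)
    ab_impl = banded_matrix(1.0)
    for i in range(1, nx):
        th = 1.0 if i <= startup_steps else theta
        ab = ab_impl if th == 1.0 else ab_cn
        rhs = explicit_part(c[i - 1], th)
        c[i] = solve_banded((1, 1), ab, rhs)

    return GradientField(
        concentration=c,
        x=x,
        y=y,
        diffusivity_cm2_s=diffusivity_cm2_s,
        velocity_profile=u,
        geometry=geom,
        flow=flow,
    )


def cross_section_profile(fieldobj: GradientField, x_um: float) -> np.ndarray:
    """Concentration profile c(y) at axial position ``x_um``, linearly interpolated."""
    if not 0 <= x_um <= fieldobj.x[-1]:
        raise ValueError(f"x={x_um} um outside the solved channel length")
    i = np.searchsorted(fieldobj.x, x_um)
    if i == 0 or np.isclose(fieldobj.x[i - 1], x_um):
        return fieldobj.concentration[max(i - 1, 0)].copy()
    if np.isclose(fieldobj.x[min(i, len(fieldobj.x) - 1)], x_um):
        return fieldobj.concentration[min(i, len(fieldobj.x) - 1)].copy()
    x0, x1 = fieldobj.x[i - 1], fieldobj.x[i]
    w = (x_um - x0) / (x1 - x0)
    return (1 - w) * fieldobj.concentration[i - 1] + w * fieldobj.concentration[i]


def mass_flux(fieldobj: GradientField) -> np.ndarray:
    """Transverse integral of c*u at every axial station (conserved along x)."""
    return fieldobj.concentration @ fieldobj.velocity_profile * fieldobj.dy


def rise_width_10_90(profile: np.ndarray, y: np.ndarray) -> float:
    """Transverse distance over which a monotone profile rises from 10% to 90%."""
    lo, hi = profile.min(), profile.max()
    if hi - lo <= 0:
        return 0.0
    norm = (profile - lo) / (hi - lo)
    y10 = float(np.interp(0.1, norm, y))
    y90 = float(np.interp(0.9, norm, y))
    return abs(y90 - y10)
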
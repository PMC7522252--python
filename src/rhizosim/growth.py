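"""Tip-level growth rules: elongation, tropisms and branching traits.

The substrate opposes tip advance with a penetration resistance (kPa)

    ln R = 0.35 log10(|psi| Se) + 0.93 rho_b + 1.26

(an empirical fit over soils of varying density and composition), which
reduces the genetically set maximum elongation rate:

    E = E_max ( 1 - R_ave / (4000 + 2.33 |psi|) ),   clamped to [0, E_max],

with the water potential psi in kPa.  The new growth direction is a
weighted, normalised sum of the (randomly rotated) previous direction, the
gravity unit vector scaled by the geotropism weight W_g, and the unit
vector pointing down the penetration-resistance gradient scaled by W_r —
roots steer towards softer, wetter substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil import SoilGrid, WaterState, VanGenuchtenSoil, _se_of_h

__all__ = [
    "AxisSpec", "GrowthTraits", "GRAVITY", "HEAD_TO_KPA",
    "penetration_resistance", "resistance_field", "resistance_gradient_at",
    "elongation_rate", "rotate", "direction_update", "sample_deviation",
    "DirectionDegeneracyError",
]

#: unit gravity vector in the x-z growth plane (z up)
GRAVITY = np.array([0.0, -1.0])
#: kPa per cm of water column
HEAD_TO_KPA = 0.09806


class DirectionDegeneracyError(RuntimeError):
    """The weighted direction sum vanished; reports the offending weights."""


@dataclass(frozen=True)
class AxisSpec:
    """Scheduled emergence of one first-order axis from the seed.

    ``angle`` is measured from vertical-down, positive towards +x, so 0
    means an axis germinating straight down.
    """

    time: float
    angle: float = 0.0

    @property
    def direction(self) -> np.ndarray:
        a = np.radians(self.angle)
        return np.array([np.sin(a), -np.cos(a)])


@dataclass
class GrowthTraits:
    """Genetic input parameters of the simulated plant.

    Elongation tables are ``(age_day, rate_cm_per_day)`` breakpoints,
    linearly interpolated and clamped outside their range; axes decline
    with age while laterals elongate at a constant rate.  Calibrated wheat
    defaults: branching angle 32.55 deg, branch spacing 0.3 cm, tip delay
    2.1 d, W_g = 0.1, W_r = 0.45, delta = 35 deg.
    """

    axes: list = field(default_factory=lambda: [AxisSpec(0.0, 0.0)])
    elongation_axis: list = field(
        default_factory=lambda: [(0.0, 2.0), (3.5, 0.5)])
    elongation_lateral: list = field(default_factory=lambda: [(0.0, 0.5)])
    branching_angle: float = 32.55    # deg
    branch_spacing: float = 0.3       # cm
    tip_delay: float = 2.1            # day
    max_order: int = 3
    w_g: float = 0.1
    w_r: float = 0.45
    delta: float = 35.0               # deg, max random deviation

    def __post_init__(self) -> None:
        if self.w_g < 0 or self.w_r < 0:
            raise ValueError("W_g and W_r must be non-negative")
        if not (0 <= self.delta < 90):
            raise ValueError("delta must lie in [0, 90)")
        if self.branch_spacing <= 0:
            raise ValueError("branch spacing must be positive")
        if self.tip_delay < 0:
            raise ValueError("tip delay must be non-negative")
        times = [a.time for a in self.axes]
        if len(set(times)) < len(times) and len(self.axes) != len(
                {(a.time, a.angle) for a in self.axes}):
            raise ValueError("duplicate axis schedule entries")
        for table in (self.elongation_axis, self.elongation_lateral):
            if any(r < 0 for _, r in table):
                raise ValueError("elongation rates must be non-negative")

    def elongation_max(self, order: int, age: float) -> float:
        table = self.elongation_axis if order == 1 else self.elongation_lateral
        ages, rates = zip(*table)
        return float(np.interp(age, ages, rates))


def penetration_resistance(psi, se, rho_b, eps: float = 1e-6):
    """Substrate penetration resistance R in kPa (clamped near saturation)."""
    psi = np.abs(np.asarray(psi, dtype=float))
    se = np.asarray(se, dtype=float)
    if np.any(se < -1e-12) or np.any(se > 1 + 1e-12):
        raise ValueError("effective saturation outside [0, 1]")
    if np.any(np.asarray(rho_b) <= 0):
        raise ValueError("bulk density must be positive")
    arg = np.maximum(psi * se, eps)
    return np.exp(0.35 * np.log10(arg) + 0.93 * np.asarray(rho_b) + 1.26)[()]


def resistance_field(grid: SoilGrid, state: WaterState, soils,
                     elem_mat) -> np.ndarray:
    """Per-element penetration resistance from element-mean heads."""
    if isinstance(soils, VanGenuchtenSoil):
        soils = [soils]
    elem_mat = np.asarray(elem_mat)
    h_e = grid.elem_mean(state.h)
    R = np.empty(grid.n_elems)
    for mi, soil in enumerate(soils):
        mask = elem_mat == mi
        if not np.any(mask):
            continue
        se = _se_of_h(h_e[mask], soil)
        psi = HEAD_TO_KPA * h_e[mask]
        R[mask] = penetration_resistance(psi, se, soil.rho_b)
    return R


def resistance_gradient_at(pos, grid: SoilGrid, R_elem: np.ndarray,
                           tol: float = 1e-9) -> np.ndarray:
    """Finite-difference gradient of the elemental R field at a point.

    Returns the zero vector when the field is uniform to within ``tol``.
    Raises for positions outside the domain.
    """
    x, z = float(pos[0]), float(pos[1])
    if not (-1e-9 <= x <= grid.Lx + 1e-9 and -1e-9 <= z <= grid.Lz + 1e-9):
        raise ValueError(f"position ({x}, {z}) outside domain")
    R = np.asarray(R_elem, dtype=float).reshape(grid.nz, grid.nx)
    if grid.nx > 1:
        dRdx = np.gradient(R, grid.dx, axis=1)
    else:
        dRdx = np.zeros_like(R)
    if grid.nz > 1:
        dRdz = np.gradient(R, grid.dz, axis=0)
    else:
        dRdz = np.zeros_like(R)
    gx = grid.interp_elem(dRdx.ravel(), x, z)
    gz = grid.interp_elem(dRdz.ravel(), x, z)
    g = np.array([gx, gz], dtype=float)
    if np.linalg.norm(g) < tol:
        return np.zeros(2)
    return g


def elongation_rate(E_max: float, R_ave: float, psi: float) -> float:
    """Resistance-limited elongation rate, cm/day, clamped to [0, E_max]."""
    if E_max < 0:
        raise ValueError("E_max must be non-negative")
    E = E_max * (1.0 - R_ave / (4000.0 + 2.33 * abs(psi)))
    return float(np.clip(E, 0.0, E_max))


def rotate(d, angle_deg: float) -> np.ndarray:
    """Rotate a 2D vector counter-clockwise by ``angle_deg`` degrees."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    d = np.asarray(d, dtype=float)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def sample_deviation(delta: float, rng: np.random.Generator) -> float:
    """Random deviation angle, uniform on [-delta, +delta] degrees."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta == 0:
        return 0.0
    return float(rng.uniform(-delta, delta))


def direction_update(d_old, g, grad_r, w_g: float, w_r: float,
                     delta_sample: float, w_hist: float = 1.0,
                     grad_tol: float = 1e-9) -> np.ndarray:
    """Weighted-sum growth direction update; returns a unit vector.

    ``d_new = normalize( w_hist * rotate(d_old, delta) + W_g g + W_r u )``
    where ``u`` points opposite the penetration-resistance gradient (roots
    grow towards softer substrate) and is zero for a uniform field.
    """
    d_old = np.asarray(d_old, dtype=float)
    g = np.asarray(g, dtype=float)
    grad_r = np.zeros(2) if grad_r is None else np.asarray(grad_r, dtype=float)
    gn = np.linalg.norm(grad_r)
    u = -grad_r / gn if gn > grad_tol else np.zeros(2)
    v = w_hist * rotate(d_old, delta_sample) + w_g * g + w_r * u
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise DirectionDegeneracyError(
            f"zero resultant direction (w_hist={w_hist}, W_g={w_g}, W_r={w_r})")
    return v / nrm
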
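"""Scenario builders and the synthetic trait/trajectory generator.

The tracings behind the wheat growth experiments exist only as figures, so
this module provides (a) the default wheat trait set and ready-made run
configurations for the two physical setups — the 10 x 10 cm petri dish and
the 4.8 x 6.8 cm rhizobox with an inclined obstacle — and (b) a seeded
generator of synthetic calibration data with the same statistical
structure: axis elongation declining with age, constant lateral elongation,
growth-angle (beta) trajectories with a contact plateau at the obstacle
inclination followed by a recovery whose duration is ``kappa`` times the
contact duration, and network-index time series.  Gaussian noise of
configurable standard deviation can be added to every output.

The beta and index generators double as cheap surrogate simulators for the
calibration grid searches: they emulate the direction-update kinematics and
the branching arithmetic of the full model without the soil FEM, so a grid
sweep runs in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DomainConfig, SimulationConfig
from .growth import GRAVITY, AxisSpec, GrowthTraits, direction_update
from .obstacles import Obstacle

__all__ = ["default_wheat_traits", "petri_config", "obstacle_config",
           "FixtureSpec", "Fixture", "generate_fixture",
           "beta_series_model", "index_series_model", "axis_arc_length"]


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def default_wheat_traits() -> GrowthTraits:
    """Calibrated wheat trait set.

    Branching angle 32.55 deg, branch spacing 0.3 cm, tip delay 2.1 d and
    direction weights W_g = 0.1, W_r = 0.45, delta = 35 deg are the
    calibrated values; the five-axis emergence schedule and the
    elongation-versus-age tables (axes declining 2.0 -> 0.5 cm/day over the
    first 3.5 days, laterals constant at 0.5 cm/day) reproduce the observed
    qualitative pattern at realistic wheat seminal-root rates.
    """
    return GrowthTraits(
        axes=[AxisSpec(0.0, 0.0), AxisSpec(0.5, 30.0), AxisSpec(0.8, -30.0),
              AxisSpec(1.2, 55.0), AxisSpec(1.5, -55.0)],
        elongation_axis=[(0.0, 2.0), (3.5, 0.5)],
        elongation_lateral=[(0.0, 0.5)],
    )


def petri_config(nx: int = 40, nz: int = 40, horizon: float = 6.0,
                 dt: float = 0.05) -> SimulationConfig:
    """The 10 x 10 x 0.2 cm petri-dish calibration scenario.

    Undrained on all sides, hydrostatic initial condition with the water
    table at the bottom, collar transpiration 0.2 cm3/day.
    """
    return SimulationConfig(
        domain=DomainConfig(10.0, 10.0, nx, nz, 0.2),
        traits=default_wheat_traits(),
        seed_pos=(5.0, 9.5), horizon=horizon, dt=dt)


def obstacle_config(eta: float = 45.0, w_oi: float = 5.0, kappa: float = 2.0,
                    nx: int = 32, nz: int = 45, horizon: float = 8.0,
                    dt: float = 0.05, multiple: bool = False) -> SimulationConfig:
    """The 4.8 x 6.8 x 0.08 cm rhizobox scenario with a rigid obstacle.

    A single axis germinates straight down 2 cm above the centre of a 2 cm
    long obstacle inclined at ``eta`` degrees.  The random deviation is
    suppressed (delta = 0) to isolate the obstacle response, and the bottom
    row of nodes is held at zero pressure head (the maintained water table
    of the rhizobox) while all walls stay undrained.
    """
    traits = default_wheat_traits()
    traits.axes = [AxisSpec(0.0, 0.0)]
    traits.delta = 0.0
    traits.max_order = 2
    center = (2.4, 3.8)
    obstacles = [Obstacle(center=center, length=2.0, width=0.2, eta=eta)]
    if multiple:
        obstacles += [Obstacle(center=(1.2, 2.2), length=1.2, width=0.2, eta=-30.0),
                      Obstacle(center=(3.6, 2.0), length=1.2, width=0.2, eta=20.0)]
    return SimulationConfig(
        domain=DomainConfig(4.8, 6.8, nx, nz, 0.08),
        traits=traits,
        obstacles=obstacles,
        seed_pos=(center[0], center[1] + 2.0),
        horizon=horizon, dt=dt,
        bottom_head=0.0,
        w_oi=w_oi, kappa=kappa)


# ---------------------------------------------------------------------------
# kinematic surrogates
# ---------------------------------------------------------------------------

def axis_arc_length(age, table=((0.0, 2.0), (3.5, 0.5))):
    """Arc length grown by an axis of the given age (cm), by integrating
    the piecewise-linear elongation table (clamped outside its range)."""
    age = np.asarray(age, dtype=float)
    ages, rates = zip(*table)
    grid_t = np.linspace(0.0, max(float(np.max(age)), ages[-1]) + 1e-9, 2001)
    rate = np.interp(grid_t, ages, rates)
    arc = np.concatenate([[0.0], np.cumsum(
        0.5 * (rate[1:] + rate[:-1]) * np.diff(grid_t))])
    return np.interp(np.maximum(age, 0.0), grid_t, arc)[()]


def beta_series_model(eta: float, w_oi: float = 5.0, kappa: float = 2.0,
                      w_g: float = 0.1, contact_duration: float = 1.0,
                      t0: float = 1.0, dt: float = 0.05,
                      horizon: float | None = None) -> pd.DataFrame:
    """Growth-angle trajectory of a tip passing an inclined obstacle.

    Emulates the direction-update rule without the soil solve: beta sits at
    the obstacle inclination ``eta`` during contact, then the history term
    (weighted by the linearly vanishing W_o) competes with geotropism until
    the tip is vertical again.  Returns columns ``t``, ``beta`` and attrs
    ``t0``, ``t1``, ``t2``.
    """
    t1 = t0 + contact_duration
    t2 = t1 + kappa * contact_duration
    if horizon is None:
        horizon = t2 + 2.0 * (t2 - t1)
    e = np.radians(eta)
    d = np.array([-np.cos(e), -np.sin(e)])  # sliding down along the edge
    rows = [(t, float(eta)) for t in np.arange(t0, t1 + 1e-9, dt)]
    t = t1 + dt
    while t <= horizon + 1e-9:
        if t < t2:
            w_o = w_oi * (1.0 - (t - t1) / (t2 - t1))
        else:
            w_o = 1.0
        d = direction_update(d, GRAVITY, None, w_g, 0.0, 0.0, w_hist=w_o)
        rows.append((t, float(np.degrees(np.arctan2(abs(d[1]), abs(d[0]))))))
        t += dt
    df = pd.DataFrame(rows, columns=["t", "beta"])
    df.attrs.update(t0=t0, t1=t1, t2=t2)
    return df


def index_series_model(times, tip_delay: float = 2.1, w_g: float = 0.1,
                       w_r: float = 0.45, delta: float = 35.0,
                       traits: GrowthTraits | None = None) -> pd.DataFrame:
    """Network-index time series from branching arithmetic plus a fan model.

    Total length follows the emergence schedule, the elongation tables and
    the branching delay exactly; the foraging area uses a fan half-angle
    that widens with the random deviation and the resistance weight and
    narrows with geotropism.  Deterministic, and sensitive to each of the
    four calibration parameters, which is what a recovery grid search
    needs.
    """
    traits = traits or default_wheat_traits()
    times = np.asarray(times, dtype=float)
    ax_table = tuple(traits.elongation_axis)
    lat_rate = traits.elongation_lateral[0][1]
    spacing, max_lat_age = traits.branch_spacing, None
    total, area, dens = [], [], []
    # half-angle of the explored fan (rad): wider with delta and W_r,
    # narrower with W_g
    sigma = (0.2 + 0.5 * np.radians(delta)) * (1.0 + 0.5 * w_r) / (1.0 + 3.0 * w_g)
    # inverse map: time at which an axis reaches a given arc
    probe_age = np.linspace(0.0, max(times.max(), 8.0), 2001)
    probe_arc = np.atleast_1d(axis_arc_length(probe_age, ax_table))
    for t in times:
        L_ax, L_lat, n_lat, ax12_len, ax12_lat = 0.0, 0.0, 0, 0.0, 0
        for k, ax in enumerate(traits.axes):
            age = t - ax.time
            if age <= 0:
                continue
            arc = float(axis_arc_length(age, ax_table))
            L_ax += arc
            n_bp = int(arc / spacing)
            for j in range(1, n_bp + 1):
                t_create = ax.time + float(np.interp(
                    (j - 1) * spacing, probe_arc, probe_age))
                act = t_create + tip_delay
                if act < t:
                    lat_len = lat_rate * (t - act)
                    L_lat += lat_len
                    n_lat += 1
                    if k < 2:
                        ax12_lat += 1
            if k < 2:
                ax12_len += arc
        total.append(L_ax + L_lat)
        depth = max((float(axis_arc_length(t - ax.time, ax_table))
                     for ax in traits.axes if t > ax.time), default=0.0)
        area.append(0.5 * sigma * depth ** 2 * (1.0 + L_lat / max(L_ax, 1e-9)))
        dens.append(ax12_lat / ax12_len if ax12_len > 0 else 0.0)
    return pd.DataFrame({"t": times, "total_length": total,
                         "foraging_area": area,
                         "branching_density": dens}).set_index("t")


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """What synthetic calibration data to generate, and how noisy."""

    seed: int = 0
    noise_sd: float = 0.0            # relative noise on indices / traits
    beta_noise_sd: float = 0.0       # degrees, on beta trajectories
    etas: tuple = (0.0, 30.0, 45.0)
    kappa: float = 2.0
    w_oi: float = 5.0
    tip_delay: float = 2.1
    w_g: float = 0.1
    w_r: float = 0.45
    delta: float = 35.0
    n_episodes: int = 6
    times: tuple = tuple(np.arange(0.5, 6.01, 0.5))

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.beta_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class Fixture:
    trait_tables: pd.DataFrame          # age, axis_rate, lateral_rate
    beta: dict                          # eta -> DataFrame(t, beta)
    episodes: list                      # (t0, t1, t2) tuples
    indices: pd.DataFrame               # index time series


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Seeded synthetic stand-in for the experimental tracing data."""
    rng = np.random.default_rng(spec.seed)
    traits = default_wheat_traits()
    traits.tip_delay = spec.tip_delay

    ages = np.arange(0.0, 4.01, 0.5)
    ax = np.interp(ages, *zip(*[(a, r) for a, r in traits.elongation_axis]))
    lat = np.full_like(ages, traits.elongation_lateral[0][1])
    if spec.noise_sd > 0:
        ax = ax * (1 + spec.noise_sd * rng.standard_normal(ax.shape))
        lat = lat * (1 + spec.noise_sd * rng.standard_normal(lat.shape))
    trait_tables = pd.DataFrame({"age": ages, "axis_rate": ax,
                                 "lateral_rate": lat})

    episodes = []
    for _ in range(spec.n_episodes):
        contact = rng.uniform(0.4, 1.2)
        t0 = rng.uniform(0.5, 1.5)
        t1 = t0 + contact
        t2 = t1 + spec.kappa * contact
        if spec.noise_sd > 0:
            t2 += spec.noise_sd * rng.standard_normal()
        episodes.append((t0, t1, t2))

    beta = {}
    for eta in spec.etas:
        df = beta_series_model(eta, w_oi=spec.w_oi, kappa=spec.kappa,
                               w_g=spec.w_g)
        if spec.beta_noise_sd > 0:
            df = df.copy()
            df["beta"] = df["beta"] + spec.beta_noise_sd * rng.standard_normal(
                len(df))
        beta[eta] = df

    indices = index_series_model(np.asarray(spec.times),
                                 tip_delay=spec.tip_delay, w_g=spec.w_g,
                                 w_r=spec.w_r, delta=spec.delta, traits=traits)
    if spec.noise_sd > 0:
        noisy = indices * (1 + spec.noise_sd * rng.standard_normal(indices.shape))
        indices = noisy
    return Fixture(trait_tables=trait_tables, beta=beta, episodes=episodes,
                   indices=indices)
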
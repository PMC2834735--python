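"""Run-and-tumble population simulator.

Couples field → receptor → controller → motor → movement per agent on a
0.5 s motor time scale.  Within each interval an agent either runs
forward at constant speed or tumbles in place and reorients; at the end
of the interval the local ligand concentration is read at the new
position, the controller output ([CheY-P]) is updated, and that value
sets the tumble probability for the next interval.

Controllers come in two flavours:

* an LTI :class:`~taxisim.filters.ControllerFilter`, advanced by exact
  zero-order-hold discretization.  Its input is the occupancy *deviation*
  from the occupancy at the initial position (where the controller state
  is at equilibrium); for band-pass controllers the reference is
  immaterial since H(0) = 0, while for low-pass controllers it pins the
  unstimulated operating point at the start position.
* a nonlinear :class:`~taxisim.pathways.DesignedPathway`, integrated by
  fixed-step RK4 with substeps (integration error far below the motor
  stochasticity).  Its [CheY-P] is the pathway state itself; no baseline
  or sign bookkeeping is needed.

All randomness flows from a single integer seed; identical seeds give
bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .fields import ConcentrationField, field_concentration
from .filters import ControllerFilter, zoh_discretize
from .motor import RUN, MotorModel, cw_bias, motor_step
from .pathways import DesignedPathway, designed_derivs, designed_equilibrium

__all__ = ["SimulationConfig", "Bacterium", "PopulationRecord",
           "agent_step", "simulate"]

Controller = Union[ControllerFilter, DesignedPathway]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one population experiment."""

    controller: Controller = field(default_factory=ControllerFilter)
    motor: MotorModel = field(default_factory=MotorModel)
    field_: ConcentrationField = field(default_factory=ConcentrationField)
    n_bacteria: int = 100
    duration: float = 1000.0     # s
    dt: float = 0.5              # s, motor time scale
    speed: float = 0.02          # mm/s run speed
    init_position: tuple = (1.4, 0.0)  # mm
    seed: int = 0
    record_stride: int = 1
    record_positions: bool = False
    reorientation: str = "uniform"   # "uniform" | "wrapped_normal"
    reorient_sd: float = 1.0         # rad, wrapped_normal only
    K_L: float = 1.0                 # µM, occupancy scale for LTI controllers
    pathway_substeps: int = 10       # RK4 substeps per dt (designed pathways)

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of dt")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.n_bacteria < 1:
            raise ValueError("need at least one bacterium")
        if self.reorientation not in ("uniform", "wrapped_normal"):
            raise ValueError(f"unknown reorientation {self.reorientation!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class Bacterium:
    """Single-agent state, used by :func:`agent_step`."""

    position: np.ndarray
    heading: float
    motor_state: int
    controller_state: np.ndarray
    cheyp: float


@dataclass(frozen=True)
class PopulationRecord:
    """Per-step population snapshots of local ligand concentration."""

    times: np.ndarray            # (n_rec,)
    local_L: np.ndarray          # (n_rec, n_agents) µM
    positions: np.ndarray | None  # (n_rec, n_agents, 2) mm, optional
    cheyp: np.ndarray | None     # (n_rec, n_agents) µM, optional
    config: SimulationConfig
    seed: int

    @property
    def n_agents(self) -> int:
        return self.local_L.shape[1]

    def to_frame(self):
        """Long-format table (time_s, agent_id, local_L_uM [, x_mm, y_mm])."""
        import pandas as pd

        n_rec, n = self.local_L.shape
        data = {
            "time_s": np.repeat(self.times, n),
            "agent_id": np.tile(np.arange(n), n_rec),
            "local_L_uM": self.local_L.ravel(),
        }
        if self.positions is not None:
            data["x_mm"] = self.positions[..., 0].ravel()
            data["y_mm"] = self.positions[..., 1].ravel()
        if self.cheyp is not None:
            data["cheyp_uM"] = self.cheyp.ravel()
        return pd.DataFrame(data)


class _LTIBank:
    """Vectorized ZOH-discretized LTI controller for n agents."""

    def __init__(self, filt: ControllerFilter, n: int, u_ref: float, dt: float):
        self.Ad, self.Bd, self.C, self.D = zoh_discretize(filt.tf, dt)
        order = self.Ad.shape[0]
        # deviation input with zero state == equilibrium at occupancy u_ref
        self.X = np.zeros((n, order))
        self.u_ref = u_ref
        self.sign = filt.sign_factor
        self.baseline = filt.baseline

    def step(self, u: np.ndarray) -> np.ndarray:
        du = u - self.u_ref
        self.X = self.X @ self.Ad.T + du[:, None] * self.Bd.ravel()
        y = self.X @ self.C.ravel() + self.D.item() * du
        return np.maximum(self.baseline + self.sign * y, 0.0)

    @property
    def state(self) -> np.ndarray:
        return self.X


class _PathwayBank:
    """Vectorized RK4 integrator for the designed nonlinear pathways."""

    def __init__(self, p: DesignedPathway, n: int, u0: np.ndarray,
                 dt: float, substeps: int):
        self.p = p
        self.h = dt / substeps
        self.substeps = substeps
        u0 = np.broadcast_to(np.asarray(u0, dtype=float), (n,))
        # per-agent equilibrium at the initial occupancy
        self.X = np.column_stack([p.c_v * u0 / p.d_v, _pathway_ystar(p, u0)])

    def step(self, u: np.ndarray) -> np.ndarray:
        X = self.X
        h = self.h
        f = lambda z: np.asarray(designed_derivs(z, u, self.p))
        for _ in range(self.substeps):
            k1 = f(X)
            k2 = f(X + 0.5 * h * k1)
            k3 = f(X + 0.5 * h * k2)
            k4 = f(X + h * k3)
            X = X + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        self.X = X
        return np.maximum(X[:, 1], 0.0)

    @property
    def state(self) -> np.ndarray:
        return self.X


def _pathway_ystar(p: DesignedPathway, u):
    """Vectorized equilibrium [CheY-P] of a designed pathway."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty_like(u)
    for i, ui in enumerate(u):
        out[i] = designed_equilibrium(float(ui), p)[1]
    return out


def _make_bank(config: SimulationConfig, n: int, u0: np.ndarray):
    c = config.controller
    if isinstance(c, ControllerFilter):
        return _LTIBank(c, n, float(np.mean(u0)), config.dt)
    if isinstance(c, DesignedPathway):
        return _PathwayBank(c, n, u0, config.dt, config.pathway_substeps)
    raise TypeError(f"unsupported controller {type(c).__name__}")


def _occupancy(config: SimulationConfig, L):
    c = config.controller
    if isinstance(c, DesignedPathway):
        K_L = c.receptor.K_L
    else:
        K_L = config.K_L
    return np.asarray(L) / (np.asarray(L) + K_L)


def _reorient(heading, config: SimulationConfig, rng):
    if config.reorientation == "uniform":
        return rng.uniform(0.0, 2 * np.pi, size=np.shape(heading))
    defl = rng.normal(0.0, config.reorient_sd, size=np.shape(heading))
    return np.mod(heading + defl, 2 * np.pi)


def agent_step(b: Bacterium, config: SimulationConfig,
               rng: np.random.Generator, bank=None) -> Bacterium:
    """Advance one agent by one motor interval.

    Ordering within the step: if the motor is in the run state, displace
    by speed·dt along the heading, otherwise reorient in place; read the
    local [L] at the end-of-interval position and convert to occupancy;
    advance the controller over dt to obtain [CheY-P]; finally draw the
    motor state for the next interval from the fresh [CheY-P].
    """
    if bank is None:
        L0 = field_concentration(config.field_, config.init_position)
        bank = _make_bank(config, 1, np.atleast_1d(_occupancy(config, L0)))
        bank.X = np.atleast_2d(b.controller_state).astype(float)
    pos = np.array(b.position, dtype=float)
    heading = b.heading
    if b.motor_state == RUN:
        pos = pos + config.speed * config.dt * np.array(
            [np.cos(heading), np.sin(heading)])
    else:
        heading = float(_reorient(np.asarray(heading), config, rng))
    L = field_concentration(config.field_, (pos[0], pos[1]))
    u = _occupancy(config, L)
    cheyp = float(bank.step(np.atleast_1d(u))[0])
    nxt = int(motor_step(b.motor_state, cheyp, rng, config.motor))
    return Bacterium(position=pos, heading=heading, motor_state=nxt,
                     controller_state=bank.state[0].copy(), cheyp=cheyp)


def simulate(config: SimulationConfig) -> PopulationRecord:
    """Run the full population experiment.

    All agents start at ``init_position`` with uniform random headings;
    controller states start at equilibrium for the local input, and the
    initial motor states are drawn from the stationary law at the
    baseline [CheY-P].
    """
    n = config.n_bacteria
    rng = np.random.default_rng(config.seed)
    pos = np.tile(np.asarray(config.init_position, dtype=float), (n, 1))
    heading = rng.uniform(0.0, 2 * np.pi, size=n)

    L = np.asarray(field_concentration(
        config.field_, (pos[:, 0], pos[:, 1])), dtype=float)
    u = _occupancy(config, L)
    bank = _make_bank(config, n, u)
    if isinstance(bank, _LTIBank):
        cheyp0 = np.full(n, bank.baseline)
    else:
        cheyp0 = bank.X[:, 1].copy()
    motor_state = np.where(rng.random(n) < cw_bias(cheyp0, config.motor),
                           0, 1)

    n_steps = config.n_steps
    stride = config.record_stride
    rec_steps = list(range(0, n_steps, stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_set = {k: i for i, k in enumerate(rec_steps)}
    n_rec = len(rec_steps)

    times = np.array([k * config.dt for k in rec_steps])
    local_L = np.empty((n_rec, n))
    positions = np.empty((n_rec, n, 2)) if config.record_positions else None
    cheyp_rec = np.empty((n_rec, n)) if config.record_positions else None

    cheyp = cheyp0
    if 0 in rec_set:
        local_L[0] = L
        if positions is not None:
            positions[0] = pos
            cheyp_rec[0] = cheyp
    for k in range(1, n_steps + 1):
        running = motor_state == RUN
        pos[running] += (config.speed * config.dt
                         * np.column_stack([np.cos(heading[running]),
                                            np.sin(heading[running])]))
        tumbling = ~running
        if np.any(tumbling):
            heading[tumbling] = _reorient(heading[tumbling], config, rng)
        L = np.asarray(field_concentration(
            config.field_, (pos[:, 0], pos[:, 1])), dtype=float)
        u = _occupancy(config, L)
        cheyp = bank.step(u)
        motor_state = motor_step(motor_state, cheyp, rng, config.motor)
        if k in rec_set:
            i = rec_set[k]
            local_L[i] = L
            if positions is not None:
                positions[i] = pos
                cheyp_rec[i] = cheyp

    return PopulationRecord(times=times, local_L=local_L,
                            positions=positions, cheyp=cheyp_rec,
                            config=config, seed=config.seed)


def with_controller(config: SimulationConfig, **params) -> SimulationConfig:
    """Copy ``config`` with controller parameters replaced."""
    c = config.controller
    if isinstance(c, ControllerFilter):
        new = ControllerFilter(**{**{f: getattr(c, f) for f in
                                     ("kind", "A", "omega0", "omega1",
                                      "omega2", "rank", "sign", "baseline")},
                                  **params})
    else:
        new = replace(c, **params)
    return replace(config, controller=new)
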
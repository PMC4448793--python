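"""Agent-based simulator of a two-exit evacuation environment.

The environment is a rectangular central room with two exits on its right
wall.  The top exit leads into the longer of two corridors, the bottom exit
into the shorter one.  A scripted crowd splits between the exits, walks
straight to its assigned exit, queues there, and is serviced at a rate
proportional to the exit width (capacity ``c * width`` persons per second,
implemented with a deterministic fractional accumulator).  The simulator's
only job is to provide realistic queue dynamics — queue lengths and their
drain rates — as the time-dependent stimulus that exit-choice models observe;
it deliberately has no collision avoidance or social-force dynamics.

Coordinates are 2-D Cartesian in metres with the origin at the room centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EnvironmentConfig",
    "ConfigurationError",
    "CapacityError",
    "Environment",
    "SimState",
    "SimHistory",
    "build_environment",
    "initialize_crowd",
    "step",
    "queue_length",
    "queue_flow",
    "run_evacuation",
    "TOP",
    "BOTTOM",
]

TOP = "top"
BOTTOM = "bottom"

#: Exit service capacity, persons per metre of exit width per second.
DEFAULT_SERVICE_RATE = 1.9
#: Scripted pedestrian desired walking speed, m/s.
DEFAULT_WALK_SPEED = 1.3
#: Capture radius around an exit centre inside which an assigned pedestrian
#: counts as queued, metres.
DEFAULT_CAPTURE_RADIUS = 5.0
#: Pedestrian body radius, metres (used for placement and jam geometry).
PED_RADIUS = 0.25
#: Spacing of ordered queue slots along the queue axis, metres.
QUEUE_SLOT_SPACING = 0.5

# pedestrian states
MOVING, QUEUED, EXITED = 0, 1, 2
STATE_NAMES = {MOVING: "moving", QUEUED: "queued", EXITED: "exited"}


class ConfigurationError(ValueError):
    """Invalid environment configuration; the message names the field."""


class CapacityError(ValueError):
    """Crowd too large for non-overlapping placement."""


@dataclass(frozen=True)
class EnvironmentConfig:
    """Geometry and treatment flags of the virtual environment.

    ``room_height`` is the H of the change-of-mind rule (a change of mind
    requires walking at least H/5 towards one exit before using the other).
    Under treatment W the top exit (feeding the longer corridor) is
    ``width_ratio`` times as wide as the bottom exit; without W both exits
    have the bottom width.
    """

    room_width: float = 10.0
    room_height: float = 10.0
    exit_bottom_width: float = 1.0
    exit_top_width: float | None = None  # derived from treatments if None
    corridor_top_length: float = 12.0
    corridor_bottom_length: float = 8.0
    treatment_S: bool = False
    treatment_W: bool = False
    treatment_M: bool = False
    width_ratio: float = 1.5
    #: vertical offset of each exit centre from the wall midpoint, metres
    exit_offset: float = 2.5

    def resolved_top_width(self) -> float:
        if self.exit_top_width is not None:
            return self.exit_top_width
        return self.exit_bottom_width * (self.width_ratio if self.treatment_W else 1.0)

    def validate(self) -> None:
        for name in (
            "room_width",
            "room_height",
            "exit_bottom_width",
            "corridor_top_length",
            "corridor_bottom_length",
            "width_ratio",
            "exit_offset",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        top_w = self.resolved_top_width()
        if top_w <= 0:
            raise ConfigurationError("exit_top_width must be strictly positive")
        if self.corridor_top_length <= self.corridor_bottom_length:
            raise ConfigurationError(
                "corridor_top_length must exceed corridor_bottom_length "
                "(the top exit feeds the longer corridor)"
            )
        if self.treatment_W:
            if not np.isclose(top_w / self.exit_bottom_width, self.width_ratio):
                raise ConfigurationError(
                    "exit_top_width inconsistent with width_ratio under treatment_W"
                )
        else:
            if not np.isclose(top_w, self.exit_bottom_width):
                raise ConfigurationError(
                    "exit_top_width must equal exit_bottom_width without treatment_W"
                )
        # both openings must fit on the right wall without overlapping
        half_wall = self.room_height / 2.0
        if self.exit_offset + top_w / 2.0 > half_wall:
            raise ConfigurationError("exit_top_width exceeds its wall segment")
        if self.exit_offset + self.exit_bottom_width / 2.0 > half_wall:
            raise ConfigurationError("exit_bottom_width exceeds its wall segment")
        if self.exit_offset - top_w / 2.0 <= 0 or self.exit_offset - self.exit_bottom_width / 2.0 <= 0:
            raise ConfigurationError("exit openings overlap at the wall midpoint")


@dataclass(frozen=True)
class Environment:
    """Resolved geometry: exit centres and opening segments on the right wall."""

    config: EnvironmentConfig
    wall_x: float
    exit_centres: dict  # exit id -> (x, y)
    exit_widths: dict  # exit id -> metres

    def exit_centre(self, exit_id: str) -> np.ndarray:
        return np.asarray(self.exit_centres[exit_id], dtype=float)

    def exit_segment(self, exit_id: str) -> tuple[np.ndarray, np.ndarray]:
        """End points of the exit opening on the wall (the near edges)."""
        cx, cy = self.exit_centres[exit_id]
        half = self.exit_widths[exit_id] / 2.0
        return (np.array([cx, cy - half]), np.array([cx, cy + half]))

    def opposite(self, exit_id: str) -> str:
        return BOTTOM if exit_id == TOP else TOP

    def corridor_length(self, exit_id: str) -> float:
        cfg = self.config
        return cfg.corridor_top_length if exit_id == TOP else cfg.corridor_bottom_length

    def shorter_route_exit(self) -> str:
        """Exit feeding the shorter corridor (bottom under the default layout)."""
        cfg = self.config
        return TOP if cfg.corridor_top_length < cfg.corridor_bottom_length else BOTTOM

    def mirrored(self) -> "Environment":
        """Top<->bottom mirror of the environment (for antisymmetry tests)."""
        cfg = self.config
        mirrored_cfg = replace(
            cfg,
            exit_top_width=cfg.exit_bottom_width,
            exit_bottom_width=cfg.resolved_top_width(),
            corridor_top_length=cfg.corridor_bottom_length,
            corridor_bottom_length=cfg.corridor_top_length,
        )
        # mirrored geometry violates the top-feeds-longer-corridor convention
        # on purpose; bypass validation and rebuild by hand
        centres = {
            TOP: (self.exit_centres[BOTTOM][0], -self.exit_centres[BOTTOM][1]),
            BOTTOM: (self.exit_centres[TOP][0], -self.exit_centres[TOP][1]),
        }
        widths = {TOP: self.exit_widths[BOTTOM], BOTTOM: self.exit_widths[TOP]}
        return Environment(
            config=mirrored_cfg, wall_x=self.wall_x, exit_centres=centres, exit_widths=widths
        )


def build_environment(config: EnvironmentConfig) -> Environment:
    """Resolve a validated configuration into explicit geometry.

    Raises :class:`ConfigurationError` naming the offending field when the
    geometry is inconsistent (non-positive length, exit opening exceeding its
    wall segment, corridor ordering violated).
    """
    config.validate()
    wall_x = config.room_width / 2.0
    centres = {
        TOP: (wall_x, config.exit_offset),
        BOTTOM: (wall_x, -config.exit_offset),
    }
    widths = {TOP: config.resolved_top_width(), BOTTOM: config.exit_bottom_width}
    return Environment(config=config, wall_x=wall_x, exit_centres=centres, exit_widths=widths)


@dataclass
class CrowdParams:
    """Scripted crowd parameters."""

    n_peds: int = 40
    split_fraction: float = 0.5
    walk_speed: float = DEFAULT_WALK_SPEED
    service_rate: float = DEFAULT_SERVICE_RATE  # persons/(m*s)
    capture_radius: float = DEFAULT_CAPTURE_RADIUS
    dt: float = 0.1
    time_cap: float = 300.0


@dataclass
class SimState:
    """Mutable crowd state at one instant."""

    env: Environment
    params: CrowdParams
    t: float
    positions: np.ndarray  # (n, 2) metres
    assigned_exit: np.ndarray  # (n,) 0=top, 1=bottom
    states: np.ndarray  # (n,) MOVING/QUEUED/EXITED
    exit_times: np.ndarray  # (n,) seconds, nan while not exited
    queue_order: dict = field(default_factory=lambda: {TOP: [], BOTTOM: []})
    accumulators: dict = field(default_factory=lambda: {TOP: 0.0, BOTTOM: 0.0})

    @property
    def n_peds(self) -> int:
        return len(self.positions)

    def copy(self) -> "SimState":
        return SimState(
            env=self.env,
            params=self.params,
            t=self.t,
            positions=self.positions.copy(),
            assigned_exit=self.assigned_exit.copy(),
            states=self.states.copy(),
            exit_times=self.exit_times.copy(),
            queue_order={k: list(v) for k, v in self.queue_order.items()},
            accumulators=dict(self.accumulators),
        )


EXIT_CODE = {TOP: 0, BOTTOM: 1}
EXIT_NAME = {0: TOP, 1: BOTTOM}


def initialize_crowd(
    env: Environment,
    n_peds: int,
    split_fraction: float = 0.5,
    seed: int = 0,
    params: CrowdParams | None = None,
) -> SimState:
    """Place ``n_peds`` scripted pedestrians at non-overlapping start positions.

    ``round(n_peds * split_fraction)`` pedestrians are assigned to the top
    exit, the remainder to the bottom exit.  Placement is uniform over the
    left two-thirds of the room with a minimum pairwise separation of one
    body diameter, reproducible from ``seed``.
    """
    if n_peds < 0:
        raise ValueError("n_peds must be non-negative")
    if not 0.0 <= split_fraction <= 1.0:
        raise ValueError("split_fraction must lie in [0, 1]")
    params = params or CrowdParams()
    cfg = env.config
    rng = np.random.default_rng(seed)
    # spawn region: left 2/3 of the room, inset by a body radius
    x_lo, x_hi = -cfg.room_width / 2 + PED_RADIUS, cfg.room_width / 6
    y_lo, y_hi = -cfg.room_height / 2 + PED_RADIUS, cfg.room_height / 2 - PED_RADIUS
    min_sep = 2 * PED_RADIUS
    positions = np.empty((n_peds, 2))
    placed = 0
    attempts = 0
    max_attempts = 4000 + 400 * n_peds
    while placed < n_peds:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n_peds} pedestrians without overlap "
                f"in the spawn region after {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform([x_lo, y_lo], [x_hi, y_hi])
        if placed and np.any(
            np.linalg.norm(positions[:placed] - cand, axis=1) < min_sep
        ):
            continue
        positions[placed] = cand
        placed += 1
    n_top = int(round(n_peds * split_fraction))
    assigned = np.full(n_peds, EXIT_CODE[BOTTOM], dtype=np.int8)
    assigned[:n_top] = EXIT_CODE[TOP]
    return SimState(
        env=env,
        params=params,
        t=0.0,
        positions=positions,
        assigned_exit=assigned,
        states=np.full(n_peds, MOVING, dtype=np.int8),
        exit_times=np.full(n_peds, np.nan),
    )


def _queue_slot(env: Environment, exit_id: str, rank: int) -> np.ndarray:
    """Ordered queue slot ``rank`` (0 = head) in front of an exit.

    Slots extend from just inside the opening into the room along -x.
    """
    centre = env.exit_centre(exit_id)
    return centre + np.array([-(QUEUE_SLOT_SPACING * (rank + 1)), 0.0])


def step(state: SimState, dt: float | None = None) -> SimState:
    """Advance the crowd by one time step (in place) and return the state.

    Moving pedestrians seek their assigned exit in a straight line; once
    inside the capture radius they join that exit's ordered queue and track
    their slot.  Each exit services its queue head at ``c * width`` persons
    per second through a fractional accumulator that saturates (no service
    credit accrues at an empty queue).
    """
    params = state.params
    if dt is None:
        dt = params.dt
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    env = state.env

    # 1. service queues (deterministic accumulator, saturating when empty)
    for exit_id in (TOP, BOTTOM):
        order = state.queue_order[exit_id]
        if not order:
            state.accumulators[exit_id] = 0.0
            continue
        cap = params.service_rate * env.exit_widths[exit_id]
        state.accumulators[exit_id] += cap * dt
        while state.accumulators[exit_id] >= 1.0 and order:
            ped = order.pop(0)
            state.states[ped] = EXITED
            state.exit_times[ped] = state.t + dt
            # park exited pedestrians just beyond the wall, inside the corridor
            state.positions[ped] = env.exit_centre(exit_id) + np.array([0.6, 0.0])
            state.accumulators[exit_id] -= 1.0
        if not order:
            state.accumulators[exit_id] = 0.0

    # 2. movement
    for exit_id in (TOP, BOTTOM):
        code = EXIT_CODE[exit_id]
        centre = env.exit_centre(exit_id)
        order = state.queue_order[exit_id]
        # queued pedestrians track their (possibly advanced) slot
        for rank, ped in enumerate(order):
            slot = _queue_slot(env, exit_id, rank)
            delta = slot - state.positions[ped]
            dist = float(np.hypot(*delta))
            step_len = params.walk_speed * dt
            if dist <= step_len or dist == 0.0:
                state.positions[ped] = slot
            else:
                state.positions[ped] += delta * (step_len / dist)
        # moving pedestrians seek the exit centre; join the queue inside R
        moving = np.flatnonzero((state.states == MOVING) & (state.assigned_exit == code))
        for ped in moving:
            delta = centre - state.positions[ped]
            dist = float(np.hypot(*delta))
            step_len = params.walk_speed * dt
            if dist > step_len:
                state.positions[ped] += delta * (step_len / dist)
            else:
                state.positions[ped] = centre.copy()
            if np.hypot(*(centre - state.positions[ped])) <= params.capture_radius:
                state.states[ped] = QUEUED
                state.queue_order[exit_id].append(int(ped))

    state.t += dt
    return state


def queue_length(state: SimState, exit_id: str) -> int:
    """Number of non-exited pedestrians assigned to ``exit_id`` within the
    capture radius of its centre."""
    if exit_id not in (TOP, BOTTOM):
        raise ValueError(f"unknown exit_id {exit_id!r}")
    code = EXIT_CODE[exit_id]
    centre = state.env.exit_centre(exit_id)
    alive = (state.states != EXITED) & (state.assigned_exit == code)
    if not alive.any():
        return 0
    d = np.linalg.norm(state.positions[alive] - centre, axis=1)
    return int(np.sum(d <= state.params.capture_radius))


class FlowUnavailable(Exception):
    """Raised when fewer than one full window of history exists."""


@dataclass
class SimHistory:
    """Time-indexed record of one evacuation.

    Queue lengths and cumulative exit counts are stored per snapshot;
    positions and states are retained so that feature extraction can look up
    the crowd configuration at any sample time.
    """

    env: Environment
    params: CrowdParams
    times: np.ndarray  # (T,) strictly increasing seconds
    queue_top: np.ndarray  # (T,) persons
    queue_bottom: np.ndarray
    exited_top: np.ndarray  # (T,) cumulative persons
    exited_bottom: np.ndarray
    positions: np.ndarray  # (T, n, 2) float32, metres
    states: np.ndarray  # (T, n) int8
    assigned_exit: np.ndarray  # (n,) int8
    complete: bool = True

    @property
    def n_peds(self) -> int:
        return self.assigned_exit.shape[0]

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def index_at(self, t: float) -> int:
        """Index of the last snapshot at or before ``t``."""
        idx = int(np.searchsorted(self.times, t + 1e-9, side="right")) - 1
        return max(idx, 0)

    def queue_length_at(self, t: float, exit_id: str) -> int:
        i = self.index_at(t)
        return int(self.queue_top[i] if exit_id == TOP else self.queue_bottom[i])

    def state_at(self, t: float) -> SimState:
        """Reconstruct a SimState view at snapshot time <= t (read-only use)."""
        i = self.index_at(t)
        return SimState(
            env=self.env,
            params=self.params,
            t=float(self.times[i]),
            positions=self.positions[i].astype(float),
            assigned_exit=self.assigned_exit,
            states=self.states[i].copy(),
            exit_times=np.full(self.n_peds, np.nan),
        )


def queue_flow(history: SimHistory, exit_id: str, t: float, window: float) -> float:
    """Queue drain rate over ``[t - window, t]``, persons/second.

    Positive when the queue is shrinking.  Raises :class:`FlowUnavailable`
    when less than one full window of history exists before ``t`` (callers
    substitute 0 for the first samples).
    """
    if window <= 0:
        raise ValueError("window must be strictly positive")
    if t - window < history.times[0] - 1e-9:
        raise FlowUnavailable(f"no full window of history before t={t}")
    q_then = history.queue_length_at(t - window, exit_id)
    q_now = history.queue_length_at(t, exit_id)
    return (q_then - q_now) / window


def run_evacuation(
    env: Environment,
    crowd_params: CrowdParams | None = None,
    seed: int = 0,
) -> SimHistory:
    """Run the scripted crowd to completion and record every simulation step.

    Stops when every pedestrian has exited or the time cap is reached; a
    capped run is returned with ``complete=False``.
    """
    params = crowd_params or CrowdParams()
    state = initialize_crowd(
        env, params.n_peds, params.split_fraction, seed=seed, params=params
    )
    times = [0.0]
    q_top = [queue_length(state, TOP)]
    q_bot = [queue_length(state, BOTTOM)]
    e_top = [0]
    e_bot = [0]
    pos = [state.positions.copy()]
    sts = [state.states.copy()]
    complete = state.n_peds == 0
    while not complete and state.t < params.time_cap:
        step(state, params.dt)
        times.append(state.t)
        q_top.append(queue_length(state, TOP))
        q_bot.append(queue_length(state, BOTTOM))
        exited = state.states == EXITED
        e_top.append(int(np.sum(exited & (state.assigned_exit == EXIT_CODE[TOP]))))
        e_bot.append(int(np.sum(exited & (state.assigned_exit == EXIT_CODE[BOTTOM]))))
        pos.append(state.positions.copy())
        sts.append(state.states.copy())
        complete = bool(exited.all())
    return SimHistory(
        env=env,
        params=params,
        times=np.asarray(times),
        queue_top=np.asarray(q_top, dtype=int),
        queue_bottom=np.asarray(q_bot, dtype=int),
        exited_top=np.asarray(e_top, dtype=int),
        exited_bottom=np.asarray(e_bot, dtype=int),
        positions=np.asarray(pos, dtype=np.float32),
        states=np.asarray(sts, dtype=np.int8),
        assigned_exit=state.assigned_exit.copy(),
        complete=complete,
    )


def history_to_frames(history: SimHistory):
    """Tidy exports: (trajectory frame, queue-series frame).

    The trajectory frame has one row per (time, pedestrian); the queue frame
    one row per snapshot.  Import is deferred so numpy-only use stays light.
    """
    import pandas as pd

    T, n = history.states.shape
    traj = pd.DataFrame(
        {
            "time_s": np.repeat(history.times, n),
            "ped_id": np.tile(np.arange(n), T),
            "x_m": history.positions[:, :, 0].ravel(),
            "y_m": history.positions[:, :, 1].ravel(),
            "assigned_exit": np.tile(
                np.array([EXIT_NAME[c] for c in history.assigned_exit]), T
            ),
            "state": np.vectorize(STATE_NAMES.get)(history.states.ravel()),
        }
    )
    queues = pd.DataFrame(
        {
            "time_s": history.times,
            "q_top": history.queue_top,
            "q_bottom": history.queue_bottom,
            "exited_top": history.exited_top,
            "exited_bottom": history.exited_bottom,
        }
    )
    return traj, queues
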
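"""Per-sample decision features and per-participant behavioural statistics.

A participant trajectory coupled to a simulated evacuation is reduced to
tidy feature rows sampled at a fixed interval.  Each row describes, from the
top exit's point of view, the information available at that instant:

- ``q_adv``   queue-length advantage of the top exit (q_bottom - q_top), persons
- ``f_adv``   flow advantage of the top exit (flow_top - flow_bottom), persons/s
- ``w_adv``   width advantage of the top exit, metres
- ``s_vis``   signed shortest-route visibility indicator in {-1, 0, +1}
- ``d_adv``   distance advantage of the top exit (dist_bottom - dist_top), metres
- ``jam``     signed blocked-in-queue indicator in {-1, 0, +1}
- ``choice``  exit the participant currently prefers

plus the behavioural summaries the outcome-level analysis uses: whether the
participant used the shorter corridor and whether they changed their mind
(walked at least one-fifth of the room height towards one exit before
exiting through the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envsim import (
    BOTTOM,
    EXITED,
    PED_RADIUS,
    TOP,
    Environment,
    FlowUnavailable,
    SimHistory,
    SimState,
    queue_flow,
)

__all__ = [
    "ParticipantTrajectory",
    "FeatureRow",
    "BehaviouralSummary",
    "TrajectoryError",
    "sample_decision_points",
    "detect_change_of_mind",
    "detect_jam",
    "chose_shortest_route",
    "exit_used",
]

#: default fixed sampling interval between feature rows, seconds
DEFAULT_SAMPLE_INTERVAL = 0.5
#: default finite-difference window for the queue-flow feature, seconds
DEFAULT_FLOW_WINDOW = 2.0
#: minimum per-tick reduction in distance to an exit that counts as having
#: indicated an initial preference, metres
ONSET_EPSILON = 0.05

FEATURE_COLUMNS = [
    "participant_id",
    "condition",
    "t_s",
    "q_adv",
    "f_adv",
    "w_adv",
    "s_vis",
    "d_adv",
    "jam",
    "choice",
]


class TrajectoryError(ValueError):
    """Trajectory does not terminate beyond an exit; outcome undefined."""


@dataclass
class ParticipantTrajectory:
    """Ordered (time, position, preferred exit) samples for one participant.

    The preferred exit is defined at every retained sample — participants are
    modelled as never undecided once their initial preference is indicated.
    """

    participant_id: str
    condition: str
    age: float
    gender: int
    times: np.ndarray  # (T,) strictly increasing seconds
    positions: np.ndarray  # (T, 2) metres
    preferred: np.ndarray  # (T,) unicode {"top", "bottom"}
    complete: bool = True  # False if a time cap cut the run short

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.preferred = np.asarray(self.preferred)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def position_at(self, t: float) -> np.ndarray:
        """Linear interpolation of position at ``t`` (clamped to the ends)."""
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        return np.array([x, y])

    def preferred_at(self, t: float) -> str:
        idx = int(np.searchsorted(self.times, t + 1e-9, side="right")) - 1
        return str(self.preferred[max(idx, 0)])


@dataclass(frozen=True)
class FeatureRow:
    t_s: float
    q_adv: float
    f_adv: float
    w_adv: float
    s_vis: int
    d_adv: float
    jam: int
    choice: str


@dataclass(frozen=True)
class BehaviouralSummary:
    participant_id: str
    condition: str
    age: float
    gender: int
    chose_shortest: bool
    changed_mind: bool
    n_samples: int


def exit_used(traj: ParticipantTrajectory, env: Environment) -> str:
    """Exit through which the trajectory left the central room.

    The final sample must lie beyond the exit wall; the exit whose centre is
    closest to the wall-crossing point is the one used.
    """
    if traj.n_samples == 0 or traj.positions[-1, 0] < env.wall_x:
        raise TrajectoryError(
            f"trajectory {traj.participant_id} never passes an exit"
        )
    xs = traj.positions[:, 0]
    cross = int(np.argmax(xs >= env.wall_x))
    y_cross = traj.positions[cross, 1]
    d_top = abs(y_cross - env.exit_centres[TOP][1])
    d_bot = abs(y_cross - env.exit_centres[BOTTOM][1])
    return TOP if d_top <= d_bot else BOTTOM


def chose_shortest_route(traj: ParticipantTrajectory, env: Environment) -> bool:
    """True iff the exit used feeds the shorter corridor."""
    return exit_used(traj, env) == env.shorter_route_exit()


def detect_change_of_mind(
    traj: ParticipantTrajectory, env: Environment, threshold_fraction: float = 0.2
) -> bool:
    """Change-of-mind rule.

    True iff the participant walked at least ``threshold_fraction`` of the
    room height towards one exit and ultimately exited through the opposite
    exit.  Because both exits sit on the same wall, moving towards either
    one usually also reduces the Euclidean distance to the other, so each
    movement segment is attributed to the exit whose distance it reduces
    *most*; progress towards an exit is the distance reduction accumulated
    over maximal runs of segments attributed to it.
    """
    final_exit = exit_used(traj, env)  # raises if undefined
    threshold = threshold_fraction * env.config.room_height
    other = env.opposite(final_exit)
    d_other = np.linalg.norm(traj.positions - env.exit_centre(other), axis=1)
    d_final = np.linalg.norm(traj.positions - env.exit_centre(final_exit), axis=1)
    dec_other = -np.diff(d_other)
    dec_final = -np.diff(d_final)
    run = 0.0
    for do, df in zip(dec_other, dec_final):
        if do > 0 and do > df:  # segment heads towards the abandoned exit
            run += do
            if run >= threshold:
                return True
        else:
            run = 0.0
    return False


def detect_jam(
    state: SimState,
    participant_position: np.ndarray,
    current_queue_exit: str | None,
    ped_radius: float = PED_RADIUS,
) -> int:
    """Signed blocked-in-queue indicator.

    Nonzero only when the participant currently sits in the queue zone of
    exit *k* and at least one scripted pedestrian's body disc intersects the
    straight segment from the participant to the nearest edge point of the
    opposite exit's opening.  The sign pushes towards the occupied queue:
    +1 for the top queue, -1 for the bottom queue.
    """
    if current_queue_exit not in (TOP, BOTTOM):
        return 0
    env = state.env
    p = np.asarray(participant_position, dtype=float)
    centre = env.exit_centre(current_queue_exit)
    if np.linalg.norm(p - centre) > state.params.capture_radius:
        return 0
    opposite = env.opposite(current_queue_exit)
    a, b = env.exit_segment(opposite)
    # nearest edge point of the opposite opening to the participant
    target = a if np.linalg.norm(p - a) <= np.linalg.norm(p - b) else b
    seg = target - p
    seg_len2 = float(seg @ seg)
    alive = state.states != EXITED
    if seg_len2 == 0.0 or not alive.any():
        return 0
    rel = state.positions[alive] - p
    t = np.clip(rel @ seg / seg_len2, 0.0, 1.0)
    closest = np.outer(t, seg)
    dist = np.linalg.norm(rel - closest, axis=1)
    if np.any(dist <= ped_radius):
        return 1 if current_queue_exit == TOP else -1
    return 0


def _blocker_count(state: SimState, participant_position: np.ndarray, current_queue_exit: str) -> int:
    """Number of scripted pedestrians blocking the cross-path (diagnostics)."""
    if current_queue_exit not in (TOP, BOTTOM):
        return 0
    env = state.env
    p = np.asarray(participant_position, dtype=float)
    opposite = env.opposite(current_queue_exit)
    a, b = env.exit_segment(opposite)
    target = a if np.linalg.norm(p - a) <= np.linalg.norm(p - b) else b
    seg = target - p
    seg_len2 = float(seg @ seg)
    alive = state.states != EXITED
    if seg_len2 == 0.0 or not alive.any():
        return 0
    rel = state.positions[alive] - p
    t = np.clip(rel @ seg / seg_len2, 0.0, 1.0)
    dist = np.linalg.norm(rel - np.outer(t, seg), axis=1)
    return int(np.sum(dist <= PED_RADIUS))


def _static_features(env: Environment) -> tuple[float, int]:
    """(w_adv, s_vis) — time-independent features of the environment."""
    w_adv = env.exit_widths[TOP] - env.exit_widths[BOTTOM]
    if not env.config.treatment_S:
        s_vis = 0
    else:
        s_vis = 1 if env.shorter_route_exit() == TOP else -1
    return w_adv, s_vis


def preference_onset_index(
    traj: ParticipantTrajectory, env: Environment, interval: float
) -> int | None:
    """First sampling tick at which an initial preference is established.

    Operationalised as the first tick whose displacement since the previous
    tick reduces the distance to one of the exits by at least
    :data:`ONSET_EPSILON`.  Returns the tick index on the grid
    ``t0 + k * interval``, or None if no such tick exists before the
    trajectory ends.  Tick 0 counts as onset when the participant starts
    already moving (the first difference is taken over ``[t0, t0+interval]``
    and attributed to the earlier tick so that a participant decided from
    the start yields rows from the start).
    """
    if traj.n_samples == 0:
        return None
    t0, t_end = traj.times[0], traj.times[-1]
    n_ticks = int(np.floor((t_end - t0) / interval)) + 1
    if n_ticks < 2:
        return None
    prev = traj.position_at(t0)
    for k in range(1, n_ticks):
        cur = traj.position_at(t0 + k * interval)
        for exit_id in (TOP, BOTTOM):
            c = env.exit_centre(exit_id)
            if np.linalg.norm(prev - c) - np.linalg.norm(cur - c) >= ONSET_EPSILON:
                return k - 1
        prev = cur
    return None


def sample_decision_points(
    traj: ParticipantTrajectory,
    history: SimHistory,
    interval: float = DEFAULT_SAMPLE_INTERVAL,
    flow_window: float = DEFAULT_FLOW_WINDOW,
) -> pd.DataFrame:
    """Extract one feature row per sampling tick.

    Rows run from the tick at which the participant first indicates a
    preference (see :func:`preference_onset_index`) until the participant
    passes an exit.  Flow is 0 until one full ``flow_window`` of simulated
    history exists.  Returns a tidy DataFrame with :data:`FEATURE_COLUMNS`.
    """
    if interval <= 0:
        raise ValueError("interval must be strictly positive")
    env = history.env
    if traj.n_samples == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    onset = preference_onset_index(traj, env, interval)
    if onset is None:
        return pd.DataFrame(columns=FEATURE_COLUMNS)

    w_adv, s_vis = _static_features(env)
    t0 = traj.times[0]
    # last tick: while the participant is still inside the room
    xs = traj.positions[:, 0]
    beyond = xs >= env.wall_x
    t_exit = traj.times[int(np.argmax(beyond))] if beyond.any() else traj.times[-1]

    rows = []
    k = onset
    while True:
        t = t0 + k * interval
        if t > traj.times[-1] + 1e-9 or t > t_exit + 1e-9:
            break
        pos = traj.position_at(t)
        if pos[0] >= env.wall_x:
            break
        q_top = history.queue_length_at(t, TOP)
        q_bot = history.queue_length_at(t, BOTTOM)
        f_adv = 0.0
        try:
            f_top = queue_flow(history, TOP, t, flow_window)
            f_bot = queue_flow(history, BOTTOM, t, flow_window)
            f_adv = f_top - f_bot
        except FlowUnavailable:
            f_adv = 0.0
        d_top = float(np.linalg.norm(pos - env.exit_centre(TOP)))
        d_bot = float(np.linalg.norm(pos - env.exit_centre(BOTTOM)))
        choice = traj.preferred_at(t)
        state = history.state_at(t)
        # queue membership reflects the queue the participant already walked
        # into, i.e. the preference at the previous tick; the jam feature is
        # therefore predetermined at the moment the current choice is made
        prev_t = t - interval
        in_queue = None
        if prev_t >= traj.times[0] - 1e-9:
            prev_choice = traj.preferred_at(prev_t)
            if (
                np.linalg.norm(pos - env.exit_centre(prev_choice))
                <= history.params.capture_radius
            ):
                in_queue = prev_choice
        jam = detect_jam(state, pos, in_queue)
        rows.append(
            {
                "participant_id": traj.participant_id,
                "condition": traj.condition,
                "t_s": t,
                "q_adv": float(q_bot - q_top),
                "f_adv": float(f_adv),
                "w_adv": float(w_adv),
                "s_vis": int(s_vis),
                "d_adv": float(d_bot - d_top),
                "jam": int(jam),
                "choice": choice,
            }
        )
        k += 1
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def behavioural_summary(
    traj: ParticipantTrajectory, env: Environment, n_samples: int
) -> BehaviouralSummary:
    return BehaviouralSummary(
        participant_id=traj.participant_id,
        condition=traj.condition,
        age=traj.age,
        gender=traj.gender,
        chose_shortest=chose_shortest_route(traj, env),
        changed_mind=detect_change_of_mind(traj, env),
        n_samples=n_samples,
    )
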
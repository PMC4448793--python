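import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitchoice import (
    BOTTOM,
    TOP,
    CrowdParams,
    ParticipantTrajectory,
    chose_shortest_route,
    detect_change_of_mind,
    detect_jam,
    initialize_crowd,
    sample_decision_points,
)
from exitchoice.envsim import SimHistory
from exitchoice.features import (
    TrajectoryError,
    exit_used,
    preference_onset_index,
)


def make_traj(times, positions, preferred=None, **kwargs):
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if preferred is None:
        preferred = np.full(len(times), TOP)
    defaults = dict(participant_id="p0", condition="control", age=23.0, gender=0)
    defaults.update(kwargs)
    return ParticipantTrajectory(
        times=times, positions=positions, preferred=np.asarray(preferred), **defaults
    )


def straight_path(start, end, n=21, t_end=10.0):
    ts = np.linspace(0.0, t_end, n)
    pos = np.linspace(start, end, n)
    return ts, pos


class TestExitUsedAndShortestRoute:
    def test_bottom_exit_is_shorter_route(self, control_env):
        ts, pos = straight_path([-3.0, 0.0], [5.6, -2.5])
        traj = make_traj(ts, pos, np.full(len(ts), BOTTOM))
        assert exit_used(traj, control_env) == BOTTOM
        assert chose_shortest_route(traj, control_env)

    def test_top_exit_is_not_shortest(self, control_env):
        ts, pos = straight_path([-3.0, 0.0], [5.6, 2.5])
        traj = make_traj(ts, pos)
        assert not chose_shortest_route(traj, control_env)

    def test_unfinished_trajectory_raises(self, control_env):
        ts, pos = straight_path([-3.0, 0.0], [0.0, 0.0])
        traj = make_traj(ts, pos)
        with pytest.raises(TrajectoryError):
            chose_shortest_route(traj, control_env)


def _detour_trajectory(env, progress_fraction):
    """Walk ``progress_fraction * H`` straight towards the top exit from a
    point where that is unambiguous, then exit via the bottom exit."""
    H = env.config.room_height
    start = np.array([1.0, 0.0])
    towards_top = env.exit_centre(TOP) - start
    towards_top /= np.linalg.norm(towards_top)
    turn = start + towards_top * (progress_fraction * H)
    pts = [start]
    pts += [start + towards_top * s for s in np.linspace(0.2, progress_fraction * H, 12)]
    end = env.exit_centre(BOTTOM) + np.array([0.7, 0.0])
    pts += [turn + (end - turn) * f for f in np.linspace(0.1, 1.0, 12)]
    pos = np.array(pts)
    ts = np.arange(len(pos), dtype=float) * 0.4
    return make_traj(ts, pos, np.full(len(pos), BOTTOM))


class TestChangeOfMind:
    def test_straight_path_is_not_a_change(self, control_env):
        ts, pos = straight_path([-3.0, 0.0], [5.6, 2.5])
        traj = make_traj(ts, pos)
        assert not detect_change_of_mind(traj, control_env)

    def test_quarter_height_detour_is_a_change(self, control_env):
        traj = _detour_trajectory(control_env, 0.25)
        assert detect_change_of_mind(traj, control_env)

    def test_tenth_height_detour_is_below_threshold(self, control_env):
        traj = _detour_trajectory(control_env, 0.10)
        assert not detect_change_of_mind(traj, control_env)

    @settings(deadline=None, max_examples=25)
    @given(
        frac=st.floats(min_value=0.05, max_value=0.45),
        thr_lo=st.floats(min_value=0.05, max_value=0.4),
        thr_hi=st.floats(min_value=0.05, max_value=0.4),
    )
    def test_monotone_in_threshold(self, control_env, frac, thr_lo, thr_hi):
        # lowering the threshold never turns a detected change into a miss
        lo, hi = sorted([thr_lo, thr_hi])
        traj = _detour_trajectory(control_env, frac)
        hit_hi = detect_change_of_mind(traj, control_env, threshold_fraction=hi)
        hit_lo = detect_change_of_mind(traj, control_env, threshold_fraction=lo)
        assert hit_lo or not hit_hi


class TestDetectJam:
    def _state(self, env, ped_positions):
        n = len(ped_positions)
        params = CrowdParams(n_peds=n)
        state = initialize_crowd(env, n, 0.5, seed=0, params=params)
        if n:
            state.positions = np.asarray(ped_positions, dtype=float)
        return state

    def test_open_room_no_jam(self, control_env):
        state = self._state(control_env, np.empty((0, 2)))
        assert detect_jam(state, np.array([0.0, 0.0]), None) == 0

    def test_blocked_in_top_queue_is_plus_one(self, control_env):
        participant = np.array([3.0, 3.1])  # inside top queue zone
        # pedestrian disc sitting on the straight segment to the bottom
        # exit's near edge (5, -2)
        midpoint = (participant + np.array([5.0, -2.0])) / 2.0
        state = self._state(control_env, [midpoint])
        assert detect_jam(state, participant, TOP) == 1

    def test_blocked_in_bottom_queue_is_minus_one(self, control_env):
        participant = np.array([3.0, -3.1])
        midpoint = (participant + np.array([5.0, 2.0])) / 2.0
        state = self._state(control_env, [midpoint])
        assert detect_jam(state, participant, BOTTOM) == -1

    def test_no_jam_outside_queue_zone(self, control_env):
        participant = np.array([-4.0, 3.0])  # far from both exits
        midpoint = (participant + np.array([5.0, -2.0])) / 2.0
        state = self._state(control_env, [midpoint])
        assert detect_jam(state, participant, TOP) == 0

    def test_clear_cross_path_no_jam(self, control_env):
        participant = np.array([3.0, 3.1])
        state = self._state(control_env, [[-4.0, -4.0]])
        assert detect_jam(state, participant, TOP) == 0


class TestSampleDecisionPoints:
    def test_row_count_matches_duration(self, control_env):
        # 10 s of decided walking sampled at 0.5 s, exit exactly at 10 s
        ts = np.array([0.0, 10.0])
        pos = np.array([[-3.0, 0.0], [5.0, 2.5]])
        traj = make_traj(ts, pos)
        history = _empty_history(control_env, duration=12.0)
        rows = sample_decision_points(traj, history, interval=0.5)
        assert len(rows) == 20

    def test_participant_exiting_before_first_tick_yields_nothing(self, control_env):
        ts = np.array([0.0, 0.2])
        pos = np.array([[4.9, 2.5], [5.6, 2.5]])
        traj = make_traj(ts, pos)
        history = _empty_history(control_env, duration=1.0)
        rows = sample_decision_points(traj, history, interval=0.5)
        assert len(rows) == 0

    def test_empty_trajectory_yields_empty_frame(self, control_env):
        traj = make_traj(np.empty(0), np.empty((0, 2)), np.empty(0, dtype=str))
        history = _empty_history(control_env, duration=1.0)
        rows = sample_decision_points(traj, history)
        assert len(rows) == 0

    def test_symmetric_control_rows(self, control_env):
        ts, pos = straight_path([-3.0, 0.0], [5.6, 2.5])
        traj = make_traj(ts, pos)
        history = _empty_history(control_env, duration=12.0)
        rows = sample_decision_points(traj, history, interval=0.5)
        assert (rows["q_adv"] == 0).all()
        assert (rows["w_adv"] == 0).all()
        assert (rows["s_vis"] == 0).all()

    def test_onset_requires_approach(self, control_env):
        # standing still: no preference onset, no rows
        ts = np.linspace(0, 5, 11)
        pos = np.tile([[-3.0, 0.0]], (11, 1))
        traj = make_traj(ts, pos)
        assert preference_onset_index(traj, control_env, 0.5) is None


def _empty_history(env, duration, dt=0.1):
    times = np.arange(0.0, duration + dt / 2, dt)
    n = len(times)
    return SimHistory(
        env=env,
        params=CrowdParams(n_peds=0),
        times=times,
        queue_top=np.zeros(n, dtype=int),
        queue_bottom=np.zeros(n, dtype=int),
        exited_top=np.zeros(n, dtype=int),
        exited_bottom=np.zeros(n, dtype=int),
        positions=np.zeros((n, 0, 2), dtype=np.float32),
        states=np.zeros((n, 0), dtype=np.int8),
        assigned_exit=np.zeros(0, dtype=np.int8),
    )


class TestMirrorAntisymmetry:
    def test_extraction_commutes_with_top_bottom_mirror(self, control_env, control_history):
        from exitchoice.cohort import DEFAULT_GENERATING_SPEC, DEFAULT_PARAMS_NON_M
        from exitchoice import simulate_participant

        h = control_history
        traj = simulate_participant(
            h, DEFAULT_GENERATING_SPEC, DEFAULT_PARAMS_NON_M, seed=5
        )
        rows = sample_decision_points(traj, h)

        # mirror the whole world top<->bottom
        env_m = control_env.mirrored()
        flip = np.array([1.0, -1.0])
        h_m = SimHistory(
            env=env_m,
            params=h.params,
            times=h.times,
            queue_top=h.queue_bottom,
            queue_bottom=h.queue_top,
            exited_top=h.exited_bottom,
            exited_bottom=h.exited_top,
            positions=h.positions * flip.astype(np.float32),
            states=h.states,
            assigned_exit=(1 - h.assigned_exit).astype(np.int8),
        )
        swap = {TOP: BOTTOM, BOTTOM: TOP}
        traj_m = ParticipantTrajectory(
            participant_id=traj.participant_id,
            condition=traj.condition,
            age=traj.age,
            gender=traj.gender,
            times=traj.times,
            positions=traj.positions * flip,
            preferred=np.array([swap[p] for p in traj.preferred]),
        )
        rows_m = sample_decision_points(traj_m, h_m)
        assert len(rows) == len(rows_m) > 0
        for col in ("q_adv", "f_adv", "w_adv", "s_vis", "d_adv", "jam"):
            np.testing.assert_allclose(
                rows_m[col].to_numpy(), -rows[col].to_numpy(), atol=1e-9
            )
        assert (rows_m["choice"].map(swap) == rows["choice"]).all()
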
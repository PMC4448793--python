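import numpy as np
import pytest

from exitchoice import (
    BOTTOM,
    TOP,
    CrowdParams,
    EnvironmentConfig,
    build_environment,
    initialize_crowd,
    queue_flow,
    queue_length,
    run_evacuation,
    step,
)
from exitchoice.envsim import (
    EXITED,
    MOVING,
    QUEUED,
    CapacityError,
    ConfigurationError,
    FlowUnavailable,
    SimHistory,
)


class TestBuildEnvironment:
    def test_control_exits_equal_width(self, control_env):
        assert control_env.exit_widths[TOP] == control_env.exit_widths[BOTTOM]

    def test_treatment_w_top_exit_is_one_point_five_times_wider(self):
        env = build_environment(EnvironmentConfig(treatment_W=True, exit_bottom_width=1.0))
        assert env.exit_widths[TOP] == pytest.approx(1.5)
        assert env.exit_widths[BOTTOM] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"corridor_top_length": 5.0, "corridor_bottom_length": 8.0},
            {"corridor_top_length": 8.0, "corridor_bottom_length": 8.0},
            {"room_width": -1.0},
            {"exit_bottom_width": 0.0},
            {"exit_bottom_width": 6.0},  # exceeds the wall segment
            {"treatment_W": False, "exit_top_width": 1.5},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            build_environment(EnvironmentConfig(**kwargs))

    def test_exit_segments_lie_on_right_wall(self, control_env):
        for exit_id in (TOP, BOTTOM):
            a, b = control_env.exit_segment(exit_id)
            assert a[0] == b[0] == control_env.wall_x
            assert abs(b[1] - a[1]) == pytest.approx(control_env.exit_widths[exit_id])

    def test_top_exit_feeds_longer_corridor(self, control_env):
        assert control_env.corridor_length(TOP) > control_env.corridor_length(BOTTOM)
        assert control_env.shorter_route_exit() == BOTTOM


class TestInitializeCrowd:
    def test_even_split(self, control_env):
        state = initialize_crowd(control_env, 40, 0.5, seed=0)
        n_top = int(np.sum(state.assigned_exit == 0))
        assert n_top == 20 and state.n_peds == 40

    def test_empty_crowd_has_zero_queues(self, control_env):
        state = initialize_crowd(control_env, 0, 0.5, seed=0)
        assert queue_length(state, TOP) == 0
        assert queue_length(state, BOTTOM) == 0

    def test_same_seed_reproduces_positions(self, control_env):
        a = initialize_crowd(control_env, 30, 0.5, seed=5)
        b = initialize_crowd(control_env, 30, 0.5, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_positions_non_overlapping(self, control_env):
        state = initialize_crowd(control_env, 40, 0.5, seed=1)
        d = np.linalg.norm(
            state.positions[:, None, :] - state.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.5  # one body diameter

    def test_overfull_room_raises(self, control_env):
        with pytest.raises(CapacityError):
            initialize_crowd(control_env, 5000, 0.5, seed=0)


class TestServiceAccumulator:
    def _queued_state(self, env, n, exit_id=TOP):
        params = CrowdParams(n_peds=n)
        state = initialize_crowd(env, n, 1.0 if exit_id == TOP else 0.0, seed=0, params=params)
        state.states[:] = QUEUED
        state.queue_order[exit_id] = list(range(n))
        return state

    def test_queue_of_ten_services_one_and_retains_fraction(self, control_env):
        # capacity 1.9 persons/s * 1 s = 1.9: one serviced, 0.9 retained
        state = self._queued_state(control_env, 10)
        step(state, dt=1.0)
        assert int(np.sum(state.states == EXITED)) == 1
        assert state.accumulators[TOP] == pytest.approx(0.9)

    def test_empty_queue_exits_nobody_and_banks_nothing(self, control_env):
        state = initialize_crowd(control_env, 0, 0.5, seed=0)
        step(state, dt=1.0)
        assert state.accumulators[TOP] == 0.0 and state.accumulators[BOTTOM] == 0.0

    def test_wider_exit_drains_queue_faster(self):
        def clearing_time(env):
            history = run_evacuation(env, CrowdParams(), seed=3)
            n_top = int(np.sum(history.assigned_exit == 0))
            done = history.exited_top >= n_top
            return history.times[int(np.argmax(done))]

        env_eq = build_environment(EnvironmentConfig())
        env_w = build_environment(EnvironmentConfig(treatment_W=True))
        t_eq, t_w = clearing_time(env_eq), clearing_time(env_w)
        assert t_w < t_eq

    def test_top_and_bottom_clear_together_in_control(self, control_history):
        # equal widths, even split: clearing times match within a second
        h = control_history
        t_top = h.times[int(np.argmax(h.exited_top >= 20))]
        t_bot = h.times[int(np.argmax(h.exited_bottom >= 20))]
        assert abs(t_top - t_bot) < 1.0


class TestQueueObservables:
    def test_queue_length_counts_only_within_capture_radius(self, control_env):
        params = CrowdParams(n_peds=10, capture_radius=5.0)
        state = initialize_crowd(control_env, 10, 1.0, seed=0, params=params)
        centre = control_env.exit_centre(TOP)
        # 7 in the queue zone, 3 far across the room
        state.positions[:7] = centre + np.array([-1.0, 0.0])
        state.positions[7:] = np.array([-4.5, 0.0])
        assert queue_length(state, TOP) == 7

    def test_queue_length_zero_when_all_exited(self, control_env):
        state = initialize_crowd(control_env, 5, 1.0, seed=0)
        state.states[:] = EXITED
        assert queue_length(state, TOP) == 0

    def test_queue_length_rejects_unknown_exit(self, control_env):
        state = initialize_crowd(control_env, 1, 1.0, seed=0)
        with pytest.raises(ValueError):
            queue_length(state, "left")


class TestQueueFlow:
    def _history_with_queue_series(self, env, times, q_top):
        n = len(times)
        return SimHistory(
            env=env,
            params=CrowdParams(n_peds=0),
            times=np.asarray(times, dtype=float),
            queue_top=np.asarray(q_top, dtype=int),
            queue_bottom=np.zeros(n, dtype=int),
            exited_top=np.zeros(n, dtype=int),
            exited_bottom=np.zeros(n, dtype=int),
            positions=np.zeros((n, 0, 2), dtype=np.float32),
            states=np.zeros((n, 0), dtype=np.int8),
            assigned_exit=np.zeros(0, dtype=np.int8),
        )

    def test_constant_queue_has_zero_flow(self, control_env):
        h = self._history_with_queue_series(control_env, [0, 1, 2, 3, 4], [5, 5, 5, 5, 5])
        assert queue_flow(h, TOP, t=4.0, window=4.0) == 0.0

    def test_shrinking_queue_positive_flow(self, control_env):
        h = self._history_with_queue_series(control_env, [0, 1, 2, 3, 4], [10, 9, 8, 7, 6])
        assert queue_flow(h, TOP, t=4.0, window=4.0) == pytest.approx(1.0)

    def test_growing_queue_negative_flow(self, control_env):
        h = self._history_with_queue_series(control_env, [0, 1, 2], [4, 5, 6])
        assert queue_flow(h, TOP, t=2.0, window=2.0) == pytest.approx(-1.0)

    def test_insufficient_history_signalled(self, control_env):
        h = self._history_with_queue_series(control_env, [0, 1, 2], [4, 5, 6])
        with pytest.raises(FlowUnavailable):
            queue_flow(h, TOP, t=1.0, window=2.0)


class TestRunEvacuation:
    def test_empty_crowd_history(self, control_env):
        h = run_evacuation(control_env, CrowdParams(n_peds=0), seed=0)
        assert len(h.times) >= 1
        assert h.queue_top.max() == 0 and h.queue_bottom.max() == 0
        assert h.complete

    def test_fixed_seed_bitwise_identical_queue_series(self, control_env):
        a = run_evacuation(control_env, CrowdParams(), seed=9)
        b = run_evacuation(control_env, CrowdParams(), seed=9)
        np.testing.assert_array_equal(a.queue_top, b.queue_top)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_conservation_every_step(self, control_history):
        h = control_history
        n = h.n_peds
        for i in range(len(h.times)):
            counts = np.bincount(h.states[i], minlength=3)
            assert counts.sum() == n
        assert h.exited_top[-1] + h.exited_bottom[-1] == n

    def test_cumulative_exits_monotone_and_queues_nonnegative(self, control_history):
        h = control_history
        assert np.all(np.diff(h.exited_top) >= 0)
        assert np.all(np.diff(h.exited_bottom) >= 0)
        assert h.queue_top.min() >= 0 and h.queue_bottom.min() >= 0

    def test_time_cap_flags_incomplete(self, control_env):
        h = run_evacuation(control_env, CrowdParams(time_cap=0.5), seed=0)
        assert not h.complete

    def test_desk_scale_runtime(self, control_env):
        import time

        t0 = time.perf_counter()
        run_evacuation(control_env, CrowdParams(n_peds=40), seed=2)
        assert time.perf_counter() - t0 < 1.0
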
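"""Surrogate kinematics, command semantics, toy vision and timing plans."""

import math

import numpy as np
import pytest

from hybridbci.hybrid import Command
from hybridbci.surrogate import (Arena, Mode, RobotState, ViewFrame,
                                 apply_command, default_arena,
                                 detect_objects, in_central_zone,
                                 recognition_sequence, render_view, tick,
                                 virtual_center)


def idle_at(x=75.0, y=150.0, heading=90.0, offset=0.0, mode=Mode.NAV_IDLE):
    return RobotState(position=(x, y), body_heading=heading,
                      head_offset=offset, mode=mode)


class TestCommands:
    def test_head_turns_three_degrees_each(self):
        s = idle_at()
        for _ in range(4):
            s = apply_command(s, Command.HEAD_LEFT)
        assert s.head_offset == pytest.approx(12.0)
        s = apply_command(s, Command.HEAD_RIGHT)
        assert s.head_offset == pytest.approx(9.0)

    def test_erd_with_misaligned_head_starts_alignment(self):
        s = apply_command(idle_at(offset=12.0), Command.ERD_SWITCH)
        assert s.mode is Mode.ALIGNING

    def test_alignment_transfers_offset_to_body(self):
        s = apply_command(idle_at(offset=12.0), Command.ERD_SWITCH)
        arena = default_arena()
        for _ in range(100):
            s, _ = tick(s, 0.25, arena)
            if s.mode is not Mode.ALIGNING:
                break
        assert s.mode is Mode.NAV_IDLE
        assert s.body_heading == pytest.approx(102.0)
        assert s.head_offset == pytest.approx(0.0)

    def test_erd_with_aligned_head_toggles_walking(self):
        s = apply_command(idle_at(offset=6.0), Command.ERD_SWITCH)
        assert s.mode is Mode.WALKING  # within 9 deg: just walk
        s = apply_command(s, Command.ERD_SWITCH)
        assert s.mode is Mode.NAV_IDLE

    @pytest.mark.parametrize("mode", [Mode.ALIGNING, Mode.RECOGNITION])
    def test_commands_ignored_while_busy(self, mode):
        s = idle_at(offset=15.0, mode=mode)
        for cmd in Command:
            assert apply_command(s, cmd) == s

    def test_none_command_is_a_no_op(self):
        s = idle_at(offset=3.0)
        assert apply_command(s, Command.NONE) == s


class TestTick:
    def test_walking_speed_integrates_exactly(self):
        arena = default_arena()
        s = idle_at(y=50.0, mode=Mode.WALKING)
        for _ in range(100):
            s, hit = tick(s, 0.1, arena)
            assert not hit
        assert s.position[1] == pytest.approx(50.0 + 33.0)
        assert s.position[0] == pytest.approx(75.0)

    def test_alignment_clamps_without_overshoot(self):
        arena = default_arena()
        s = idle_at(offset=9.0, mode=Mode.ALIGNING)
        s, _ = tick(s, 100.0, arena)  # way more than needed
        assert s.head_offset == 0.0
        assert s.body_heading == pytest.approx(99.0)
        assert s.mode is Mode.NAV_IDLE

    def test_wall_stops_walk_and_flags_collision(self):
        arena = default_arena()
        s = idle_at(y=299.0, mode=Mode.WALKING)  # 1 cm from the far wall
        s, hit = tick(s, 10.0, arena)
        assert hit
        assert s.mode is Mode.NAV_IDLE
        assert s.position[1] == pytest.approx(300.0, abs=0.01)

    def test_distance_accumulates_as_speed_times_time(self):
        arena = default_arena()
        s = idle_at(y=20.0, mode=Mode.WALKING)
        dist = 0.0
        t_walk = 0.0
        for k in range(200):
            prev = s.position
            s, _ = tick(s, 0.25, arena)
            dist += math.hypot(s.position[0] - prev[0],
                               s.position[1] - prev[1])
            t_walk += 0.25
        assert dist == pytest.approx(3.3 * t_walk, abs=1e-9)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            tick(idle_at(), 0.0, default_arena())


class TestVision:
    def test_single_disk_detected_at_center(self):
        s = idle_at(x=75.0, y=100.0, heading=90.0)
        arena = Arena(objects=[((75.0, 160.0), 1)])
        frame = render_view(s, arena)
        boxes = detect_objects(frame)
        assert len(boxes) == 1
        assert boxes[0].center[0] == pytest.approx(0.5, abs=0.02)
        assert boxes[0].center[1] == pytest.approx(0.5, abs=0.02)

    def test_empty_frame_detects_nothing(self):
        frame = ViewFrame(pixels=np.zeros((120, 160), dtype=int))
        assert detect_objects(frame) == []

    def test_two_disks_two_boxes_with_correct_geometry(self):
        s = idle_at(x=75.0, y=100.0, heading=90.0)
        arena = Arena(objects=[((60.0, 160.0), 1), ((90.0, 160.0), 2)])
        frame = render_view(s, arena)
        boxes = detect_objects(frame)
        assert len(boxes) == 2
        xs = sorted(b.center[0] for b in boxes)
        assert xs[0] < 0.5 < xs[1]
        # symmetric layout: centers mirror around the view center
        assert xs[0] + xs[1] == pytest.approx(1.0, abs=0.04)

    def test_object_behind_camera_not_rendered(self):
        s = idle_at(x=75.0, y=100.0, heading=90.0)
        arena = Arena(objects=[((75.0, 40.0), 1)])
        frame = render_view(s, arena)
        assert detect_objects(frame) == []

    def test_head_turn_shifts_object_in_view(self):
        arena = Arena(objects=[((75.0, 160.0), 1)])
        centered = render_view(idle_at(x=75.0, y=100.0), arena)
        turned = render_view(idle_at(x=75.0, y=100.0, offset=15.0), arena)
        x0 = detect_objects(centered)[0].center[0]
        x1 = detect_objects(turned)[0].center[0]
        assert x1 > x0  # looking left moves the object right in the frame


class TestZoneLogic:
    def test_virtual_center_is_mean_of_centers(self):
        from hybridbci.surrogate import BoundingBox
        boxes = [BoundingBox((0.3, 0.5), 0.1, 0.1),
                 BoundingBox((0.6, 0.5), 0.1, 0.1)]
        assert virtual_center(boxes) == pytest.approx((0.45, 0.5))
        assert in_central_zone(virtual_center(boxes))

    def test_single_offcenter_box_not_central(self):
        from hybridbci.surrogate import BoundingBox
        assert not in_central_zone(
            virtual_center([BoundingBox((0.1, 0.1), 0.1, 0.1)]))

    def test_half_open_boundary(self):
        from hybridbci.surrogate import BoundingBox
        boxes = [BoundingBox((0.2, 0.5), 0.1, 0.1),
                 BoundingBox((0.6, 0.5), 0.1, 0.1)]
        center = virtual_center(boxes)
        assert center == pytest.approx((0.4, 0.5))
        assert in_central_zone(center)      # 0.4 included
        assert not in_central_zone((0.6, 0.5))  # 0.6 excluded

    def test_empty_boxes_rejected(self):
        with pytest.raises(ValueError):
            virtual_center([])


class TestRecognitionTiming:
    @pytest.mark.parametrize("n_obj,flashes,expected", [
        (2, 5, 2.85),
        (4, 5, 5.35),
        (2, 1, 0.85),
    ])
    def test_flash_phase_duration(self, n_obj, flashes, expected):
        plan = recognition_sequence(n_obj, flashes)
        assert plan.flash_phase == pytest.approx(expected)

    def test_total_includes_rest_and_display(self):
        plan = recognition_sequence(2, 5)
        assert plan.total == pytest.approx(4.0 + 2.85 + 2.0)

    def test_single_object_rejected(self):
        with pytest.raises(ValueError):
            recognition_sequence(1, 5)


class TestClosedLoop:
    def test_scripted_brain_reaches_goal_without_collisions(
            self, trained_decoders):
        from hybridbci.closedloop import run_closed_loop
        res = run_closed_loop(trained_decoders, default_arena(),
                              waypoints=[(40.0, 200.0), (100.0, 255.0)],
                              seed=5)
        m = res.metrics
        assert res.reached_goal
        assert res.collisions == 0 and m.collisions == 0
        assert m.distance_travelled == pytest.approx(
            3.3 * res.walking_time, abs=1e-6)

    def test_replayed_log_reproduces_live_metrics(self, trained_decoders,
                                                  tmp_path):
        from hybridbci.closedloop import run_closed_loop
        from hybridbci.evaluation import (accumulate_metrics,
                                          read_trajectory, write_trajectory)
        res = run_closed_loop(trained_decoders, default_arena(),
                              waypoints=[(40.0, 120.0)], seed=6)
        path = tmp_path / "traj.tsv"
        write_trajectory(res.log, path)
        replayed = accumulate_metrics(read_trajectory(path))
        live = res.metrics
        for f in ("total_time", "distance_travelled", "forward_steps",
                  "turning_steps", "explored_angle", "transitions",
                  "collisions"):
            assert getattr(replayed, f) == pytest.approx(getattr(live, f))
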
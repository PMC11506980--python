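"""Arena mechanics: sensors, actuation, prey motion, catches, strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evochase import _kernels as K
from evochase._rng import SplitMix64, derive_seed
from evochase.asm import chaser_genome
from evochase.cpu8080 import CpuState
from evochase.world import (WorldConfig, WorldState, apply_agent_move,
                            check_catch_and_respawn, classify_strategy,
                            move_prey_circular, move_prey_random, read_move,
                            run_hunt_episode, run_hunt_step, torus_delta,
                            write_sensors)


@pytest.fixture
def cfg64():
    return WorldConfig(width=64, height=64, T=200)


def test_sensors_hold_raw_coordinate_bytes(memmap):
    cpu = CpuState(memmap)
    w = WorldState(agent_pos=(0, 0), prey_pos=(255, 255))
    write_sensors(w, cpu)
    s = memmap.sensor_agent_x
    assert list(cpu.mem[s:s + 4]) == [0x00, 0x00, 0xFF, 0xFF]
    w2 = WorldState(agent_pos=(128, 64), prey_pos=(1, 2))
    write_sensors(w2, cpu)
    assert list(cpu.mem[s:s + 2]) == [0x80, 0x40]


def test_program_writes_to_sensors_are_dropped(memmap):
    # MVI A,0x77 ; STA sensor_agent_x ; HLT
    from evochase.asm import assemble
    from evochase.cpu8080 import reset_slice, run_slice
    src = f"MVI A,0x77\nSTA 0x{memmap.sensor_agent_x:04X}\nHLT\n"
    code = assemble(src, memmap=memmap, pad_to=memmap.genome_len)
    cpu = CpuState(memmap, genome=code)
    cpu.mem[memmap.sensor_agent_x] = 0x21
    reset_slice(cpu)
    run_slice(cpu, budget=10)
    assert cpu.mem[memmap.sensor_agent_x] == 0x21


@pytest.mark.parametrize("byte,L,expected", [
    (0x00, 5, 0),
    (0xFF, 5, -1),          # two's complement -1
    (0x7F, 5, 5),           # +127 clipped to +L
    (0x80, 5, -5),          # -128 clipped to -L
    (0x03, 5, 3),
    (0xFB, 5, -5),
])
def test_read_move_twos_complement_and_clip(memmap, byte, L, expected):
    cpu = CpuState(memmap)
    cpu.mem[memmap.out_dx] = byte
    dx, dy = read_move(cpu, L)
    assert dx == expected and dy == 0


def test_agent_move_wraps_on_torus(cfg64):
    w = WorldState(agent_pos=(63, 0), prey_pos=(10, 10))
    apply_agent_move(w, cfg64, (1, -1))
    assert w.agent_pos == (0, 63)
    apply_agent_move(w, cfg64, (-1, 1))
    assert w.agent_pos == (63, 0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 5), st.integers(0, 2 ** 32 - 1))
def test_prey_step_never_exceeds_l(l, seed):
    cfg = WorldConfig(width=64, height=64, l=l)
    rng = SplitMix64(seed)
    w = WorldState(prey_pos=(30, 30))
    for _ in range(20):
        before = w.prey_pos
        move_prey_random(w, cfg, l, rng)
        dx = torus_delta(w.prey_pos[0], before[0], 64)
        dy = torus_delta(w.prey_pos[1], before[1], 64)
        assert abs(dx) <= l and abs(dy) <= l


def test_stationary_prey_when_l_zero(cfg64):
    rng = SplitMix64(1)
    w = WorldState(prey_pos=(5, 6))
    move_prey_random(w, cfg64, 0, rng)
    assert w.prey_pos == (5, 6)


class TestCircularPrey:
    def test_quarter_steps_return_to_start(self):
        cfg = WorldConfig(circle_radius=7.0, circle_step_angle=90.0)
        w = WorldState(circle_center=(100, 100), circle_k=0)
        move_prey_circular(w, cfg)  # k=1
        start = None
        positions = [w.prey_pos]
        for _ in range(3):
            move_prey_circular(w, cfg)
            positions.append(w.prey_pos)
        w2 = WorldState(circle_center=(100, 100), circle_k=0)
        for _ in range(8):
            move_prey_circular(w2, cfg)
        # period four: position after k and k+4 steps identical
        assert positions[0] == positions[-1] or len(set(positions)) <= 4
        move_prey_circular(w, cfg)
        assert w.prey_pos == positions[0]

    def test_cw_ccw_mirror_images(self):
        cfg = WorldConfig(circle_radius=10.0, circle_step_angle=30.0)
        a = WorldState(circle_center=(100, 100), circle_k=0)
        b = WorldState(circle_center=(100, 100), circle_k=0)
        move_prey_circular(a, cfg, direction="cw")
        move_prey_circular(b, cfg, direction="ccw")
        # mirrored across the horizontal axis through the centre
        assert a.prey_pos[0] == b.prey_pos[0]
        assert (a.prey_pos[1] - 100) == -(b.prey_pos[1] - 100)

    def test_zero_radius_is_stationary(self):
        cfg = WorldConfig(circle_radius=0.0, circle_step_angle=45.0)
        w = WorldState(circle_center=(50, 50), circle_k=0)
        p0 = (50, 50)
        w.prey_pos = p0
        for _ in range(5):
            move_prey_circular(w, cfg)
            assert w.prey_pos == p0


class TestCatchRespawn:
    def test_same_cell_zero_radius(self):
        cfg = WorldConfig(width=64, height=64, catch_radius=0)
        w = WorldState(agent_pos=(3, 3), prey_pos=(3, 3))
        w, caught = check_catch_and_respawn(w, cfg, SplitMix64(0))
        assert caught and w.catches == 1
        assert w.prey_pos != w.agent_pos  # exactly one prey, elsewhere

    def test_distance_two_radius_one_misses(self):
        cfg = WorldConfig(width=64, height=64, catch_radius=1)
        w = WorldState(agent_pos=(3, 3), prey_pos=(5, 3))
        w, caught = check_catch_and_respawn(w, cfg, SplitMix64(0))
        assert not caught and w.catches == 0
        assert w.prey_pos == (5, 3)

    def test_chebyshev_metric_wraps(self):
        cfg = WorldConfig(width=64, height=64, catch_radius=1)
        w = WorldState(agent_pos=(0, 0), prey_pos=(63, 63))
        _, caught = check_catch_and_respawn(w, cfg, SplitMix64(0))
        assert caught


class TestHuntPipeline:
    def test_null_genome_agent_never_moves(self, cfg64, memmap):
        cpu = CpuState(memmap, genome=bytes(memmap.genome_len))
        rng = SplitMix64(derive_seed(3, 1))
        w = WorldState(agent_pos=(10, 10), prey_pos=(40, 40))
        for _ in range(50):
            run_hunt_step(cpu, w, cfg64, rng)
        assert w.agent_pos == (10, 10)

    def test_chaser_catches_stationary_prey_in_d_over_L_steps(self, memmap):
        # stationary prey (l=0) at Chebyshev distance 15, L=5 -> 3 steps
        cfg = WorldConfig(width=64, height=64, l=0, L=5, catch_radius=0)
        cpu = CpuState(memmap, genome=chaser_genome(memmap, clip=5))
        w = WorldState(agent_pos=(10, 10), prey_pos=(25, 22))
        rng = SplitMix64(7)
        steps = 0
        caught = False
        while not caught and steps < 10:
            _, _, caught = run_hunt_step(cpu, w, cfg, rng)
            steps += 1
        assert caught and steps == 3

    def test_python_pipeline_matches_compiled_kernel(self, cfg64, memmap):
        """The readable step pipeline and the numba epoch kernel produce
        bit-identical trajectories from the same stream seed."""
        seed = derive_seed(11, 5)
        code = chaser_genome(memmap)
        cpu_py = CpuState(memmap, genome=code)
        _, w = run_hunt_episode(cpu_py, cfg64, SplitMix64(seed), record=True)

        cpu_k = CpuState(memmap, genome=code)
        rs = np.array([seed], dtype=np.uint64)
        traj = np.zeros((cfg64.T, 6), dtype=np.int64)
        catches = K.hunt_steps(
            cpu_k.mem, cpu_k.st, rs, cfg64.T, cfg64.width, cfg64.height,
            cfg64.l, cfg64.L, cfg64.catch_radius, cfg64.motion_code,
            cfg64.circle_radius, cfg64.circle_step_angle, 400,
            memmap.genome_base, memmap.genome_len, memmap.sensor_agent_x,
            memmap.out_dx, memmap.out_dy, memmap.sp_top, -1, -1, True, traj)
        assert catches == w.catches
        assert np.array_equal(np.array(w.trajectory, dtype=np.int64), traj)
        assert np.array_equal(cpu_py.mem, cpu_k.mem)

    def test_episode_replay_is_deterministic(self, cfg64, memmap):
        outs = []
        for _ in range(2):
            cpu = CpuState(memmap, genome=chaser_genome(memmap))
            _, w = run_hunt_episode(cpu, cfg64, SplitMix64(42), record=True)
            outs.append((w.catches, tuple(map(tuple, w.trajectory))))
        assert outs[0] == outs[1]


class TestClassifyStrategy:
    @staticmethod
    def _traj(deltas):
        rows = []
        for i, (dx, dy) in enumerate(deltas):
            rows.append((i, (100 + dx) % 256, (100 + dy) % 256, 100, 100, 0))
        return pd.DataFrame(rows, columns=["step", "agent_x", "agent_y",
                                           "prey_x", "prey_y", "caught"])

    def test_vertical_alignment_detected(self):
        # x offset collapses first, then y
        deltas = [(30 - 3 * i, 40) for i in range(10)] \
            + [(0, 40 - 4 * i) for i in range(11)]
        assert classify_strategy(self._traj(deltas)) == "vertical_align"

    def test_horizontal_alignment_detected(self):
        deltas = [(40, 30 - 3 * i) for i in range(10)] \
            + [(40 - 4 * i, 0) for i in range(11)]
        assert classify_strategy(self._traj(deltas)) == "horizontal_align"

    def test_diagonal_pursuit_detected(self):
        deltas = [(40 - 4 * i, 40 - 4 * i) for i in range(11)] + [(0, 0)] * 4
        assert classify_strategy(self._traj(deltas)) == "diagonal_direct"

    def test_random_walk_is_unclassified(self):
        rng = np.random.default_rng(5)
        deltas = np.cumsum(rng.integers(-3, 4, size=(120, 2)), axis=0) + 40
        assert classify_strategy(self._traj(list(map(tuple, deltas)))) == "none"

    def test_short_trajectory_is_unclassified(self):
        assert classify_strategy(self._traj([(5, 5)] * 5)) == "none"
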
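"""The hunting arena: prey motion, agent actuation, catches and trajectories.

The field is a torus (coordinates wrap modulo the field size, which matches
the 8-bit arithmetic of the agent brains on the default 256x256 field).  One
prey exists at a time; when it is caught a new one appears on a uniformly
random cell.  Prey either performs a jumpy random walk (per-axis uniform
steps of at most ``l`` cells) or moves along a circle in a fixed direction.
The agent's jump is read from its actuator cells as two's-complement bytes
and clipped to at most ``L`` cells per axis.

The functions here are the readable reference pipeline; the evolution module
runs the same pipeline inside a compiled kernel, and a test asserts that the
two produce bit-identical episodes from the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cpu8080
from ._rng import SplitMix64
from .cpu8080 import CpuState, default_budget

__all__ = [
    "WorldConfig", "WorldState", "write_sensors", "read_move",
    "move_prey_random", "move_prey_circular", "apply_agent_move",
    "check_catch_and_respawn", "run_hunt_step", "run_hunt_episode",
    "classify_strategy", "trajectory_frame", "torus_delta",
]

PREY_MOTIONS = ("random", "circular_cw", "circular_ccw")


@dataclass(frozen=True)
class WorldConfig:
    """Arena geometry and motion parameters.

    ``l``/``L`` are the prey/agent per-axis maximum step, ``T`` the number of
    world steps per epoch, ``catch_radius`` the Chebyshev catch distance.
    """

    width: int = 256
    height: int = 256
    l: int = 3
    L: int = 5
    catch_radius: int = 1
    T: int = 1000
    prey_motion: str = "random"
    circle_radius: float = 10.0
    circle_step_angle: float = 15.0  # degrees per world step

    def __post_init__(self):
        if not (1 <= self.width <= 256 and 1 <= self.height <= 256):
            raise ValueError("field dimensions must be in [1, 256] "
                             "(coordinates are sensor bytes)")
        if self.l < 0 or self.L < 1 or self.T < 1 or self.catch_radius < 0:
            raise ValueError("require l >= 0, L >= 1, T >= 1, catch_radius >= 0")
        if self.prey_motion not in PREY_MOTIONS:
            raise ValueError(f"prey_motion must be one of {PREY_MOTIONS}")

    @property
    def motion_code(self) -> int:
        return PREY_MOTIONS.index(self.prey_motion)


@dataclass
class WorldState:
    """Mutable per-agent world: positions, catch count, step index."""

    agent_pos: tuple[int, int] = (0, 0)
    prey_pos: tuple[int, int] = (1, 1)
    catches: int = 0
    step_index: int = 0
    # circular-motion state: circle centre and integer angle index
    circle_center: tuple[int, int] = (0, 0)
    circle_k: int = 0
    trajectory: list | None = None

    @classmethod
    def random_init(cls, cfg: WorldConfig, rng: SplitMix64,
                    record: bool = False) -> "WorldState":
        """Draw agent and prey starting positions from the agent's stream."""
        ax = rng.below(cfg.width)
        ay = rng.below(cfg.height)
        ws = cls(agent_pos=(ax, ay), trajectory=[] if record else None)
        _spawn_prey(ws, cfg, rng)
        return ws


def _circle_pos(cfg: WorldConfig, center, k: int, direction: int):
    theta = direction * k * cfg.circle_step_angle * math.pi / 180.0
    px = int(math.floor(center[0] + cfg.circle_radius * math.cos(theta) + 0.5))
    py = int(math.floor(center[1] + cfg.circle_radius * math.sin(theta) + 0.5))
    return px % cfg.width, py % cfg.height


def _direction(cfg: WorldConfig) -> int:
    return -1 if cfg.prey_motion == "circular_cw" else 1


def _spawn_prey(world: WorldState, cfg: WorldConfig, rng: SplitMix64) -> None:
    """Place a fresh prey on a random cell distinct from the agent."""
    if cfg.prey_motion == "random":
        while True:
            px = rng.below(cfg.width)
            py = rng.below(cfg.height)
            if (px, py) != world.agent_pos:
                break
        world.prey_pos = (px, py)
    else:
        while True:
            cc = (rng.below(cfg.width), rng.below(cfg.height))
            pos = _circle_pos(cfg, cc, 0, _direction(cfg))
            if pos != world.agent_pos:
                break
        world.circle_center = cc
        world.circle_k = 0
        world.prey_pos = pos


def write_sensors(world: WorldState, cpu: CpuState) -> CpuState:
    """Expose current coordinates in the four sensor cells (host write)."""
    mm = cpu.memmap
    cpu.mem[mm.sensor_agent_x] = world.agent_pos[0]
    cpu.mem[mm.sensor_agent_y] = world.agent_pos[1]
    cpu.mem[mm.sensor_prey_x] = world.prey_pos[0]
    cpu.mem[mm.sensor_prey_y] = world.prey_pos[1]
    return cpu


def read_move(cpu: CpuState, L: int) -> tuple[int, int]:
    """Actuator bytes as two's-complement, clipped per axis to [-L, L]."""
    mm = cpu.memmap
    out = []
    for addr in (mm.out_dx, mm.out_dy):
        v = int(cpu.mem[addr])
        if v >= 128:
            v -= 256
        out.append(max(-L, min(L, v)))
    return out[0], out[1]


def move_prey_random(world: WorldState, cfg: WorldConfig, l: int,
                     rng: SplitMix64) -> WorldState:
    """Random-walk jump: per-axis uniform integer step in [-l, l], wrapped."""
    if l > 0:
        dx = rng.below(2 * l + 1) - l
        dy = rng.below(2 * l + 1) - l
        px, py = world.prey_pos
        world.prey_pos = ((px + dx) % cfg.width, (py + dy) % cfg.height)
    return world


def move_prey_circular(world: WorldState, cfg: WorldConfig,
                       direction: str | None = None) -> WorldState:
    """Advance the prey one angular step along its circle."""
    d = -1 if direction == "cw" else 1 if direction == "ccw" else _direction(cfg)
    world.circle_k += 1
    world.prey_pos = _circle_pos(cfg, world.circle_center, world.circle_k, d)
    return world


def apply_agent_move(world: WorldState, cfg: WorldConfig,
                     move: tuple[int, int]) -> WorldState:
    dx, dy = move
    ax, ay = world.agent_pos
    world.agent_pos = ((ax + dx) % cfg.width, (ay + dy) % cfg.height)
    return world


def torus_delta(a: int, b: int, size: int) -> int:
    """Signed shortest displacement from b to a on a ring of given size."""
    d = (a - b) % size
    return d - size if d > size // 2 else d


def _torus_cheb(world: WorldState, cfg: WorldConfig) -> int:
    ax, ay = world.agent_pos
    px, py = world.prey_pos
    return max(abs(torus_delta(ax, px, cfg.width)),
               abs(torus_delta(ay, py, cfg.height)))


def check_catch_and_respawn(world: WorldState, cfg: WorldConfig,
                            rng: SplitMix64) -> tuple[WorldState, bool]:
    """Catch when Chebyshev distance <= catch_radius; then respawn the prey."""
    caught = _torus_cheb(world, cfg) <= cfg.catch_radius
    if caught:
        world.catches += 1
        _spawn_prey(world, cfg, rng)
    return world, caught


def run_hunt_step(cpu: CpuState, world: WorldState, cfg: WorldConfig,
                  rng: SplitMix64, budget: int | None = None
                  ) -> tuple[CpuState, WorldState, bool]:
    """One world step: sense, think, act, catch, prey move."""
    if budget is None:
        budget = default_budget(cpu.memmap.genome_len)
    write_sensors(world, cpu)
    cpu8080.reset_slice(cpu)
    cpu8080.run_slice(cpu, budget)
    move = read_move(cpu, cfg.L)
    apply_agent_move(world, cfg, move)
    world, caught = check_catch_and_respawn(world, cfg, rng)
    if cfg.prey_motion == "random":
        move_prey_random(world, cfg, cfg.l, rng)
    else:
        move_prey_circular(world, cfg)
    if world.trajectory is not None:
        world.trajectory.append((world.step_index, world.agent_pos[0],
                                 world.agent_pos[1], world.prey_pos[0],
                                 world.prey_pos[1], int(caught)))
    world.step_index += 1
    return cpu, world, caught


def run_hunt_episode(cpu: CpuState, cfg: WorldConfig, rng: SplitMix64,
                     steps: int | None = None, record: bool = False,
                     world: WorldState | None = None
                     ) -> tuple[CpuState, WorldState]:
    """Run a full episode (default T steps) on a freshly initialised world."""
    if steps is None:
        steps = cfg.T
    if world is None:
        world = WorldState.random_init(cfg, rng, record=record)
    elif record and world.trajectory is None:
        world.trajectory = []
    for _ in range(steps):
        run_hunt_step(cpu, world, cfg, rng)
    return cpu, world


TRAJ_COLUMNS = ["step", "agent_x", "agent_y", "prey_x", "prey_y", "caught"]


def trajectory_frame(world_or_rows) -> pd.DataFrame:
    """Trajectory as a DataFrame with the documented CSV columns."""
    rows = (world_or_rows.trajectory
            if isinstance(world_or_rows, WorldState) else world_or_rows)
    return pd.DataFrame(list(rows) if rows else [], columns=TRAJ_COLUMNS)


# ------------------------------------------------------------ strategy labels
def classify_strategy(trajectory, width: int = 256, height: int = 256,
                      align_tol: int = 2, align_run: int = 3,
                      majority: float = 0.6) -> str:
    """Heuristic label for the catching strategy shown by a trajectory.

    Looks at each approach segment (the steps leading up to a catch; the
    whole trajectory if there is no catch) and asks which relative coordinate
    collapses to ~0 first: the x offset first means the agent lines up in the
    vertical column of the prey (``vertical_align``), y first means
    horizontal alignment, and both together mean a straight diagonal pursuit
    (``diagonal_direct``).  An axis counts as collapsed once |delta| <=
    ``align_tol`` for ``align_run`` consecutive steps; a label is returned
    only if at least ``majority`` of the segments agree, otherwise ``none``.
    """
    df = trajectory if isinstance(trajectory, pd.DataFrame) \
        else trajectory_frame(trajectory)
    if len(df) < 10:
        return "none"
    dx = np.array([torus_delta(a, p, width)
                   for a, p in zip(df.agent_x, df.prey_x)])
    dy = np.array([torus_delta(a, p, height)
                   for a, p in zip(df.agent_y, df.prey_y)])
    caught = df.caught.to_numpy().astype(bool)
    bounds = [0] + [i + 1 for i in np.flatnonzero(caught)]
    if bounds[-1] < len(df):
        bounds.append(len(df))
    votes = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < align_run:
            continue
        tx = _first_aligned(np.abs(dx[s:e]), align_tol, align_run)
        ty = _first_aligned(np.abs(dy[s:e]), align_tol, align_run)
        if tx is None and ty is None:
            votes.append("none")
        elif tx is not None and ty is not None and abs(tx - ty) <= align_run:
            votes.append("diagonal_direct")
        elif ty is None or (tx is not None and tx < ty):
            votes.append("vertical_align")
        else:
            votes.append("horizontal_align")
    if not votes:
        return "none"
    for label in ("diagonal_direct", "vertical_align", "horizontal_align"):
        if votes.count(label) / len(votes) >= majority:
            return label
    return "none"


def _first_aligned(absd: np.ndarray, tol: int, run: int) -> int | None:
    ok = absd <= tol
    count = 0
    for i, v in enumerate(ok):
        count = count + 1 if v else 0
        if count >= run:
            return i - run + 1
    return None
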
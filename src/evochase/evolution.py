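"""Darwinian population dynamics over i8080 machine-code genomes.

Each epoch every agent hunts for T steps on its own independent world; agents
are then ranked by catches.  The bottom third is destroyed, the top third
survives *and* reproduces (offspring counts drawn catch-proportionally), and
the middle third survives childless.  Offspring inherit the parent genome
with each byte independently resampled with probability ``delta``; genome
length ``psi`` is constant forever.

Everything is replayable bit-exactly from the master seed: hunting streams
are derived per (epoch, agent), selection streams per epoch, so results do
not depend on execution order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from ._rng import derive_seed
from .cpu8080 import MEM_SIZE, MemoryMap, default_budget
from .world import WorldConfig

__all__ = [
    "Genome", "EvolutionConfig", "EvolutionResult", "Population",
    "init_population", "mutate", "rank_select_reproduce", "run_evolution",
    "sweep_parameter",
]

# seed-stream tags (arbitrary distinct constants)
_TAG_INIT = 0x01
_TAG_HUNT = 0x02
_TAG_SELECT = 0x03


@dataclass(frozen=True)
class Genome:
    """A heritable block of machine code with a lineage identifier."""

    code: bytes
    lineage_id: int = 0

    def __len__(self):
        return len(self.code)

    @property
    def sha1(self) -> str:
        return hashlib.sha1(self.code).hexdigest()


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one evolutionary run."""

    population_size: int = 100
    epochs: int = 10_000
    psi: int = 100            # genome length in bytes
    delta: float = 0.05       # per-byte mutation probability
    destroy_fraction: float = 1 / 3
    elite_fraction: float = 1 / 3
    seed: int = 0
    slice_budget: int | None = None   # default: 4 * psi
    world: WorldConfig = field(default_factory=WorldConfig)

    def __post_init__(self):
        if self.population_size < 1 or self.epochs < 1 or self.psi < 1:
            raise ValueError("population_size, epochs and psi must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if not (0.0 <= self.destroy_fraction <= 1.0
                and 0.0 <= self.elite_fraction <= 1.0
                and self.destroy_fraction + self.elite_fraction <= 1.0):
            raise ValueError("selection fractions must lie in [0, 1] and "
                             "destroy + elite <= 1")

    @property
    def budget(self) -> int:
        return self.slice_budget if self.slice_budget else default_budget(self.psi)

    @property
    def memmap(self) -> MemoryMap:
        return MemoryMap(genome_len=self.psi)


class Population:
    """Array-of-structs ensemble state used by the compiled epoch kernel."""

    def __init__(self, cfg: EvolutionConfig):
        n = cfg.population_size
        self.cfg = cfg
        self.genomes = np.zeros((n, cfg.psi), dtype=np.uint8)
        self.mems = np.zeros((n, MEM_SIZE), dtype=np.uint8)
        self.sts = np.zeros((n, K.STATE_LEN), dtype=np.int64)
        self.lineage_ids = np.arange(n, dtype=np.int64)
        self.parent_ids = np.full(n, -1, dtype=np.int64)
        self.ages = np.zeros(n, dtype=np.int64)
        self.catches = np.zeros(n, dtype=np.int64)
        self._next_id = n

    def __len__(self):
        return self.genomes.shape[0]

    def birth(self, slot: int, code: np.ndarray, parent_id: int) -> None:
        """Install a fresh agent: new genome, cleared memory and CPU state."""
        mm = self.cfg.memmap
        self.genomes[slot] = code
        self.mems[slot] = 0
        self.mems[slot, mm.genome_base:mm.genome_end] = code
        self.sts[slot] = 0
        self.ages[slot] = 0
        self.parent_ids[slot] = parent_id
        self.lineage_ids[slot] = self._next_id
        self._next_id += 1

    def agent_genome(self, i: int) -> Genome:
        return Genome(self.genomes[i].tobytes(), int(self.lineage_ids[i]))


def init_population(cfg: EvolutionConfig,
                    rng: np.random.Generator | None = None) -> Population:
    """Uniform random genomes: psi i.i.d. bytes per agent."""
    if rng is None:
        rng = np.random.default_rng(derive_seed(cfg.seed, _TAG_INIT))
    pop = Population(cfg)
    codes = rng.integers(0, 256, size=(len(pop), cfg.psi), dtype=np.uint8)
    for i in range(len(pop)):
        pop.birth(i, codes[i], parent_id=-1)
    pop.parent_ids[:] = -1
    return pop


def mutate(genome: Genome | bytes | np.ndarray, delta: float,
           rng: np.random.Generator) -> Genome | np.ndarray:
    """Each byte is independently resampled (uniform, may repeat) w.p. delta."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    is_genome = isinstance(genome, Genome)
    code = np.frombuffer(genome.code if is_genome else bytes(genome),
                         dtype=np.uint8).copy()
    hit = rng.random(len(code)) < delta
    n = int(hit.sum())
    if n:
        code[hit] = rng.integers(0, 256, size=n, dtype=np.uint8)
    return replace(genome, code=code.tobytes()) if is_genome else code


def rank_select_reproduce(pop: Population, rng: np.random.Generator,
                          delta: float | None = None) -> Population:
    """Apply one round of rank selection and catch-proportional reproduction.

    Ranking ties are broken by the selection stream.  Survivors (elite and
    middle) keep their CPU scratch state; each destroyed slot is refilled by
    a mutated copy of an elite, drawn multinomially with probabilities
    proportional to elite catches (uniform if no elite caught anything).
    """
    n = len(pop)
    if n == 0:
        raise ValueError("empty population")
    cfg = pop.cfg
    if delta is None:
        delta = cfg.delta
    n_destroy = int(round(n * cfg.destroy_fraction))
    n_elite = int(round(n * cfg.elite_fraction))
    if n_destroy == 0 or n_elite == 0:
        pop.ages += 1
        return pop
    tiebreak = rng.random(n)
    order = np.lexsort((tiebreak, -pop.catches))   # descending catches
    elite = order[:n_elite]
    doomed = order[n - n_destroy:]
    weights = pop.catches[elite].astype(float)
    total = weights.sum()
    p = weights / total if total > 0 else np.full(n_elite, 1.0 / n_elite)
    counts = rng.multinomial(n_destroy, p)
    children_parents = np.repeat(elite, counts)
    for slot, parent in zip(doomed, children_parents):
        child = mutate(pop.genomes[parent], delta, rng)
        pop.birth(int(slot), child, parent_id=int(pop.lineage_ids[parent]))
    survivors = np.setdiff1d(np.arange(n), doomed, assume_unique=False)
    pop.ages[survivors] += 1
    return pop


@dataclass
class EvolutionResult:
    """Per-epoch ensemble catch totals plus the final genomes."""

    raw_catches: np.ndarray          # shape (epochs,), ensemble totals
    best_hashes: list[str]           # per-epoch best-agent genome sha1
    final_genomes: list[Genome]
    config: EvolutionConfig

    @property
    def t(self) -> np.ndarray:
        """Astronomical time axis: epoch indices 1..N."""
        return np.arange(1, len(self.raw_catches) + 1)

    def to_frame(self) -> pd.DataFrame:
        raw = np.asarray(self.raw_catches)
        mx = raw.max()
        k = raw / mx if mx > 0 else np.zeros_like(raw, dtype=float)
        return pd.DataFrame({"epoch": self.t, "total_catches": raw, "K": k,
                             "best_hash": self.best_hashes})


def _epoch_seeds(cfg: EvolutionConfig, epoch: int) -> np.ndarray:
    return np.array(
        [derive_seed(cfg.seed, _TAG_HUNT, epoch, i)
         for i in range(cfg.population_size)], dtype=np.uint64)


def run_epoch(pop: Population, epoch: int) -> np.ndarray:
    """Hunt one epoch for the whole ensemble (compiled path)."""
    cfg = pop.cfg
    w = cfg.world
    mm = cfg.memmap
    K.run_epoch_all(pop.mems, pop.sts, _epoch_seeds(cfg, epoch), pop.catches,
                    w.T, w.width, w.height, w.l, w.L, w.catch_radius,
                    w.motion_code, w.circle_radius, w.circle_step_angle,
                    cfg.budget, mm.genome_base, mm.genome_len,
                    mm.sensor_agent_x, mm.out_dx, mm.out_dy, mm.sp_top)
    return pop.catches


def run_evolution(cfg: EvolutionConfig, pop: Population | None = None,
                  start_epoch: int = 0,
                  prior_catches: np.ndarray | None = None,
                  prior_best: list | None = None,
                  progress: bool = False,
                  checkpoint_cb=None, checkpoint_every: int = 0
                  ) -> EvolutionResult:
    """Run the full evolutionary experiment, reproducible from cfg.seed.

    ``pop``/``start_epoch``/``prior_catches``/``prior_best`` allow resuming a
    checkpointed run; because all random streams are derived from
    (seed, epoch, agent), a resumed run is bit-identical to an uninterrupted
    one.  ``checkpoint_cb(epoch, pop, totals, best)`` is invoked every
    ``checkpoint_every`` epochs when set.
    """
    if pop is None:
        pop = init_population(cfg)
    totals = [] if prior_catches is None else list(prior_catches)
    best = [] if prior_best is None else list(prior_best)
    for epoch in range(start_epoch, cfg.epochs):
        catches = run_epoch(pop, epoch)
        totals.append(int(catches.sum()))
        best.append(pop.agent_genome(int(np.argmax(catches))).sha1)
        sel_rng = np.random.default_rng(derive_seed(cfg.seed, _TAG_SELECT, epoch))
        rank_select_reproduce(pop, sel_rng)
        if progress and (epoch + 1) % 100 == 0:
            print(f"epoch {epoch + 1}/{cfg.epochs}: total={totals[-1]}",
                  flush=True)
        if (checkpoint_cb is not None and checkpoint_every > 0
                and (epoch + 1) % checkpoint_every == 0):
            checkpoint_cb(epoch + 1, pop, totals, best)
    final = [pop.agent_genome(i) for i in range(len(pop))]
    return EvolutionResult(np.asarray(totals, dtype=np.int64), best, final, cfg)


def sweep_parameter(cfg: EvolutionConfig, param: str, values) -> pd.DataFrame:
    """Run the experiment across a grid of psi or delta values.

    All grid points share the same master seed.  ``K`` is the total number
    of catches over the whole run, normalised by the maximum across the
    grid (the best grid point has K = 1).
    """
    if param not in ("psi", "delta"):
        raise ValueError("param must be 'psi' or 'delta'")
    values = list(values)
    if not values:
        raise ValueError("empty parameter grid")
    totals = []
    for v in values:
        c = replace(cfg, **{param: v})
        res = run_evolution(c)
        totals.append(int(res.raw_catches.sum()))
    totals = np.asarray(totals, dtype=float)
    mx = totals.max()
    k = totals / mx if mx > 0 else np.zeros_like(totals)
    return pd.DataFrame({param: values, "total_catches": totals.astype(int),
                         "K": k})
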
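import pytest

from evochase.asm import chaser_genome
from evochase.cpu8080 import CpuState, MemoryMap
from evochase.evolution import EvolutionConfig, run_evolution
from evochase.world import WorldConfig


@pytest.fixture
def memmap():
    return MemoryMap()


@pytest.fixture
def chaser(memmap):
    return chaser_genome(memmap)


@pytest.fixture
def fresh_cpu(memmap):
    def make(genome=None):
        return CpuState(memmap, genome=genome)
    return make


def scaled_config(seed: int) -> EvolutionConfig:
    """The scaled-down evolutionary study: 30 agents on a 64x64 field."""
    return EvolutionConfig(population_size=30, epochs=1500, psi=100,
                           delta=0.05, seed=seed,
                           world=WorldConfig(width=64, height=64, T=200))


@pytest.fixture(scope="session")
def scaled_replicates():
    """Ten seeded replicates of the scaled study (shared across tests)."""
    return {seed: run_evolution(scaled_config(seed)).raw_catches
            for seed in range(1, 11)}
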
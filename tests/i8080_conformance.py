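"""Randomized conformance harness: package emulator vs the table oracle."""

from __future__ import annotations

import numpy as np

from evochase.cpu8080 import CpuState, MemoryMap, step_instruction

from oracle_i8080 import Ref8080

FLAG_NAMES = ("S", "Z", "AC", "P", "CY")
REG_NAMES = ("A", "B", "C", "D", "E", "H", "L")


def run_conformance(cases_per_opcode: int = 2, seed: int = 0,
                    memmap: MemoryMap | None = None) -> list[str]:
    """Execute every opcode from random states on both implementations.

    Returns a list of human-readable mismatch descriptions (empty when the
    emulator is conformant).  State, memory image, PC/SP and all five flags
    are compared after a single instruction.
    """
    mm = memmap or MemoryMap()
    readonly = ((mm.genome_base, mm.genome_end - 1),
                (mm.sensor_agent_x, mm.sensor_prey_y))
    rng = np.random.default_rng(seed)
    mismatches = []
    for opcode in range(256):
        for _ in range(cases_per_opcode):
            mem = rng.integers(0, 256, size=65536, dtype=np.uint8)
            pc = int(rng.integers(0, 0x10000))
            mem[pc] = opcode
            regs = rng.integers(0, 256, size=7)
            flags = rng.integers(0, 2, size=5).astype(bool)
            sp = int(rng.integers(0, 0x10000))

            cpu = CpuState(mm)
            cpu.mem[:] = mem
            ref = Ref8080(mem.tobytes(), readonly=readonly)
            for name, val in zip(REG_NAMES, regs):
                setattr(cpu, name, int(val))
                setattr(ref, name, int(val))
            for name, val in zip(FLAG_NAMES, flags):
                setattr(cpu, name, bool(val))
                setattr(ref, name, bool(val))
            cpu.PC = ref.PC = pc
            cpu.SP = ref.SP = sp

            step_instruction(cpu)
            ref.step()

            diffs = _diff(cpu, ref)
            if diffs:
                mismatches.append(f"opcode {opcode:#04x} at PC={pc:#06x}: "
                                  + "; ".join(diffs))
    return mismatches


def _diff(cpu: CpuState, ref: Ref8080) -> list[str]:
    out = []
    for name in REG_NAMES:
        a, b = getattr(cpu, name), getattr(ref, name)
        if a != b:
            out.append(f"{name}: {a:#04x} != {b:#04x}")
    for name in FLAG_NAMES:
        a, b = getattr(cpu, name), getattr(ref, name)
        if a != b:
            out.append(f"flag {name}: {a} != {b}")
    if cpu.PC != ref.PC:
        out.append(f"PC: {cpu.PC:#06x} != {ref.PC:#06x}")
    if cpu.SP != ref.SP:
        out.append(f"SP: {cpu.SP:#06x} != {ref.SP:#06x}")
    if cpu.halted != ref.halted:
        out.append(f"halted: {cpu.halted} != {ref.halted}")
    if not np.array_equal(cpu.mem, np.frombuffer(ref.mem, dtype=np.uint8)):
        where = np.flatnonzero(
            cpu.mem != np.frombuffer(ref.mem, dtype=np.uint8))[:4]
        out.append(f"memory differs at {[hex(int(w)) for w in where]}")
    return out
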
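"""Sandboxed Intel i8080 emulator that serves as the agent's brain.

An agent is a fixed-length block of i8080 machine code (its genome) placed in
a 64 KiB address space together with a memory-mapped sensor/actuator region:

* four read-only sensor cells holding the current agent and prey coordinates,
* two writable actuator cells holding the signed jump vector (dx, dy),
* a scratch RAM region (also hosting the stack) that persists between steps.

Every world step the CPU runs one "thought slice": registers and flags are
cleared, PC returns to the genome base, and up to ``budget`` instructions are
executed.  Scratch RAM and the actuator cells are *not* cleared, so a genome
can carry state from one step to the next — this is what makes behaviours
such as discriminating clockwise from counter-clockwise prey possible even
though the sensors only ever expose current coordinates.

The emulator is deterministic and total: undocumented opcodes, IN/OUT, EI/DI
and RST are executed as no-effect instructions, HLT ends the slice, and
writes to the sensor cells or the genome region are silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels as K

MEM_SIZE = 0x10000

__all__ = [
    "MemoryMap", "CpuState", "reset_slice", "step_instruction", "run_slice",
    "default_budget", "load_genome", "save_genome", "parse_hex_genome",
    "format_hex_genome",
]


@dataclass(frozen=True)
class MemoryMap:
    """Layout of the agent's address space.

    The defaults put the actuator cells at the very bottom of page zero.
    Register pairs are cleared at the start of every slice, so a fresh
    register pair already points at (or one INX away from) the actuators:
    single random bytes such as ``DCR A; STAX B`` are enough to produce
    movement, which gives blind evolution a findable first foothold.
    """

    genome_base: int = 0x0100
    genome_len: int = 100
    out_dx: int = 0x0000
    out_dy: int = 0x0001
    sensor_agent_x: int = 0x0004
    sensor_agent_y: int = 0x0005
    sensor_prey_x: int = 0x0006
    sensor_prey_y: int = 0x0007
    scratch_base: int = 0x0800
    scratch_len: int = 0x0800

    def __post_init__(self):
        s = self.sensor_agent_x
        if (self.sensor_agent_y, self.sensor_prey_x, self.sensor_prey_y) != (
                s + 1, s + 2, s + 3):
            raise ValueError("sensor cells must be four consecutive bytes")
        regions = [
            ("genome", self.genome_base, self.genome_base + self.genome_len),
            ("sensors", s, s + 4),
            ("actuators", min(self.out_dx, self.out_dy),
             max(self.out_dx, self.out_dy) + 1),
            ("scratch", self.scratch_base,
             self.scratch_base + self.scratch_len),
        ]
        for i, (na, a0, a1) in enumerate(regions):
            if not (0 <= a0 <= a1 <= MEM_SIZE):
                raise ValueError(f"{na} region out of the 64 KiB space")
            for nb, b0, b1 in regions[i + 1:]:
                if a0 < b1 and b0 < a1:
                    raise ValueError(f"{na} and {nb} regions overlap")

    @property
    def genome_end(self) -> int:
        return self.genome_base + self.genome_len

    @property
    def sp_top(self) -> int:
        """Initial stack pointer: one past the top of scratch RAM."""
        return self.scratch_base + self.scratch_len


def default_budget(genome_len: int) -> int:
    """Default slice budget: 4 executed instructions per genome byte.

    The factor leaves room for loops and branches while still guaranteeing
    that every slice terminates.
    """
    return 4 * genome_len


_REGS = {"A": K.A, "B": K.B, "C": K.C, "D": K.D, "E": K.E, "H": K.H, "L": K.L}
_FLAGS = {"S": K.FS, "Z": K.FZ, "AC": K.FAC, "P": K.FP, "CY": K.FCY}


class CpuState:
    """One agent CPU: a 64 KiB memory image plus the packed register vector.

    Register and flag access goes through attributes (``cpu.A``, ``cpu.CY``,
    ...); the underlying numpy arrays (``cpu.mem``, ``cpu.st``) are what the
    compiled kernels operate on.
    """

    __slots__ = ("mem", "st", "memmap")

    def __init__(self, memmap: MemoryMap | None = None,
                 genome: bytes | np.ndarray | None = None):
        self.memmap = memmap if memmap is not None else MemoryMap()
        self.mem = np.zeros(MEM_SIZE, dtype=np.uint8)
        self.st = np.zeros(K.STATE_LEN, dtype=np.int64)
        self.st[K.F] = K.FBASE
        self.st[K.PC] = self.memmap.genome_base
        self.st[K.SP] = self.memmap.sp_top
        if genome is not None:
            self.load_genome(genome)

    # -- register / flag attribute access -----------------------------------
    def __getattr__(self, name):
        if name in _REGS:
            return int(self.st[_REGS[name]])
        if name in _FLAGS:
            return bool(self.st[K.F] & _FLAGS[name])
        if name == "PC":
            return int(self.st[K.PC])
        if name == "SP":
            return int(self.st[K.SP])
        if name == "halted":
            return bool(self.st[K.HALT])
        if name == "executed_count":
            return int(self.st[K.EXEC])
        raise AttributeError(name)

    def __setattr__(self, name, value):
        if name in CpuState.__slots__:
            object.__setattr__(self, name, value)
        elif name in _REGS:
            self.st[_REGS[name]] = value & 0xFF
        elif name in _FLAGS:
            if value:
                self.st[K.F] |= _FLAGS[name]
            else:
                self.st[K.F] &= ~_FLAGS[name]
        elif name == "PC":
            self.st[K.PC] = value & 0xFFFF
        elif name == "SP":
            self.st[K.SP] = value & 0xFFFF
        elif name == "halted":
            self.st[K.HALT] = 1 if value else 0
        else:
            raise AttributeError(name)

    # -- genome handling ----------------------------------------------------
    def load_genome(self, code: bytes | np.ndarray) -> None:
        """Install genome bytes at the genome base (host write, unprotected)."""
        code = np.frombuffer(bytes(code), dtype=np.uint8)
        mm = self.memmap
        if len(code) != mm.genome_len:
            raise ValueError(
                f"genome is {len(code)} bytes, memory map expects "
                f"{mm.genome_len}")
        self.mem[mm.genome_base:mm.genome_end] = code

    @property
    def genome(self) -> np.ndarray:
        mm = self.memmap
        return self.mem[mm.genome_base:mm.genome_end].copy()

    def clear_volatile(self) -> None:
        """Birth reset: clear scratch RAM and the actuator cells."""
        mm = self.memmap
        self.mem[mm.scratch_base:mm.scratch_base + mm.scratch_len] = 0
        self.mem[mm.out_dx] = 0
        self.mem[mm.out_dy] = 0

    def copy(self) -> "CpuState":
        other = CpuState(self.memmap)
        other.mem[:] = self.mem
        other.st[:] = self.st
        return other


def reset_slice(cpu: CpuState) -> CpuState:
    """Start a new thought slice: PC to genome base, registers/flags cleared.

    Scratch RAM and the actuator cells keep their contents — persistence
    across steps is the agent's only memory of the past.  Idempotent.
    """
    K.reset_slice_k(cpu.st, cpu.memmap.genome_base, cpu.memmap.sp_top)
    return cpu


def step_instruction(cpu: CpuState) -> CpuState:
    """Execute exactly one instruction at PC (caller ensures not halted)."""
    if cpu.halted:
        raise RuntimeError("CPU is halted; reset_slice before stepping")
    mm = cpu.memmap
    K.exec_instr(cpu.mem, cpu.st, mm.genome_base, mm.genome_end,
                 mm.sensor_agent_x, mm.sensor_prey_y)
    cpu.st[K.EXEC] += 1
    return cpu


def run_slice(cpu: CpuState, budget: int) -> CpuState:
    """Execute until HLT, the budget, or PC leaving the genome region."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    mm = cpu.memmap
    K.exec_slice(cpu.mem, cpu.st, budget, mm.genome_base, mm.genome_len,
                 mm.sensor_agent_x, mm.sensor_prey_y, True)
    return cpu


# ---------------------------------------------------------------- genome I/O
def parse_hex_genome(text: str) -> bytes:
    """Parse the hex-text genome dialect: byte pairs, whitespace, # comments."""
    out = bytearray()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0]
        for tok in line.split():
            if len(tok) != 2:
                raise ValueError(
                    f"line {lineno}: token {tok!r} is not a two-digit hex byte")
            try:
                out.append(int(tok, 16))
            except ValueError:
                raise ValueError(
                    f"line {lineno}: token {tok!r} is not a two-digit hex byte"
                ) from None
    return bytes(out)


def format_hex_genome(code: bytes | np.ndarray, per_line: int = 16) -> str:
    code = bytes(code)
    lines = []
    for i in range(0, len(code), per_line):
        lines.append(" ".join(f"{b:02X}" for b in code[i:i + per_line]))
    return "\n".join(lines) + "\n"


def load_genome(path: str | Path, genome_len: int | None = None) -> bytes:
    """Load a genome file: ``.hex`` text dialect, anything else raw binary."""
    path = Path(path)
    if path.suffix.lower() == ".hex":
        code = parse_hex_genome(path.read_text())
    else:
        code = path.read_bytes()
    if genome_len is not None and len(code) != genome_len:
        raise ValueError(
            f"{path}: genome is {len(code)} bytes, expected {genome_len}")
    return code


def save_genome(path: str | Path, code: bytes | np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() == ".hex":
        path.write_text(format_hex_genome(code))
    else:
        path.write_bytes(bytes(code))
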
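"""Independent table-driven i8080 reference implementation.

Written directly from the published 8080 opcode table as a dictionary of
per-opcode handlers over a boolean-flag state object.  It shares no code
with the package emulator and exists purely as the oracle for conformance
testing (flags included).  Optional read-only address ranges model the
sandbox semantics (writes to sensors/genome are dropped).
"""

from __future__ import annotations

M16 = 0xFFFF

PARITY_EVEN = [bin(i).count("1") % 2 == 0 for i in range(256)]

REG_NAMES = ["B", "C", "D", "E", "H", "L", None, "A"]  # code 6 is memory


class Ref8080:
    def __init__(self, mem: bytes | bytearray | None = None,
                 readonly: tuple[tuple[int, int], ...] = ()):
        self.mem = bytearray(mem) if mem is not None else bytearray(65536)
        self.readonly = readonly  # list of (lo, hi) inclusive ranges
        self.A = self.B = self.C = self.D = self.E = self.H = self.L = 0
        self.S = self.Z = self.AC = self.P = self.CY = False
        self.PC = 0
        self.SP = 0
        self.halted = False

    # -- memory helpers -----------------------------------------------------
    def rd(self, addr):
        return self.mem[addr & M16]

    def wr(self, addr, val):
        addr &= M16
        for lo, hi in self.readonly:
            if lo <= addr <= hi:
                return
        self.mem[addr] = val & 0xFF

    # -- register helpers ---------------------------------------------------
    def get_reg(self, code):
        if code == 6:
            return self.rd((self.H << 8) | self.L)
        return getattr(self, REG_NAMES[code])

    def set_reg(self, code, val):
        if code == 6:
            self.wr((self.H << 8) | self.L, val)
        else:
            setattr(self, REG_NAMES[code], val & 0xFF)

    def get_pair(self, name):
        if name == "B":
            return (self.B << 8) | self.C
        if name == "D":
            return (self.D << 8) | self.E
        if name == "H":
            return (self.H << 8) | self.L
        return self.SP

    def set_pair(self, name, val):
        val &= M16
        if name == "B":
            self.B, self.C = val >> 8, val & 0xFF
        elif name == "D":
            self.D, self.E = val >> 8, val & 0xFF
        elif name == "H":
            self.H, self.L = val >> 8, val & 0xFF
        else:
            self.SP = val

    @property
    def psw_byte(self):
        return ((0x80 if self.S else 0) | (0x40 if self.Z else 0)
                | (0x10 if self.AC else 0) | (0x04 if self.P else 0)
                | 0x02 | (0x01 if self.CY else 0))

    def set_psw_byte(self, v):
        self.S = bool(v & 0x80)
        self.Z = bool(v & 0x40)
        self.AC = bool(v & 0x10)
        self.P = bool(v & 0x04)
        self.CY = bool(v & 0x01)

    # -- flag/ALU helpers ---------------------------------------------------
    def szp(self, v):
        self.S = v >= 0x80
        self.Z = v == 0
        self.P = PARITY_EVEN[v]

    def alu_add(self, v, with_carry):
        c = 1 if (with_carry and self.CY) else 0
        a = self.A
        total = a + v + c
        self.CY = total > 0xFF
        self.AC = (a & 0xF) + (v & 0xF) + c > 0xF
        self.A = total & 0xFF
        self.szp(self.A)

    def alu_sub(self, v, with_borrow, store=True):
        c = 1 if (with_borrow and self.CY) else 0
        a = self.A
        r = (a - v - c) & 0xFF
        self.CY = a - v - c < 0
        self.AC = (a & 0xF) - (v & 0xF) - c >= 0
        self.szp(r)
        if store:
            self.A = r

    def alu_and(self, v):
        self.AC = bool((self.A | v) & 0x08)  # 8080: OR of bit 3
        self.CY = False
        self.A = self.A & v
        self.szp(self.A)

    def alu_xor(self, v):
        self.A = self.A ^ v
        self.CY = self.AC = False
        self.szp(self.A)

    def alu_or(self, v):
        self.A = self.A | v
        self.CY = self.AC = False
        self.szp(self.A)

    def push16(self, v):
        self.SP = (self.SP - 1) & M16
        self.wr(self.SP, (v >> 8) & 0xFF)
        self.SP = (self.SP - 1) & M16
        self.wr(self.SP, v & 0xFF)

    def pop16(self):
        lo = self.rd(self.SP)
        hi = self.rd(self.SP + 1)
        self.SP = (self.SP + 2) & M16
        return (hi << 8) | lo

    def condition(self, code):
        return [not self.Z, self.Z, not self.CY, self.CY,
                not self.P, self.P, not self.S, self.S][code]

    # -- execution ----------------------------------------------------------
    def step(self):
        """Execute one instruction at PC."""
        pc = self.PC & M16
        op = self.mem[pc]
        length, handler = TABLE[op]
        o1 = self.mem[(pc + 1) & M16]
        o2 = self.mem[(pc + 2) & M16]
        self.PC = (pc + length) & M16
        handler(self, o1, o2)


# --------------------------------------------------------------- build table
def _build():
    table = {}

    def put(code, length, handler):
        assert code not in table
        table[code] = (length, handler)

    def nop(_cpu, _a, _b):
        pass

    put(0x00, 1, nop)
    for hole in (0x08, 0x10, 0x18, 0x20, 0x28, 0x30, 0x38,
                 0xCB, 0xD9, 0xDD, 0xED, 0xFD):
        put(hole, 1, nop)          # undocumented: executed as no-ops
    put(0xD3, 2, nop)              # OUT
    put(0xDB, 2, nop)              # IN
    put(0xF3, 1, nop)              # DI
    put(0xFB, 1, nop)              # EI
    for n in range(8):
        put(0xC7 | n << 3, 1, nop)  # RST: no effect in the sandbox

    # data transfer -------------------------------------------------------
    for dst in range(8):
        for src in range(8):
            code = 0x40 | dst << 3 | src
            if code == 0x76:
                continue

            def mov(cpu, _a, _b, d=dst, s=src):
                cpu.set_reg(d, cpu.get_reg(s))
            put(code, 1, mov)

    def hlt(cpu, _a, _b):
        cpu.halted = True
    put(0x76, 1, hlt)

    for dst in range(8):
        def mvi(cpu, a, _b, d=dst):
            cpu.set_reg(d, a)
        put(0x06 | dst << 3, 2, mvi)

    for i, pair in enumerate(["B", "D", "H", "SP"]):
        def lxi(cpu, a, b, p=pair):
            cpu.set_pair(p, (b << 8) | a)
        put(0x01 | i << 4, 3, lxi)

        def inx(cpu, _a, _b, p=pair):
            cpu.set_pair(p, cpu.get_pair(p) + 1)
        put(0x03 | i << 4, 1, inx)

        def dcx(cpu, _a, _b, p=pair):
            cpu.set_pair(p, cpu.get_pair(p) - 1)
        put(0x0B | i << 4, 1, dcx)

        def dad(cpu, _a, _b, p=pair):
            total = cpu.get_pair("H") + cpu.get_pair(p)
            cpu.CY = total > M16
            cpu.set_pair("H", total)
        put(0x09 | i << 4, 1, dad)

    def stax_b(cpu, _a, _b):
        cpu.wr(cpu.get_pair("B"), cpu.A)

    def stax_d(cpu, _a, _b):
        cpu.wr(cpu.get_pair("D"), cpu.A)

    def ldax_b(cpu, _a, _b):
        cpu.A = cpu.rd(cpu.get_pair("B"))

    def ldax_d(cpu, _a, _b):
        cpu.A = cpu.rd(cpu.get_pair("D"))

    put(0x02, 1, stax_b)
    put(0x12, 1, stax_d)
    put(0x0A, 1, ldax_b)
    put(0x1A, 1, ldax_d)

    def sta(cpu, a, b):
        cpu.wr((b << 8) | a, cpu.A)

    def lda(cpu, a, b):
        cpu.A = cpu.rd((b << 8) | a)

    def shld(cpu, a, b):
        cpu.wr((b << 8) | a, cpu.L)
        cpu.wr(((b << 8) | a) + 1, cpu.H)

    def lhld(cpu, a, b):
        cpu.L = cpu.rd((b << 8) | a)
        cpu.H = cpu.rd(((b << 8) | a) + 1)

    put(0x32, 3, sta)
    put(0x3A, 3, lda)
    put(0x22, 3, shld)
    put(0x2A, 3, lhld)

    def xchg(cpu, _a, _b):
        cpu.H, cpu.D = cpu.D, cpu.H
        cpu.L, cpu.E = cpu.E, cpu.L
    put(0xEB, 1, xchg)

    # arithmetic / logic ----------------------------------------------------
    for reg in range(8):
        def inr(cpu, _a, _b, r=reg):
            v = cpu.get_reg(r)
            res = (v + 1) & 0xFF
            cpu.AC = (v & 0xF) + 1 > 0xF
            cpu.szp(res)
            cpu.set_reg(r, res)
        put(0x04 | reg << 3, 1, inr)

        def dcr(cpu, _a, _b, r=reg):
            v = cpu.get_reg(r)
            res = (v - 1) & 0xFF
            cpu.AC = (v & 0xF) >= 1
            cpu.szp(res)
            cpu.set_reg(r, res)
        put(0x05 | reg << 3, 1, dcr)

    alu_by_group = [
        lambda cpu, v: cpu.alu_add(v, False),
        lambda cpu, v: cpu.alu_add(v, True),
        lambda cpu, v: cpu.alu_sub(v, False),
        lambda cpu, v: cpu.alu_sub(v, True),
        lambda cpu, v: cpu.alu_and(v),
        lambda cpu, v: cpu.alu_xor(v),
        lambda cpu, v: cpu.alu_or(v),
        lambda cpu, v: cpu.alu_sub(v, False, store=False),  # CMP
    ]
    for grp, fn in enumerate(alu_by_group):
        for reg in range(8):
            def alu_r(cpu, _a, _b, f=fn, r=reg):
                f(cpu, cpu.get_reg(r))
            put(0x80 | grp << 3 | reg, 1, alu_r)
    for code, fn in zip([0xC6, 0xCE, 0xD6, 0xDE, 0xE6, 0xEE, 0xF6, 0xFE],
                        alu_by_group):
        def alu_i(cpu, a, _b, f=fn):
            f(cpu, a)
        put(code, 2, alu_i)

    def rlc(cpu, _a, _b):
        bit7 = cpu.A >> 7
        cpu.A = ((cpu.A << 1) | bit7) & 0xFF
        cpu.CY = bool(bit7)

    def rrc(cpu, _a, _b):
        bit0 = cpu.A & 1
        cpu.A = (cpu.A >> 1) | (bit0 << 7)
        cpu.CY = bool(bit0)

    def ral(cpu, _a, _b):
        bit7 = cpu.A >> 7
        cpu.A = ((cpu.A << 1) | (1 if cpu.CY else 0)) & 0xFF
        cpu.CY = bool(bit7)

    def rar(cpu, _a, _b):
        bit0 = cpu.A & 1
        cpu.A = (cpu.A >> 1) | ((1 if cpu.CY else 0) << 7)
        cpu.CY = bool(bit0)

    put(0x07, 1, rlc)
    put(0x0F, 1, rrc)
    put(0x17, 1, ral)
    put(0x1F, 1, rar)

    def daa(cpu, _a, _b):
        lo = cpu.A & 0xF
        hi = cpu.A >> 4
        correction = 0
        if cpu.AC or lo > 9:
            correction = 0x06
        carry = cpu.CY
        if cpu.CY or hi > 9 or (hi == 9 and lo > 9):
            correction += 0x60
            carry = True
        cpu.AC = lo + (correction & 0xF) > 0xF
        cpu.CY = carry
        cpu.A = (cpu.A + correction) & 0xFF
        cpu.szp(cpu.A)
    put(0x27, 1, daa)

    def cma(cpu, _a, _b):
        cpu.A ^= 0xFF

    def stc(cpu, _a, _b):
        cpu.CY = True

    def cmc(cpu, _a, _b):
        cpu.CY = not cpu.CY

    put(0x2F, 1, cma)
    put(0x37, 1, stc)
    put(0x3F, 1, cmc)

    # branching -------------------------------------------------------------
    def jmp(cpu, a, b):
        cpu.PC = (b << 8) | a
    put(0xC3, 3, jmp)

    def call(cpu, a, b):
        cpu.push16(cpu.PC)          # PC already past the instruction
        cpu.PC = (b << 8) | a
    put(0xCD, 3, call)

    def ret(cpu, _a, _b):
        cpu.PC = cpu.pop16()
    put(0xC9, 1, ret)

    for cc in range(8):
        def jcc(cpu, a, b, c=cc):
            if cpu.condition(c):
                cpu.PC = (b << 8) | a
        put(0xC2 | cc << 3, 3, jcc)

        def ccc(cpu, a, b, c=cc):
            if cpu.condition(c):
                cpu.push16(cpu.PC)
                cpu.PC = (b << 8) | a
        put(0xC4 | cc << 3, 3, ccc)

        def rcc(cpu, _a, _b, c=cc):
            if cpu.condition(c):
                cpu.PC = cpu.pop16()
        put(0xC0 | cc << 3, 1, rcc)

    def pchl(cpu, _a, _b):
        cpu.PC = cpu.get_pair("H")
    put(0xE9, 1, pchl)

    # stack -----------------------------------------------------------------
    for i, pair in enumerate(["B", "D", "H"]):
        def push_rp(cpu, _a, _b, p=pair):
            cpu.push16(cpu.get_pair(p))
        put(0xC5 | i << 4, 1, push_rp)

        def pop_rp(cpu, _a, _b, p=pair):
            cpu.set_pair(p, cpu.pop16())
        put(0xC1 | i << 4, 1, pop_rp)

    def push_psw(cpu, _a, _b):
        cpu.push16((cpu.A << 8) | cpu.psw_byte)

    def pop_psw(cpu, _a, _b):
        v = cpu.pop16()
        cpu.A = v >> 8
        cpu.set_psw_byte(v & 0xFF)

    put(0xF5, 1, push_psw)
    put(0xF1, 1, pop_psw)

    def xthl(cpu, _a, _b):
        lo = cpu.rd(cpu.SP)
        hi = cpu.rd(cpu.SP + 1)
        cpu.wr(cpu.SP, cpu.L)
        cpu.wr(cpu.SP + 1, cpu.H)
        cpu.L, cpu.H = lo, hi

    def sphl(cpu, _a, _b):
        cpu.SP = cpu.get_pair("H")

    put(0xE3, 1, xthl)
    put(0xF9, 1, sphl)

    assert len(table) == 256
    return table


TABLE = _build()
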
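"""Numba-compiled hot loops: the i8080 core, agent slices and hunt epochs.

Everything here operates on plain numpy arrays so that the whole
instruction-level simulation stays inside compiled code.  CPU state is a
single int64 vector (layout given by the ``A`` .. ``EXEC`` indices below);
memory is a 64 KiB uint8 image per agent.

Flags are kept packed in an 8080-style F byte (S Z 0 AC 0 P 1 CY).  Writes
from executing code to the genome region and the sensor cells are silently
dropped, which is what sandboxes the agent: a genome can never corrupt its
own heritable code or fake its sensory input.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- state layout
A, B, C, D, E, H, L, F, PC, SP, HALT, EXEC = range(12)
STATE_LEN = 12

# F-register bits (8080 layout; bit 1 is always set, bits 3 and 5 clear)
FS = 0x80
FZ = 0x40
FAC = 0x10
FP = 0x04
FCY = 0x01
FBASE = 0x02

_PARITY = np.zeros(256, dtype=np.uint8)
for _i in range(256):
    _PARITY[_i] = 1 if bin(_i).count("1") % 2 == 0 else 0

# map 8080 register codes B C D E H L M A -> state indices (M handled apart)
_RMAP = np.array([B, C, D, E, H, L, 0, A], dtype=np.int64)

_U_GOLD = np.uint64(0x9E3779B97F4A7C15)
_U_M1 = np.uint64(0xBF58476D1CE4E5B9)
_U_M2 = np.uint64(0x94D049BB133111EB)

_JIT = dict(cache=False, fastmath=False, nogil=True)


# ------------------------------------------------------------------ rng kernel
@njit(**_JIT)
def _sm_next(s):
    s[0] = s[0] + _U_GOLD
    z = s[0]
    z = (z ^ (z >> np.uint64(30))) * _U_M1
    z = (z ^ (z >> np.uint64(27))) * _U_M2
    return z ^ (z >> np.uint64(31))


@njit(**_JIT)
def _rand_below(s, n):
    return np.int64(_sm_next(s) % np.uint64(n))


# ------------------------------------------------------------------- cpu core
@njit(**_JIT)
def _szp(f, r):
    f = f & 0x13  # keep CY and AC, drop S/Z/P
    f |= FBASE
    if r & 0x80:
        f |= FS
    if r == 0:
        f |= FZ
    if _PARITY[r]:
        f |= FP
    return f


@njit(**_JIT)
def _wr(mem, addr, val, gb, ge, sl, sh):
    addr = addr & 0xFFFF
    if gb <= addr < ge:
        return
    if sl <= addr <= sh:
        return
    mem[addr] = val & 0xFF


@njit(**_JIT)
def _get_r(mem, st, r):
    if r == 6:
        return np.int64(mem[((st[H] << 8) | st[L]) & 0xFFFF])
    return st[_RMAP[r]]


@njit(**_JIT)
def _set_r(mem, st, r, v, gb, ge, sl, sh):
    if r == 6:
        _wr(mem, (st[H] << 8) | st[L], v, gb, ge, sl, sh)
    else:
        st[_RMAP[r]] = v & 0xFF


@njit(**_JIT)
def _get_rp(st, rp):
    if rp == 0:
        return (st[B] << 8) | st[C]
    if rp == 1:
        return (st[D] << 8) | st[E]
    if rp == 2:
        return (st[H] << 8) | st[L]
    return st[SP]


@njit(**_JIT)
def _set_rp(st, rp, v):
    v = v & 0xFFFF
    if rp == 0:
        st[B] = v >> 8
        st[C] = v & 0xFF
    elif rp == 1:
        st[D] = v >> 8
        st[E] = v & 0xFF
    elif rp == 2:
        st[H] = v >> 8
        st[L] = v & 0xFF
    else:
        st[SP] = v


@njit(**_JIT)
def _push16(mem, st, v, gb, ge, sl, sh):
    sp = (st[SP] - 1) & 0xFFFF
    _wr(mem, sp, (v >> 8) & 0xFF, gb, ge, sl, sh)
    sp = (sp - 1) & 0xFFFF
    _wr(mem, sp, v & 0xFF, gb, ge, sl, sh)
    st[SP] = sp


@njit(**_JIT)
def _pop16(mem, st):
    sp = st[SP]
    lo = mem[sp & 0xFFFF]
    hi = mem[(sp + 1) & 0xFFFF]
    st[SP] = (sp + 2) & 0xFFFF
    return (np.int64(hi) << 8) | np.int64(lo)


@njit(**_JIT)
def _add_to_a(st, b, cy):
    a = st[A]
    r = a + b + cy
    f = FBASE
    if r > 0xFF:
        f |= FCY
    if (a & 0xF) + (b & 0xF) + cy > 0xF:
        f |= FAC
    r = r & 0xFF
    st[A] = r
    st[F] = _szp(f, r)


@njit(**_JIT)
def _sub_from_a(st, b, cy, store):
    a = st[A]
    r = a - b - cy
    f = FBASE
    if r < 0:
        f |= FCY
        r += 256
    if (a & 0xF) - (b & 0xF) - cy >= 0:
        f |= FAC
    r = r & 0xFF
    if store:
        st[A] = r
    st[F] = _szp(f, r)


@njit(**_JIT)
def _cond(st, cc):
    f = st[F]
    if cc == 0:
        return (f & FZ) == 0
    if cc == 1:
        return (f & FZ) != 0
    if cc == 2:
        return (f & FCY) == 0
    if cc == 3:
        return (f & FCY) != 0
    if cc == 4:
        return (f & FP) == 0
    if cc == 5:
        return (f & FP) != 0
    if cc == 6:
        return (f & FS) == 0
    return (f & FS) != 0


@njit(**_JIT)
def exec_instr(mem, st, gb, ge, sl, sh):
    """Decode and execute exactly one instruction at PC.

    Undocumented opcodes, IN/OUT, EI/DI and RST have no architectural effect
    here (they only advance PC), so any random byte string is executable.
    """
    pc = st[PC] & 0xFFFF
    op = np.int64(mem[pc])
    npc = pc + 1

    if op < 0x40:
        col = op & 7
        if col == 0:
            pass  # NOP and the 0x08/0x10/... holes
        elif col == 1:
            if op & 0x08:  # DAD rp
                hl = (st[H] << 8) | st[L]
                s = hl + _get_rp(st, (op >> 4) & 3)
                if s > 0xFFFF:
                    st[F] = st[F] | FCY
                else:
                    st[F] = st[F] & ~FCY & 0xFF
                st[H] = (s >> 8) & 0xFF
                st[L] = s & 0xFF
            else:  # LXI rp, d16
                lo = np.int64(mem[(pc + 1) & 0xFFFF])
                hi = np.int64(mem[(pc + 2) & 0xFFFF])
                _set_rp(st, (op >> 4) & 3, (hi << 8) | lo)
                npc = pc + 3
        elif col == 2:
            if op == 0x02:  # STAX B
                _wr(mem, (st[B] << 8) | st[C], st[A], gb, ge, sl, sh)
            elif op == 0x12:  # STAX D
                _wr(mem, (st[D] << 8) | st[E], st[A], gb, ge, sl, sh)
            elif op == 0x0A:  # LDAX B
                st[A] = np.int64(mem[((st[B] << 8) | st[C]) & 0xFFFF])
            elif op == 0x1A:  # LDAX D
                st[A] = np.int64(mem[((st[D] << 8) | st[E]) & 0xFFFF])
            else:
                lo = np.int64(mem[(pc + 1) & 0xFFFF])
                hi = np.int64(mem[(pc + 2) & 0xFFFF])
                addr = (hi << 8) | lo
                npc = pc + 3
                if op == 0x22:  # SHLD
                    _wr(mem, addr, st[L], gb, ge, sl, sh)
                    _wr(mem, addr + 1, st[H], gb, ge, sl, sh)
                elif op == 0x2A:  # LHLD
                    st[L] = np.int64(mem[addr & 0xFFFF])
                    st[H] = np.int64(mem[(addr + 1) & 0xFFFF])
                elif op == 0x32:  # STA
                    _wr(mem, addr, st[A], gb, ge, sl, sh)
                else:  # 0x3A LDA
                    st[A] = np.int64(mem[addr & 0xFFFF])
        elif col == 3:  # INX / DCX
            rp = (op >> 4) & 3
            if op & 0x08:
                _set_rp(st, rp, _get_rp(st, rp) - 1)
            else:
                _set_rp(st, rp, _get_rp(st, rp) + 1)
        elif col == 4:  # INR r
            r = (op >> 3) & 7
            v = _get_r(mem, st, r)
            res = (v + 1) & 0xFF
            f = (st[F] & FCY) | FBASE
            if (v & 0xF) + 1 > 0xF:
                f |= FAC
            st[F] = _szp(f, res)
            _set_r(mem, st, r, res, gb, ge, sl, sh)
        elif col == 5:  # DCR r
            r = (op >> 3) & 7
            v = _get_r(mem, st, r)
            res = (v - 1) & 0xFF
            f = (st[F] & FCY) | FBASE
            if (v & 0xF) > 0:
                f |= FAC
            st[F] = _szp(f, res)
            _set_r(mem, st, r, res, gb, ge, sl, sh)
        elif col == 6:  # MVI r, d8
            _set_r(mem, st, (op >> 3) & 7, np.int64(mem[(pc + 1) & 0xFFFF]),
                   gb, ge, sl, sh)
            npc = pc + 2
        else:
            if op == 0x07:  # RLC
                a = st[A]
                cy = (a >> 7) & 1
                st[A] = ((a << 1) | cy) & 0xFF
                st[F] = (st[F] & ~FCY & 0xFF) | cy
            elif op == 0x0F:  # RRC
                a = st[A]
                cy = a & 1
                st[A] = (a >> 1) | (cy << 7)
                st[F] = (st[F] & ~FCY & 0xFF) | cy
            elif op == 0x17:  # RAL
                a = st[A]
                old = st[F] & FCY
                st[A] = ((a << 1) | old) & 0xFF
                st[F] = (st[F] & ~FCY & 0xFF) | ((a >> 7) & 1)
            elif op == 0x1F:  # RAR
                a = st[A]
                old = st[F] & FCY
                st[A] = (a >> 1) | (old << 7)
                st[F] = (st[F] & ~FCY & 0xFF) | (a & 1)
            elif op == 0x27:  # DAA
                a = st[A]
                lo = a & 0xF
                hi = a >> 4
                ac = (st[F] & FAC) != 0
                cy = (st[F] & FCY) != 0
                corr = 0
                if ac or lo > 9:
                    corr = 6
                setcy = cy
                if cy or hi > 9 or (hi == 9 and lo > 9):
                    corr += 0x60
                    setcy = True
                res = (a + corr) & 0xFF
                f = FBASE
                if setcy:
                    f |= FCY
                if (lo + (corr & 0xF)) > 0xF:
                    f |= FAC
                st[A] = res
                st[F] = _szp(f, res)
            elif op == 0x2F:  # CMA
                st[A] = st[A] ^ 0xFF
            elif op == 0x37:  # STC
                st[F] = st[F] | FCY
            else:  # 0x3F CMC
                st[F] = st[F] ^ FCY
    elif op < 0x80:
        if op == 0x76:  # HLT
            st[HALT] = 1
        else:  # MOV d, s
            v = _get_r(mem, st, op & 7)
            _set_r(mem, st, (op >> 3) & 7, v, gb, ge, sl, sh)
    elif op < 0xC0:  # register/memory ALU group
        b = _get_r(mem, st, op & 7)
        g = (op >> 3) & 7
        cy = st[F] & FCY
        if g == 0:
            _add_to_a(st, b, 0)
        elif g == 1:
            _add_to_a(st, b, cy)
        elif g == 2:
            _sub_from_a(st, b, 0, True)
        elif g == 3:
            _sub_from_a(st, b, cy, True)
        elif g == 4:  # ANA: 8080 sets AC from OR of bit 3
            a = st[A]
            r = a & b
            f = FBASE
            if (a | b) & 0x08:
                f |= FAC
            st[A] = r
            st[F] = _szp(f, r)
        elif g == 5:  # XRA
            r = st[A] ^ b
            st[A] = r
            st[F] = _szp(FBASE, r)
        elif g == 6:  # ORA
            r = st[A] | b
            st[A] = r
            st[F] = _szp(FBASE, r)
        else:  # CMP
            _sub_from_a(st, b, 0, False)
    else:
        col = op & 7
        row = (op >> 3) & 7
        if col == 0:  # Rcc
            if _cond(st, row):
                npc = _pop16(mem, st)
        elif col == 1:
            if row & 1:
                if op == 0xC9:  # RET
                    npc = _pop16(mem, st)
                elif op == 0xE9:  # PCHL
                    npc = (st[H] << 8) | st[L]
                elif op == 0xF9:  # SPHL
                    st[SP] = (st[H] << 8) | st[L]
                # 0xD9: undocumented, no effect
            else:  # POP rp
                v = _pop16(mem, st)
                rp = row >> 1
                if rp == 3:  # PSW
                    st[A] = (v >> 8) & 0xFF
                    st[F] = (v & (FS | FZ | FAC | FP | FCY)) | FBASE
                else:
                    _set_rp(st, rp, v)
        elif col == 2:  # Jcc a16
            npc = pc + 3
            if _cond(st, row):
                lo = np.int64(mem[(pc + 1) & 0xFFFF])
                hi = np.int64(mem[(pc + 2) & 0xFFFF])
                npc = (hi << 8) | lo
        elif col == 3:
            if op == 0xC3:  # JMP
                lo = np.int64(mem[(pc + 1) & 0xFFFF])
                hi = np.int64(mem[(pc + 2) & 0xFFFF])
                npc = (hi << 8) | lo
            elif op == 0xD3 or op == 0xDB:  # OUT / IN: two bytes, no effect
                npc = pc + 2
            elif op == 0xE3:  # XTHL
                sp = st[SP]
                lo = np.int64(mem[sp & 0xFFFF])
                hi = np.int64(mem[(sp + 1) & 0xFFFF])
                _wr(mem, sp, st[L], gb, ge, sl, sh)
                _wr(mem, sp + 1, st[H], gb, ge, sl, sh)
                st[L] = lo
                st[H] = hi
            elif op == 0xEB:  # XCHG
                th = st[H]
                tl = st[L]
                st[H] = st[D]
                st[L] = st[E]
                st[D] = th
                st[E] = tl
            # 0xCB hole, 0xF3 DI, 0xFB EI: no effect
        elif col == 4:  # Ccc a16
            npc = pc + 3
            if _cond(st, row):
                _push16(mem, st, pc + 3, gb, ge, sl, sh)
                lo = np.int64(mem[(pc + 1) & 0xFFFF])
                hi = np.int64(mem[(pc + 2) & 0xFFFF])
                npc = (hi << 8) | lo
        elif col == 5:
            if row & 1:
                if op == 0xCD:  # CALL
                    _push16(mem, st, pc + 3, gb, ge, sl, sh)
                    lo = np.int64(mem[(pc + 1) & 0xFFFF])
                    hi = np.int64(mem[(pc + 2) & 0xFFFF])
                    npc = (hi << 8) | lo
                # 0xDD/0xED/0xFD holes: no effect
            else:  # PUSH rp
                rp = row >> 1
                if rp == 3:
                    v = (st[A] << 8) | ((st[F] & (FS | FZ | FAC | FP | FCY)) | FBASE)
                else:
                    v = _get_rp(st, rp)
                _push16(mem, st, v, gb, ge, sl, sh)
        elif col == 6:  # immediate ALU
            b = np.int64(mem[(pc + 1) & 0xFFFF])
            npc = pc + 2
            cy = st[F] & FCY
            if row == 0:
                _add_to_a(st, b, 0)
            elif row == 1:
                _add_to_a(st, b, cy)
            elif row == 2:
                _sub_from_a(st, b, 0, True)
            elif row == 3:
                _sub_from_a(st, b, cy, True)
            elif row == 4:
                a = st[A]
                r = a & b
                f = FBASE
                if (a | b) & 0x08:
                    f |= FAC
                st[A] = r
                st[F] = _szp(f, r)
            elif row == 5:
                r = st[A] ^ b
                st[A] = r
                st[F] = _szp(FBASE, r)
            elif row == 6:
                r = st[A] | b
                st[A] = r
                st[F] = _szp(FBASE, r)
            else:
                _sub_from_a(st, b, 0, False)
        # col == 7: RST n, treated as having no effect

    st[PC] = npc & 0xFFFF


@njit(**_JIT)
def exec_slice(mem, st, budget, gb, gl, sl, sh, require_in_genome):
    """Run instructions until HLT, the budget, or PC leaving the genome."""
    ge = gb + gl
    while st[EXEC] < budget:
        if st[HALT] != 0:
            break
        pc = st[PC]
        if require_in_genome and not (gb <= pc < ge):
            break
        exec_instr(mem, st, gb, ge, sl, sh)
        st[EXEC] += 1
    return st[EXEC]


@njit(**_JIT)
def reset_slice_k(st, gb, sp_top):
    st[A] = 0
    st[B] = 0
    st[C] = 0
    st[D] = 0
    st[E] = 0
    st[H] = 0
    st[L] = 0
    st[F] = FBASE
    st[PC] = gb
    st[SP] = sp_top
    st[HALT] = 0
    st[EXEC] = 0


# ----------------------------------------------------------------- hunt loops
@njit(**_JIT)
def _torus_cheb(ax, ay, px, py, w, h):
    dx = ax - px
    if dx < 0:
        dx = -dx
    if w - dx < dx:
        dx = w - dx
    dy = ay - py
    if dy < 0:
        dy = -dy
    if h - dy < dy:
        dy = h - dy
    return dx if dx > dy else dy


@njit(**_JIT)
def _circle_pos(ccx, ccy, radius, k, step_deg, direction, w, h):
    # direction +1 = ccw, -1 = cw; integer cell positions via round-half-up
    theta = direction * k * step_deg * math.pi / 180.0
    px = int(math.floor(ccx + radius * math.cos(theta) + 0.5)) % w
    py = int(math.floor(ccy + radius * math.sin(theta) + 0.5)) % h
    return px, py


@njit(**_JIT)
def hunt_steps(mem, st, rs, T, w, h, l, Lcap, cr, motion, circ_r, circ_step_deg,
               budget, gb, gl, s0, odx, ody, sp_top,
               init_ax, init_ay, record, traj):
    """Run T hunt steps for one agent; returns the number of catches.

    ``motion``: 0 random walk, 1 circular clockwise, 2 circular
    counter-clockwise.  When ``init_ax`` < 0 all starting positions are drawn
    from the agent's stream ``rs``.  The per-step pipeline is: write sensors,
    reset slice, execute, read actuators, move agent, check catch/respawn,
    move prey.
    """
    sl = s0
    sh = s0 + 3
    direction = -1 if motion == 1 else 1
    ccx = 0
    ccy = 0
    k = 0
    if init_ax >= 0:
        ax = init_ax
        ay = init_ay
    else:
        ax = _rand_below(rs, w)
        ay = _rand_below(rs, h)
    # spawn prey on a cell distinct from the agent
    if motion == 0:
        while True:
            px = _rand_below(rs, w)
            py = _rand_below(rs, h)
            if px != ax or py != ay:
                break
    else:
        while True:
            ccx = _rand_below(rs, w)
            ccy = _rand_below(rs, h)
            k = 0
            px, py = _circle_pos(ccx, ccy, circ_r, k, circ_step_deg,
                                 direction, w, h)
            if px != ax or py != ay:
                break
    catches = 0
    for step in range(T):
        mem[s0] = ax
        mem[s0 + 1] = ay
        mem[s0 + 2] = px
        mem[s0 + 3] = py
        reset_slice_k(st, gb, sp_top)
        exec_slice(mem, st, budget, gb, gl, sl, sh, True)
        dx = np.int64(mem[odx])
        if dx >= 128:
            dx -= 256
        dy = np.int64(mem[ody])
        if dy >= 128:
            dy -= 256
        if dx > Lcap:
            dx = Lcap
        elif dx < -Lcap:
            dx = -Lcap
        if dy > Lcap:
            dy = Lcap
        elif dy < -Lcap:
            dy = -Lcap
        ax = (ax + dx) % w
        ay = (ay + dy) % h
        caught = 0
        if _torus_cheb(ax, ay, px, py, w, h) <= cr:
            caught = 1
            catches += 1
            if motion == 0:
                while True:
                    px = _rand_below(rs, w)
                    py = _rand_below(rs, h)
                    if px != ax or py != ay:
                        break
            else:
                while True:
                    ccx = _rand_below(rs, w)
                    ccy = _rand_below(rs, h)
                    k = 0
                    px, py = _circle_pos(ccx, ccy, circ_r, k, circ_step_deg,
                                         direction, w, h)
                    if px != ax or py != ay:
                        break
        if motion == 0:
            if l > 0:
                px = (px + _rand_below(rs, 2 * l + 1) - l) % w
                py = (py + _rand_below(rs, 2 * l + 1) - l) % h
        else:
            k += 1
            px, py = _circle_pos(ccx, ccy, circ_r, k, circ_step_deg,
                                 direction, w, h)
        if record:
            traj[step, 0] = step
            traj[step, 1] = ax
            traj[step, 2] = ay
            traj[step, 3] = px
            traj[step, 4] = py
            traj[step, 5] = caught
    return catches


@njit(**_JIT)
def run_epoch_all(mems, sts, seeds, catches, T, w, h, l, Lcap, cr,
                  motion, circ_r, circ_step_deg, budget,
                  gb, gl, s0, odx, ody, sp_top):
    """One epoch for the whole ensemble, each agent on its own world."""
    dummy = np.zeros((1, 6), dtype=np.int64)
    rs = np.zeros(1, dtype=np.uint64)
    for i in range(mems.shape[0]):
        rs[0] = seeds[i]
        catches[i] = hunt_steps(mems[i], sts[i], rs, T, w, h, l, Lcap, cr,
                                motion, circ_r, circ_step_deg, budget,
                                gb, gl, s0, odx, ody, sp_top,
                                -1, -1, False, dummy)
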
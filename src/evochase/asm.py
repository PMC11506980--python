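"""A small i8080 assembler/disassembler and the hand-written chaser genome.

Supports the documented instruction set, labels, decimal/hex literals
(``0x2A``, ``2Ah``, ``42``) and a ``DB`` directive for raw bytes.  The
disassembler emits ``DB`` for undocumented opcodes and for trailing operand
bytes cut off by the end of the genome, so ``assemble(disassemble(code))``
reproduces any byte string exactly.
"""

from __future__ import annotations

import re

import numpy as np

from .cpu8080 import MemoryMap

__all__ = ["assemble", "disassemble", "AsmError", "chaser_source",
           "chaser_genome", "OPCODES"]

_R = ["B", "C", "D", "E", "H", "L", "M", "A"]
_RP = ["B", "D", "H", "SP"]
_RPP = ["B", "D", "H", "PSW"]
_CC = ["NZ", "Z", "NC", "C", "PO", "PE", "P", "M"]


def _build_opcode_table():
    """256 entries of (mnemonic-with-operand-template, length) or None."""
    t: list[tuple[str, int] | None] = [None] * 256
    t[0x00] = ("NOP", 1)
    for i, rp in enumerate(_RP):
        t[0x01 | i << 4] = (f"LXI {rp},d16", 3)
        t[0x03 | i << 4] = (f"INX {rp}", 1)
        t[0x09 | i << 4] = (f"DAD {rp}", 1)
        t[0x0B | i << 4] = (f"DCX {rp}", 1)
    t[0x02] = ("STAX B", 1)
    t[0x12] = ("STAX D", 1)
    t[0x0A] = ("LDAX B", 1)
    t[0x1A] = ("LDAX D", 1)
    t[0x22] = ("SHLD a16", 3)
    t[0x2A] = ("LHLD a16", 3)
    t[0x32] = ("STA a16", 3)
    t[0x3A] = ("LDA a16", 3)
    for r, name in enumerate(_R):
        t[0x04 | r << 3] = (f"INR {name}", 1)
        t[0x05 | r << 3] = (f"DCR {name}", 1)
        t[0x06 | r << 3] = (f"MVI {name},d8", 2)
    for op, name in [(0x07, "RLC"), (0x0F, "RRC"), (0x17, "RAL"),
                     (0x1F, "RAR"), (0x27, "DAA"), (0x2F, "CMA"),
                     (0x37, "STC"), (0x3F, "CMC")]:
        t[op] = (name, 1)
    for d in range(8):
        for s in range(8):
            op = 0x40 | d << 3 | s
            if op == 0x76:
                t[op] = ("HLT", 1)
            else:
                t[op] = (f"MOV {_R[d]},{_R[s]}", 1)
    for g, name in enumerate(["ADD", "ADC", "SUB", "SBB",
                              "ANA", "XRA", "ORA", "CMP"]):
        for s in range(8):
            t[0x80 | g << 3 | s] = (f"{name} {_R[s]}", 1)
    for cc, name in enumerate(_CC):
        t[0xC0 | cc << 3] = (f"R{name}", 1)
        t[0xC2 | cc << 3] = (f"J{name} a16", 3)
        t[0xC4 | cc << 3] = (f"C{name} a16", 3)
        t[0xC7 | cc << 3] = (f"RST {cc}", 1)
    for i, rp in enumerate(_RPP):
        t[0xC1 | i << 4] = (f"POP {rp}", 1)
        t[0xC5 | i << 4] = (f"PUSH {rp}", 1)
    t[0xC3] = ("JMP a16", 3)
    t[0xC9] = ("RET", 1)
    t[0xCD] = ("CALL a16", 3)
    for op, name in [(0xC6, "ADI"), (0xCE, "ACI"), (0xD6, "SUI"),
                     (0xDE, "SBI"), (0xE6, "ANI"), (0xEE, "XRI"),
                     (0xF6, "ORI"), (0xFE, "CPI")]:
        t[op] = (f"{name} d8", 2)
    t[0xD3] = ("OUT d8", 2)
    t[0xDB] = ("IN d8", 2)
    t[0xE3] = ("XTHL", 1)
    t[0xE9] = ("PCHL", 1)
    t[0xEB] = ("XCHG", 1)
    t[0xF3] = ("DI", 1)
    t[0xF9] = ("SPHL", 1)
    t[0xFB] = ("EI", 1)
    return t


OPCODES = _build_opcode_table()

# reverse map: ("MVI", "A", "d8") -> (opcode, length)
_ASM_MAP: dict[tuple, tuple[int, int]] = {}
for _op, _e in enumerate(OPCODES):
    if _e is None:
        continue
    _mn, _ln = _e
    _parts = _mn.split(None, 1)
    _key = (_parts[0],) + (tuple(p.strip() for p in _parts[1].split(","))
                           if len(_parts) > 1 else ())
    _ASM_MAP[_key] = (_op, _ln)


class AsmError(ValueError):
    """Assembly failure; message carries the source line number."""


_NUM = re.compile(r"^(?:0X[0-9A-F]+|[0-9A-F]+H|\d+)$")


def _parse_num(tok: str, lineno: int) -> int:
    u = tok.upper()
    try:
        if u.startswith("0X"):
            return int(u[2:], 16)
        if u.endswith("H"):
            return int(u[:-1], 16)
        return int(u, 10)
    except ValueError:
        raise AsmError(f"line {lineno}: bad numeric literal {tok!r}") from None


def _tokenize(text: str):
    """Yield (lineno, label, mnemonic, operands) for non-empty lines."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = re.split(r"[;#]", raw, 1)[0].strip()
        if not line:
            continue
        label = None
        m = re.match(r"^(\w+):\s*(.*)$", line)
        if m:
            label, line = m.group(1), m.group(2).strip()
        if not line:
            yield lineno, label, None, []
            continue
        parts = line.split(None, 1)
        mnem = parts[0].upper()
        ops = ([p.strip() for p in parts[1].split(",")]
               if len(parts) > 1 else [])
        yield lineno, label, mnem, ops


def assemble(text: str, origin: int | None = None,
             memmap: MemoryMap | None = None,
             pad_to: int | None = None) -> bytes:
    """Assemble source text into genome bytes.

    ``origin`` is the address of the first byte (defaults to the memory
    map's genome base) and is what labels resolve against.  ``pad_to`` pads
    the result with zero bytes up to a fixed genome length.
    """
    if origin is None:
        origin = (memmap or MemoryMap()).genome_base
    lines = list(_tokenize(text))
    # pass 1: label addresses
    labels: dict[str, int] = {}
    addr = origin
    for lineno, label, mnem, ops in lines:
        if label is not None:
            if label in labels:
                raise AsmError(f"line {lineno}: duplicate label {label!r}")
            labels[label] = addr
        if mnem is None:
            continue
        addr += _instr_length(lineno, mnem, ops)
    # pass 2: emit
    out = bytearray()
    for lineno, _label, mnem, ops in lines:
        if mnem is None:
            continue
        out += _emit(lineno, mnem, ops, labels)
    code = bytes(out)
    if pad_to is not None:
        if len(code) > pad_to:
            raise AsmError(f"program is {len(code)} bytes, exceeds pad_to="
                           f"{pad_to}")
        code = code + bytes(pad_to - len(code))
    return code


def _instr_length(lineno, mnem, ops) -> int:
    if mnem == "DB":
        return len(ops)
    key, _vals = _match(lineno, mnem, ops)
    return _ASM_MAP[key][1]


def _match(lineno, mnem, ops):
    """Resolve mnemonic+operands to a table key plus immediate value tokens."""
    key = [mnem]
    vals = []
    for op in ops:
        u = op.upper()
        if u in _R or u in ("SP", "PSW"):
            trial = tuple(key + [u])
            # register operand only if some entry expects it in this slot
            if any(k[:len(trial)] == trial for k in _ASM_MAP):
                key.append(u)
                continue
        key.append(None)  # placeholder for d8/a16/rst number
        vals.append(op)
    # fill placeholders with the template tokens that fit
    for tpl in _ASM_MAP:
        if len(tpl) != len(key) or tpl[0] != mnem:
            continue
        if all(k is None or k == t for k, t in zip(key, tpl)):
            return tpl, vals
    raise AsmError(f"line {lineno}: unknown instruction "
                   f"{mnem} {', '.join(ops)}".strip())


def _emit(lineno, mnem, ops, labels) -> bytes:
    if mnem == "DB":
        return bytes(_parse_num(op, lineno) & 0xFF for op in ops)
    key, vals = _match(lineno, mnem, ops)
    opcode, length = _ASM_MAP[key]
    out = bytearray([opcode])
    imm = [t for t in key if t in ("d8", "d16", "a16")]
    if mnem == "RST":
        # operand folded into the opcode; nothing to emit
        n = _parse_num(vals[0], lineno)
        if not 0 <= n <= 7:
            raise AsmError(f"line {lineno}: RST operand must be 0..7")
        out[0] = 0xC7 | n << 3
        return bytes(out)
    for tok, val in zip(imm, vals):
        if val in labels:
            v = labels[val]
        elif _NUM.match(val.upper()):
            v = _parse_num(val, lineno)
        else:
            raise AsmError(f"line {lineno}: undefined label or bad literal "
                           f"{val!r}")
        if tok == "d8":
            out.append(v & 0xFF)
        else:
            out.append(v & 0xFF)
            out.append((v >> 8) & 0xFF)
    if len(out) != length:
        raise AsmError(f"line {lineno}: wrong operand count for {mnem}")
    return bytes(out)


def disassemble(code: bytes | np.ndarray, origin: int | None = None,
                memmap: MemoryMap | None = None) -> str:
    """Disassemble genome bytes to canonical source (round-trips exactly)."""
    code = bytes(code)
    if origin is None:
        origin = (memmap or MemoryMap()).genome_base
    lines = []
    i = 0
    while i < len(code):
        op = code[i]
        entry = OPCODES[op]
        if entry is None or i + (entry[1] - 1) >= len(code):
            lines.append(f"DB 0x{op:02X}")
            i += 1
            continue
        mnem, length = entry
        text = mnem
        if "d8" in mnem:
            text = mnem.replace("d8", f"0x{code[i + 1]:02X}")
        elif "d16" in mnem or "a16" in mnem:
            v = code[i + 1] | code[i + 2] << 8
            text = (mnem.replace("d16", f"0x{v:04X}")
                    .replace("a16", f"0x{v:04X}"))
        lines.append(text)
        i += length
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------- chaser fixture
def chaser_source(memmap: MemoryMap | None = None, clip: int = 5) -> str:
    """Assembly for the known-good pursuit genome.

    Per axis it computes the two's-complement difference (prey - agent),
    clips it to [-clip, clip] and stores it in the actuator cell, so the
    agent steps straight toward the prey every world step.  Used as the
    oracle for hunt mechanics and as the skilled-agent reference in the
    evolution experiments.
    """
    mm = memmap or MemoryMap()
    neg = (256 - clip) & 0xFF
    blocks = []
    for axis, (sens_p, sens_a, out) in enumerate(
            [(mm.sensor_prey_x, mm.sensor_agent_x, mm.out_dx),
             (mm.sensor_prey_y, mm.sensor_agent_y, mm.out_dy)]):
        s = "XY"[axis]
        blocks.append(f"""\
    LDA 0x{sens_p:04X}      ; prey {s.lower()}
    MOV B,A
    LDA 0x{sens_a:04X}      ; agent {s.lower()}
    MOV C,A
    MOV A,B
    SUB C               ; A = prey - agent (two's complement)
    JZ STORE{s}
    JM NEG{s}
    CPI 0x{clip + 1:02X}            ; positive: clip to +{clip}
    JC STORE{s}
    MVI A,0x{clip:02X}
    JMP STORE{s}
NEG{s}:
    CPI 0x{neg:02X}            ; negative: clip to -{clip}
    JNC STORE{s}
    MVI A,0x{neg:02X}
STORE{s}:
    STA 0x{out:04X}      ; out_d{s.lower()}
""")
    return "".join(blocks) + "    HLT\n"


def chaser_genome(memmap: MemoryMap | None = None, clip: int | None = None,
                  psi: int | None = None) -> bytes:
    """Assembled chaser padded with zero bytes to the genome length."""
    mm = memmap or MemoryMap()
    return assemble(chaser_source(mm, clip if clip is not None else 5),
                    memmap=mm, pad_to=psi if psi is not None else mm.genome_len)
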
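"""Deterministic seed derivation and a small counter-style RNG.

The whole simulator is replayable from one master seed.  Per-(epoch, agent)
streams are derived with the splitmix64 finaliser, so ensemble members are
independent of each other and of the order in which they are run.  The same
generator is implemented inside the numba kernels; the Python class here
produces bit-identical streams, which the world-model tests rely on.
"""

from __future__ import annotations

_M64 = (1 << 64) - 1
_GOLD = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


def mix64(z: int) -> int:
    """splitmix64 finaliser: a bijective 64-bit scrambler."""
    z &= _M64
    z = ((z ^ (z >> 30)) * _MIX1) & _M64
    z = ((z ^ (z >> 27)) * _MIX2) & _M64
    return z ^ (z >> 31)


def derive_seed(master: int, *keys: int) -> int:
    """Derive a 64-bit stream seed from a master seed and integer keys.

    Distinct key tuples give (with overwhelming probability) distinct,
    well-scrambled seeds; the mapping is pure, so replay never depends on
    execution order.
    """
    s = mix64(master & _M64)
    for k in keys:
        s = mix64(s ^ ((int(k) * _GOLD + _GOLD) & _M64))
    return s


class SplitMix64:
    """Tiny deterministic RNG, bit-compatible with the kernel implementation."""

    __slots__ = ("_s",)

    def __init__(self, seed: int):
        self._s = seed & _M64

    def u64(self) -> int:
        self._s = (self._s + _GOLD) & _M64
        z = self._s
        z = ((z ^ (z >> 30)) * _MIX1) & _M64
        z = ((z ^ (z >> 27)) * _MIX2) & _M64
        return z ^ (z >> 31)

    def below(self, n: int) -> int:
        """Uniform integer in [0, n).  Modulo bias is negligible for n << 2**64."""
        return self.u64() % n

    def int_range(self, lo: int, hi: int) -> int:
        """Uniform integer in the closed interval [lo, hi]."""
        return lo + self.below(hi - lo + 1)
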
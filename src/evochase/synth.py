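"""Synthetic K(t) series generators for testing the analysis stage.

A series spec is a list of segments covering a contiguous epoch range; each
segment is constant, linear or logarithmic in t.  Optional i.i.d. Gaussian
noise is added on top.  The presets echo the characteristic shapes of real
runs: a long flat stretch followed by one or two jump-like step increases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Segment", "make_synthetic_series", "preset", "PRESETS"]


@dataclass(frozen=True)
class Segment:
    """One piece of a synthetic series over epochs [t_lo, t_hi] inclusive."""

    kind: str                 # 'const' | 'linear' | 'log'
    t_lo: int
    t_hi: int
    params: tuple

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "const":
            return np.full_like(t, float(self.params[0]), dtype=float)
        if self.kind == "linear":
            m, q = self.params
            return m * t + q
        if self.kind == "log":
            a, b = self.params
            return a * np.log(t) + b
        raise ValueError(f"unknown segment kind {self.kind!r}")


def make_synthetic_series(segments, sigma: float = 0.0, seed: int = 0
                          ) -> pd.DataFrame:
    """Build a deterministic epoch/K frame from a segment spec.

    Segments must be non-overlapping and contiguous (each starts right after
    the previous one ends); overlaps or gaps are an error.
    """
    segs = [s if isinstance(s, Segment) else Segment(**s) for s in segments]
    if not segs:
        raise ValueError("no segments")
    segs = sorted(segs, key=lambda s: s.t_lo)
    for prev, cur in zip(segs, segs[1:]):
        if cur.t_lo <= prev.t_hi:
            raise ValueError(
                f"overlapping segments at t={cur.t_lo} (previous ends "
                f"at {prev.t_hi})")
        if cur.t_lo != prev.t_hi + 1:
            raise ValueError(f"gap between t={prev.t_hi} and t={cur.t_lo}")
    parts = []
    for s in segs:
        if s.t_lo < 1 or s.t_hi < s.t_lo:
            raise ValueError(f"bad segment range [{s.t_lo}, {s.t_hi}]")
        t = np.arange(s.t_lo, s.t_hi + 1, dtype=float)
        parts.append(pd.DataFrame({"epoch": t, "K": s.evaluate(t)}))
    df = pd.concat(parts, ignore_index=True)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        df["K"] = df["K"] + rng.normal(0.0, sigma, size=len(df))
    return df


# Preset shapes.  'two_step' is the two-jump benchmark used by the jump
# detector's accuracy study: 0.05 -> 0.35 at epoch 1500, -> 0.75 at 6000.
PRESETS = {
    "two_step": [
        Segment("const", 1, 1499, (0.05,)),
        Segment("const", 1500, 5999, (0.35,)),
        Segment("const", 6000, 10000, (0.75,)),
    ],
    "one_jump": [
        Segment("linear", 1, 2980, (2.6e-6, 0.05)),
        Segment("log", 2981, 10000, (0.16, -0.62)),
    ],
    "two_jump": [
        Segment("linear", 1, 1499, (2.6e-6, 0.05)),
        Segment("log", 1500, 5999, (0.05, 0.02)),
        Segment("log", 6000, 10000, (0.18, -0.66)),
    ],
    "log_window": [
        Segment("log", 2981, 10000, (0.16, -0.62)),
    ],
    "flat": [
        Segment("linear", 1, 10000, (2.6e-6, 0.32)),
    ],
}


def preset(name: str, sigma: float = 0.0, seed: int = 0) -> pd.DataFrame:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {list(PRESETS)}")
    return make_synthetic_series(PRESETS[name], sigma=sigma, seed=seed)
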
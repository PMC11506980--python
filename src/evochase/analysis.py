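"""Catch-rate analysis: normalisation, jump detection and growth-law fits.

The raw output of an evolutionary run is the ensemble catch total per epoch.
Normalising by the run maximum gives the success rate K(t) in [0, 1], which
doubles as the rate of developmental time per epoch of astronomical time.
This module turns K(t) into the quantities of interest:

* jump-like changes — abrupt selection-driven steps in K, located by binary
  segmentation on a median-smoothed series;
* growth-law fits — logarithmic a*ln(t)+b, power (c*t)^d, hyperbolic
  a*t/(t+b) and linear m*t+q models with parameters, standard errors and R^2;
* relative-frequency histograms of jump locations and magnitudes across
  replicate runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EpochSeries", "JumpEvent", "ModelFit", "Histogram",
    "normalize_series", "detect_jumps", "fit_model", "compare_models",
    "jump_histograms", "fit_windows_from_jumps", "MODELS",
]


@dataclass(frozen=True)
class EpochSeries:
    """Epoch-indexed success-rate series: t = 1..N, K normalised to max 1."""

    t: np.ndarray
    K: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self):
        if len(self.t) != len(self.K):
            raise ValueError("t and K must have equal length")

    def __len__(self):
        return len(self.t)

    def window(self, t_lo: float, t_hi: float) -> "EpochSeries":
        m = (self.t >= t_lo) & (self.t <= t_hi)
        if not m.any():
            raise ValueError(f"empty fit window [{t_lo}, {t_hi}]")
        raw = self.raw[m] if self.raw is not None else None
        return EpochSeries(self.t[m], self.K[m], raw)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpochSeries":
        if "K" in df.columns:
            k = df["K"].to_numpy(float)
        elif "total_catches" in df.columns:
            return normalize_series(df["total_catches"].to_numpy(),
                                    t=df["epoch"].to_numpy())
        else:
            raise ValueError("series frame needs a 'K' or 'total_catches' column")
        t = (df["epoch"] if "epoch" in df.columns
             else pd.RangeIndex(1, len(df) + 1)).to_numpy(float)
        raw = (df["total_catches"].to_numpy()
               if "total_catches" in df.columns else None)
        return cls(t, k, raw)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": self.t, "K": self.K}
        if self.raw is not None:
            d["total_catches"] = self.raw
        return pd.DataFrame(d)


def normalize_series(raw_catches, t=None) -> EpochSeries:
    """K_i = raw_i / max_j raw_j; errors out if nothing was ever caught."""
    raw = np.asarray(raw_catches, dtype=float)
    if raw.size == 0:
        raise ValueError("empty series")
    mx = raw.max()
    if mx <= 0:
        raise ValueError("no catches; K undefined")
    if t is None:
        t = np.arange(1, raw.size + 1, dtype=float)
    return EpochSeries(np.asarray(t, dtype=float), raw / mx, raw)


# ------------------------------------------------------------- jump detection
@dataclass(frozen=True)
class JumpEvent:
    """A detected step change: location (epoch) and magnitude (delta K)."""

    location: float
    magnitude: float
    pre_mean: float
    post_mean: float


def _moving_median(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    return (pd.Series(x).rolling(w, center=True, min_periods=1)
            .median().to_numpy())


def _best_split(prefix, prefix2, lo, hi, min_seg):
    """Best single change point of the piecewise-constant SSE in [lo, hi)."""
    n = hi - lo
    if n < 2 * min_seg:
        return -1, 0.0, 0.0, 0.0
    s = prefix[hi] - prefix[lo]
    s2 = prefix2[hi] - prefix2[lo]
    sse0 = s2 - s * s / n
    best_gain = 0.0
    best = -1
    best_pre = best_post = 0.0
    for cut in range(lo + min_seg, hi - min_seg + 1):
        nl = cut - lo
        nr = hi - cut
        sl = prefix[cut] - prefix[lo]
        sr = s - sl
        sse = (prefix2[cut] - prefix2[lo] - sl * sl / nl) \
            + (s2 - (prefix2[cut] - prefix2[lo]) - sr * sr / nr)
        gain = sse0 - sse
        if gain > best_gain:
            best_gain = gain
            best = cut
            best_pre = sl / nl
            best_post = sr / nr
    return best, best_gain, best_pre, best_post


def detect_jumps(series: EpochSeries, window: int = 101, threshold: float = 0.1,
                 min_seg: int = 200) -> list[JumpEvent]:
    """Locate jump-like changes in K by binary segmentation.

    K is first smoothed with a centred moving median (``window`` epochs),
    then recursively split at the point that most reduces the
    piecewise-constant sum of squared errors.  A split is accepted only if
    both segments have at least ``min_seg`` points and the segment means
    differ by at least ``threshold``.  Events are reported at the first
    epoch of the post-jump segment, sorted by location.
    """
    n = len(series)
    if n < 2 * min_seg:
        return []
    x = _moving_median(np.asarray(series.K, dtype=float), window)
    prefix = np.concatenate(([0.0], np.cumsum(x)))
    prefix2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cuts: list[int] = []

    def recurse(lo, hi):
        cut, gain, pre, post = _best_split(prefix, prefix2, lo, hi, min_seg)
        if cut < 0 or abs(post - pre) < threshold:
            return
        cuts.append(cut)
        recurse(lo, cut)
        recurse(cut, hi)

    recurse(0, n)
    cuts.sort()
    bounds = [0] + cuts + [n]
    events = []
    for i in range(1, len(bounds) - 1):
        pre = float(np.mean(x[bounds[i - 1]:bounds[i]]))
        post = float(np.mean(x[bounds[i]:bounds[i + 1]]))
        if abs(post - pre) >= threshold:
            events.append(JumpEvent(location=float(series.t[bounds[i]]),
                                    magnitude=post - pre,
                                    pre_mean=pre, post_mean=post))
    return events


def fit_windows_from_jumps(series: EpochSeries,
                           events: list[JumpEvent]) -> list[tuple[float, float]]:
    """Candidate nonlinear fit windows: from each jump to the next (or end)."""
    if not events:
        return [(float(series.t[0]), float(series.t[-1]))]
    locs = [e.location for e in events] + [float(series.t[-1])]
    return [(locs[i], locs[i + 1]) for i in range(len(locs) - 1)]


# -------------------------------------------------------------- growth models
def _f_log(t, a, b):
    return a * np.log(t) + b


def _f_linear(t, m, q):
    return m * t + q


def _f_power(t, c, d):
    return np.power(c * t, d)


def _f_hyperbolic(t, a, b):
    return a * t / (t + b)


MODELS = {
    "logarithmic": _f_log,
    "linear": _f_linear,
    "power": _f_power,
    "hyperbolic": _f_hyperbolic,
}

# screens applied when models are compared: a catch *rate* is meaningless at
# t = 0, so models with a definite value there are suspect, as are models
# that saturate to a horizontal asymptote
MODEL_FLAGS = {
    "logarithmic": (),
    "linear": ("defined_at_zero",),
    "power": ("defined_at_zero",),
    "hyperbolic": ("defined_at_zero", "horizontal_asymptote"),
}


@dataclass(frozen=True)
class ModelFit:
    """A fitted growth-law model over a window of the series."""

    model: str
    params: dict
    stderr: dict
    r2: float
    window: tuple[float, float]
    flags: tuple = ()

    def predict(self, t) -> np.ndarray:
        return MODELS[self.model](np.asarray(t, dtype=float),
                                  *self.params.values())


def _ols_line(x, y):
    """Slope/intercept with standard errors for y = m x + q."""
    n = len(x)
    X = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if n > 2:
        s2 = resid @ resid / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([np.nan, np.nan])
    return beta, se


def _r2(y, yhat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def fit_model(series: EpochSeries, model: str,
              window: tuple[float, float] | None = None) -> ModelFit:
    """Least-squares fit of one growth law over a window of the series.

    Logarithmic and linear models are solved in closed form (the log model
    is linear in ln t).  The power model is seeded from a log-log regression
    when all K > 0 and then polished by nonlinear least squares; the
    hyperbolic model uses multi-start nonlinear least squares.  R^2 is
    always computed on the original K scale.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {list(MODELS)}")
    sub = series.window(*window) if window is not None else series
    t = np.asarray(sub.t, dtype=float)
    y = np.asarray(sub.K, dtype=float)
    if model in ("logarithmic", "power") and np.any(t <= 0):
        raise ValueError(f"{model} model requires t > 0")
    if np.ptp(y) == 0:
        raise ValueError("constant K in window; R^2 undefined")
    win = (float(t[0]), float(t[-1]))
    flags = MODEL_FLAGS[model]

    if model == "logarithmic":
        (a, b), (sa, sb) = _ols_line(np.log(t), y)
        yhat = _f_log(t, a, b)
        return ModelFit(model, {"a": a, "b": b}, {"a": sa, "b": sb},
                        _r2(y, yhat), win, flags)
    if model == "linear":
        (m, q), (sm, sq) = _ols_line(t, y)
        yhat = _f_linear(t, m, q)
        return ModelFit(model, {"m": m, "q": q}, {"m": sm, "q": sq},
                        _r2(y, yhat), win, flags)
    if model == "power":
        starts = []
        if np.all(y > 0):
            # ln K = d ln t + d ln c is linear in log-log space
            (d0, i0), _ = _ols_line(np.log(t), np.log(y))
            if d0 != 0 and abs(i0 / d0) < 500:   # keep exp() in range
                starts.append((float(np.exp(i0 / d0)), float(d0)))
        starts += [(1.0 / np.median(t), 0.5), (1e-4, 0.36), (1e-2, 1.0)]
        return _nls(sub, model, starts, win, flags,
                    bounds=([1e-12, -10.0], [np.inf, 10.0]))
    # hyperbolic
    a0 = float(y.max()) or 1.0
    med = float(np.median(t))
    starts = [(a0, med), (a0, med / 10), (a0, med * 10), (2 * a0, med)]
    return _nls(sub, model, starts, win, flags,
                bounds=([0.0, 1e-9], [np.inf, np.inf]))


def _nls(sub: EpochSeries, model: str, starts, win, flags, bounds) -> ModelFit:
    t = np.asarray(sub.t, dtype=float)
    y = np.asarray(sub.K, dtype=float)
    f = MODELS[model]
    best = None
    last_err = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    f, t, y, p0=p0, bounds=bounds, maxfev=20_000)
            sse = float(np.sum((y - f(t, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
    if best is None:
        raise RuntimeError(
            f"{model} fit failed to converge from {len(starts)} starts "
            f"(last error: {last_err})")
    _, popt, pcov = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.full(len(popt), np.nan)
    names = ("c", "d") if model == "power" else ("a", "b")
    return ModelFit(model, dict(zip(names, popt)), dict(zip(names, se)),
                    _r2(y, f(t, *popt)), win, flags)


@dataclass
class ModelComparison:
    """All four growth-law fits over one window, ranked by R^2."""

    fits: list[ModelFit]
    residual_traces: dict = dfield(default_factory=dict)  # model -> (t, resid^2)

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model": f.model, "r2": f.r2, "flags": ";".join(f.flags),
             **{f"param_{k}": v for k, v in f.params.items()}}
            for f in self.fits])


def compare_models(series: EpochSeries,
                   window: tuple[float, float] | None = None
                   ) -> ModelComparison:
    """Fit every growth law on the window and rank by R^2.

    R^2 alone rarely separates the candidates; the per-model squared-residual
    traces and the qualitative flags (defined at t=0, horizontal asymptote)
    carry the argument for preferring the logarithmic law.
    """
    sub = series.window(*window) if window is not None else series
    fits = []
    traces = {}
    for name in MODELS:
        try:
            fit = fit_model(sub, name)
        except (ValueError, RuntimeError):
            continue
        fits.append(fit)
        resid = np.asarray(sub.K, float) - fit.predict(sub.t)
        traces[name] = (np.asarray(sub.t, float), resid ** 2)
    if not fits:
        raise RuntimeError("no model could be fitted on this window")
    fits.sort(key=lambda f: (-(f.r2 if np.isfinite(f.r2) else -np.inf)))
    return ModelComparison(fits, traces)


# ------------------------------------------------------------------ histograms
@dataclass(frozen=True)
class Histogram:
    """Relative-frequency histogram: bar heights sum to one."""

    edges: np.ndarray
    heights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.edges[:-1],
                             "bin_right": self.edges[1:],
                             "rel_freq": self.heights})


def jump_histograms(events: list[JumpEvent], bins: int = 10,
                    location_range=None, magnitude_range=None
                    ) -> tuple[Histogram, Histogram]:
    """Relative-frequency histograms of jump locations and magnitudes."""
    if not events:
        warnings.warn("no jump events; histograms are empty")
        empty = Histogram(np.array([0.0, 1.0]), np.array([0.0]))
        return empty, empty
    locs = np.array([e.location for e in events], dtype=float)
    mags = np.array([e.magnitude for e in events], dtype=float)
    out = []
    for data, rng in ((locs, location_range), (mags, magnitude_range)):
        counts, edges = np.histogram(data, bins=bins, range=rng)
        out.append(Histogram(edges, counts / counts.sum()))
    return out[0], out[1]
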
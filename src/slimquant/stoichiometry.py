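"""Molecule counting from stepwise photobleaching.

The number of reporter molecules in a tracked aggregate is its initial
(unbleached) track intensity divided by the brightness of one fluorophore.
The single-molecule brightness is calibrated in situ from the terminal
photobleaching steps of traces that bleach to completion: after
edge-preserving (Chung–Kennedy) filtering, downward intensity steps are
detected and the modal size of the final steps is taken as the brightness of
one molecule. Population distributions of stoichiometry are rendered with
Gaussian kernel density estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SingleMoleculeBrightness",
    "StoichiometryEstimate",
    "StoichiometryDistribution",
    "chung_kennedy_filter",
    "detect_steps",
    "single_molecule_brightness",
    "initial_intensity",
    "stoichiometry",
    "kde_distribution",
]


@dataclass
class SingleMoleculeBrightness:
    value: float                      # A.U. per molecule
    ci: tuple[float, float]           # bootstrap CI over traces
    method: str                       # terminal_steps | fourier_pairwise
    n_steps_used: int


@dataclass
class StoichiometryEstimate:
    track_id: int
    initial_intensity: float          # I0, A.U.
    stoichiometry: float              # molecules
    dark_corrected: bool


@dataclass
class StoichiometryDistribution:
    grid: np.ndarray                  # molecules
    density: np.ndarray
    bandwidth: float
    peaks: np.ndarray                 # molecule positions of local maxima


def chung_kennedy_filter(trace, window: int = 10, weighting_exponent: float = 2.0):
    """Edge-preserving forward/backward mean filter.

    Each point is replaced by a combination of the trailing and leading
    window means, weighted by the inverse local variance of each predictor
    raised to ``weighting_exponent`` — so the window that straddles a step
    (high variance) is down-weighted and edges survive filtering.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if window < 2:
        raise ValueError("window must be >= 2")
    if n <= window:
        warnings.warn("trace shorter than filter window: returned unchanged")
        return trace.copy()
    eps = 1e-12
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace * trace)])
    t = np.arange(n)
    fs = np.maximum(0, t - window + 1)          # trailing window [fs, t]
    fl = t + 1 - fs
    mf = (c1[t + 1] - c1[fs]) / fl
    vf = np.maximum((c2[t + 1] - c2[fs]) / fl - mf * mf, 0.0)
    be = np.minimum(n, t + window)              # leading window [t, be)
    bl = be - t
    mb = (c1[be] - c1[t]) / bl
    vb = np.maximum((c2[be] - c2[t]) / bl - mb * mb, 0.0)
    with np.errstate(divide="ignore", over="ignore"):
        wf = np.where(vf < eps, np.inf, vf ** (-weighting_exponent))
        wb = np.where(vb < eps, np.inf, vb ** (-weighting_exponent))
    out = np.empty(n)
    both = (vf < eps) & (vb < eps)
    fonly = (vf < eps) & ~both
    bonly = (vb < eps) & ~both
    rest = ~(both | fonly | bonly)
    out[both] = 0.5 * (mf[both] + mb[both])
    out[fonly] = mf[fonly]
    out[bonly] = mb[bonly]
    out[rest] = (wf[rest] * mf[rest] + wb[rest] * mb[rest]) / (wf[rest] + wb[rest])
    return out


def detect_steps(trace, min_step: float, min_dwell: int = 5):
    """Detect downward intensity steps (photobleaching events).

    A step is a change point where the mean over the next ``min_dwell``
    frames sits at least ``min_step`` below the mean over the previous
    ``min_dwell`` frames, taken at the local maximum of the drop (non-maximum
    suppression within one dwell time). Returns a list of ``(frame, size)``
    pairs with size > 0 for drops; ``frame`` is the first frame of the new
    (lower) level.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n == 0:
        raise ValueError("empty trace")
    if n < 2 * min_dwell:
        return []
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    drops = np.zeros(n)
    ts = np.arange(min_dwell, n - min_dwell + 1)
    before = (c1[ts] - c1[ts - min_dwell]) / min_dwell
    after = (c1[ts + min_dwell] - c1[ts]) / min_dwell
    drops[ts] = before - after
    candidates = list(ts[drops[ts] >= min_step])
    steps = []
    used = np.zeros(n, dtype=bool)
    for t in sorted(candidates, key=lambda t: -drops[t]):
        if used[max(0, t - min_dwell): t + min_dwell].any():
            continue
        used[t] = True
        steps.append((t, float(drops[t])))
    steps.sort()
    return steps


def _kde_mode(values: np.ndarray, rel_bw: float = 0.15) -> float:
    """Mode of a sample via Gaussian KDE (robust to a few outliers)."""
    values = np.asarray(values, dtype=float)
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    bw = max(rel_bw * np.median(values), 1e-9)
    kde = stats.gaussian_kde(values, bw_method=bw / max(values.std(ddof=1), 1e-12))
    grid = np.linspace(values.min() - bw, values.max() + bw, 512)
    return float(grid[np.argmax(kde(grid))])


def _terminal_step_sizes(traces, ck_window, ck_exponent, min_dwell):
    sizes = []
    for trace in traces:
        trace = np.asarray(trace, dtype=float)
        if trace.size < 2 * min_dwell:
            continue
        filt = chung_kennedy_filter(trace, ck_window, ck_exponent) \
            if trace.size > ck_window else trace
        # noise scale from first differences (step-free estimate)
        noise = np.median(np.abs(np.diff(trace))) / (0.6745 * np.sqrt(2)) if trace.size > 1 else 0.0
        min_step = max(4.0 * noise, 1e-9)
        steps = detect_steps(filt, min_step=min_step, min_dwell=min_dwell)
        if not steps:
            continue
        t_last, size = steps[-1]
        tail = filt[t_last: t_last + min_dwell]
        # fully bleached: the post-step level is consistent with zero
        if abs(tail.mean()) <= max(0.5 * size, 3.0 * noise):
            sizes.append(size)
    return np.array(sizes)


def _pairwise_difference_sizes(traces, ck_window, ck_exponent):
    """Pairwise level differences within each filtered trace, with the
    within-plateau noise differences stripped out."""
    diffs = []
    for trace in traces:
        trace = np.asarray(trace, dtype=float)
        filt = chung_kennedy_filter(trace, ck_window, ck_exponent) \
            if trace.size > ck_window else trace
        noise = np.median(np.abs(np.diff(trace))) / (0.6745 * np.sqrt(2)) \
            if trace.size > 1 else 0.0
        sub = filt[:: max(1, filt.size // 200)]
        d = np.abs(sub[:, None] - sub[None, :])
        d = d[np.triu_indices_from(d, k=1)]
        diffs.append(d[d > max(4.0 * noise, 1e-9)])
    return np.concatenate(diffs) if diffs else np.array([])


def single_molecule_brightness(traces, method: str = "terminal_steps",
                               ck_window: int = 10, ck_exponent: float = 2.0,
                               min_dwell: int = 5, n_boot: int = 200,
                               rng=None) -> SingleMoleculeBrightness:
    """Calibrate the brightness of a single fluorophore from bleach traces.

    ``terminal_steps``: modal (KDE-peak) size of the last detected bleaching
    step of each fully-bleaching trace. ``fourier_pairwise``: peak of the
    distribution of pairwise level differences across each filtered trace.
    The confidence interval is a percentile bootstrap over traces.
    """
    traces = list(traces)
    if len(traces) < 10:
        raise ValueError("brightness calibration needs at least 10 traces")
    if method == "terminal_steps":
        sizes = _terminal_step_sizes(traces, ck_window, ck_exponent, min_dwell)
        if sizes.size == 0:
            raise ValueError("no trace reaches full photobleaching; cannot calibrate")
    elif method == "fourier_pairwise":
        sizes = _pairwise_difference_sizes(traces, ck_window, ck_exponent)
        if sizes.size == 0:
            raise ValueError("no intensity differences found; cannot calibrate")
    else:
        raise ValueError(f"unknown calibration method {method!r}")

    rng = np.random.default_rng(rng)
    if sizes.size > 5000:  # KDE mode cost is O(n * grid); subsample
        sizes = rng.choice(sizes, size=5000, replace=False)
    value = _kde_mode(sizes)
    if np.ptp(sizes) == 0:
        ci = (value, value)
    else:
        boots = [_kde_mode(rng.choice(sizes, size=sizes.size, replace=True))
                 for _ in range(n_boot)]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), value), max(float(hi), value))
    return SingleMoleculeBrightness(value=float(value), ci=ci, method=method,
                                    n_steps_used=int(sizes.size))


def initial_intensity(trace, frames=None, window: int = 4) -> float:
    """Initial unbleached intensity I0 of a trace.

    Fits a single-exponential decay A*exp(-k*t) and evaluates it at frame 0
    (robust to partial bleaching before tracking locks on); falls back to
    the mean of the first ``window`` frames if the fit fails.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if frames is None:
        frames = np.arange(trace.size)
    frames = np.asarray(frames, dtype=float)
    if not np.any(trace > 0):
        return 0.0
    fallback = float(trace[: max(1, min(window, trace.size))].mean())
    if trace.size < max(3, window):
        return fallback
    try:
        top = max(trace.max(), 1e-9)
        # fit only the contiguous unbleached prefix: the single-exponential
        # model does not describe the post-bleach background tail, and noise
        # excursions within the tail must not re-enter the fit
        above = trace > 0.05 * top
        cut = int(np.argmax(~above)) if not above.all() else trace.size
        pos = np.zeros(trace.size, dtype=bool)
        pos[:cut] = True
        if pos.sum() < 3:
            return fallback
        # log-linear seed, then nonlinear refinement
        k0, loga = np.polyfit(frames[pos], np.log(trace[pos]), 1)
        k0 = max(-k0, 1e-6)
        popt, _ = optimize.curve_fit(
            lambda t, a, k: a * np.exp(-k * t), frames[pos], trace[pos],
            p0=[math_exp_safe(loga), k0], maxfev=2000)
        a, k = popt
        if not np.isfinite(a) or a <= 0 or k < 0:
            return fallback
        # sanity guard against runaway extrapolation on pathological traces
        if a > 10.0 * top:
            return fallback
        return float(a)
    except Exception:
        return fallback


def math_exp_safe(x: float) -> float:
    return float(np.exp(np.clip(x, -700, 700)))


def stoichiometry(i0: float, brightness: SingleMoleculeBrightness | float,
                  dark_fraction: float = 0.0, track_id: int = -1) -> StoichiometryEstimate:
    """S = I0 / I_single, optionally corrected for never-photoactive
    fluorophores by the factor 1/(1 - dark_fraction)."""
    value = brightness.value if isinstance(brightness, SingleMoleculeBrightness) else float(brightness)
    if value <= 0:
        raise ValueError("single-molecule brightness must be positive")
    if not (0.0 <= dark_fraction < 1.0):
        raise ValueError("dark_fraction must be in [0, 1)")
    s = i0 / value
    corrected = dark_fraction > 0
    if corrected:
        s /= (1.0 - dark_fraction)
    return StoichiometryEstimate(track_id=track_id, initial_intensity=float(i0),
                                 stoichiometry=float(s), dark_corrected=corrected)


def kde_distribution(stoichiometries, bandwidth: float | None = None,
                     n_grid: int = 512) -> StoichiometryDistribution:
    """Gaussian-KDE rendering of a stoichiometry population.

    The grid spans [0, 1.2*max]; peaks are local maxima above 5% of the
    global maximum. An all-equal sample yields a single delta-like peak.
    """
    values = np.asarray(list(stoichiometries), dtype=float)
    if values.size < 5:
        raise ValueError("KDE rendering needs at least 5 values")
    hi = max(values.max() * 1.2, 1e-6)
    grid = np.linspace(0.0, hi, n_grid)
    if np.ptp(values) == 0:
        # degenerate sample: narrow Gaussian centred on the common value
        bw = max(0.01 * abs(values[0]), 1e-3)
        density = stats.norm.pdf(grid, loc=values[0], scale=bw)
        density /= np.trapezoid(density, grid)
        peaks = np.array([values[0]])
        return StoichiometryDistribution(grid=grid, density=density,
                                         bandwidth=bw, peaks=peaks)
    sd = values.std(ddof=1)
    if bandwidth is None:
        bandwidth = 0.9 * min(sd, stats.iqr(values) / 1.34) * values.size ** (-0.2)
        bandwidth = max(bandwidth, 1e-6)
    kde = stats.gaussian_kde(values, bw_method=bandwidth / sd)
    density = kde(grid)
    density /= np.trapezoid(density, grid)  # exact unit mass on the grid
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    thresh = 0.05 * density.max()
    peaks = grid[1:-1][interior & (density[1:-1] >= thresh)]
    return StoichiometryDistribution(grid=grid, density=density,
                                     bandwidth=float(bandwidth), peaks=peaks)
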
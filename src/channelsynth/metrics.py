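"""Real-vs-generated fidelity metrics.

Three complementary views of similarity between a set of real windows and a
set of generated windows:

* unbiased Gaussian-kernel maximum mean discrepancy (MMD) — a kernel
  two-sample statistic; smaller means the two distributions are closer,
* dynamic time warping (DTW) — elastic time-series dissimilarity, both the
  exact O(NM) recurrence and a coarsen-project-refine approximation,
* all-points amplitude histograms and their intersection distance — the
  electrophysiologist's first summary plot, where modes are conductance
  levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .signal_io import PairedRecord

__all__ = [
    "MetricReport",
    "mmd",
    "median_heuristic_bandwidth",
    "dtw_exact",
    "dtw_approx",
    "amplitude_histogram",
    "histogram_distance",
    "count_amplitude_peaks",
    "compare_batches",
]


# ---------------------------------------------------------------------------
# maximum mean discrepancy
# ---------------------------------------------------------------------------

def median_heuristic_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    """Median pairwise Euclidean distance over the pooled sample X ∪ Y.

    The standard default kernel scale for MMD when nothing better is known.
    """
    Z = np.vstack([np.atleast_2d(X), np.atleast_2d(Y)])
    d2 = _sq_dists(Z, Z)
    iu = np.triu_indices(len(Z), k=1)
    med = float(np.sqrt(np.median(d2[iu])))
    return med if med > 0 else 1.0


def mmd(X: np.ndarray, Y: np.ndarray, bandwidth: float | None = None) -> float:
    """Unbiased squared-MMD estimate with a Gaussian kernel.

    ``X`` is n x d, ``Y`` is m x d (windows flattened to vectors).  The
    estimator omits diagonal terms, so it can dip slightly below zero for
    similar samples.  ``bandwidth`` is the kernel length scale sigma in
    ``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))``; defaults to the median
    heuristic on the pooled sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError(f"need at least 2 samples per group, got n={n}, m={m}")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(X, Y)
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    gamma = 1.0 / (2.0 * bandwidth**2)
    Kxx = np.exp(-gamma * _sq_dists(X, X))
    Kyy = np.exp(-gamma * _sq_dists(Y, Y))
    Kxy = np.exp(-gamma * _sq_dists(X, Y))
    term_xx = (Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
    term_yy = (Kyy.sum() - np.trace(Kyy)) / (m * (m - 1))
    term_xy = 2.0 * Kxy.sum() / (n * m)
    return float(term_xx - term_xy + term_yy)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    d2 = aa + bb - 2.0 * A @ B.T
    return np.maximum(d2, 0.0)


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

_COSTS: dict[str, Callable[[float, float], float]] = {
    "squared": lambda a, b: (a - b) ** 2,
    "absolute": lambda a, b: abs(a - b),
}


def _resolve_cost(cost):
    if callable(cost):
        return cost
    try:
        return _COSTS[cost]
    except KeyError:
        raise ValueError(f"unknown cost {cost!r}; use 'squared', 'absolute' or a callable")


def dtw_exact(x: np.ndarray, y: np.ndarray, cost: str | Callable = "squared") -> float:
    """Exact DTW distance via the full dynamic program.

    ``D[i, j] = f(x_i, y_j) + min(D[i, j-1], D[i-1, j], D[i-1, j-1])`` with
    the first row/column accumulating; returns the bottom-right cell.
    ``dtw_exact(x, x) == 0`` whenever ``f(a, a) == 0``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("series must be non-empty")
    f = _resolve_cost(cost)
    if cost == "squared":
        local = (x[:, None] - y[None, :]) ** 2
    elif cost == "absolute":
        local = np.abs(x[:, None] - y[None, :])
    else:
        local = np.array([[f(a, b) for b in y] for a in x], dtype=float)
    return float(_dp_full(local))


def _dp_full_py(local: np.ndarray) -> float:
    N, M = local.shape
    D = np.empty((N, M))
    D[0, 0] = local[0, 0]
    D[0, 1:] = local[0, 1:].cumsum() + D[0, 0]
    D[1:, 0] = local[1:, 0].cumsum() + D[0, 0]
    for i in range(1, N):
        for j in range(1, M):
            D[i, j] = local[i, j] + min(D[i, j - 1], D[i - 1, j], D[i - 1, j - 1])
    return D[-1, -1]


try:  # the DP is a serial recurrence; JIT it when numba is around
    from numba import njit as _njit

    _dp_full = _njit(cache=True)(_dp_full_py)
except ImportError:  # pragma: no cover
    _dp_full = _dp_full_py


def dtw_approx(x: np.ndarray, y: np.ndarray, radius: int = 1,
               cost: str | Callable = "squared") -> float:
    """Approximate DTW by recursive coarsening and band-constrained refinement.

    The series are halved, the coarse problem solved recursively, the coarse
    warp path projected up, widened by ``radius`` cells, and the dynamic
    program re-run inside that band.  With ``radius >= max(N, M)`` the band
    covers the whole matrix and the result equals :func:`dtw_exact`.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("series must be non-empty")
    f = _resolve_cost(cost)
    dist, _ = _fastdtw(x, y, radius, f)
    return float(dist)


def _fastdtw(x, y, radius, f):
    min_size = radius + 2
    if len(x) <= min_size or len(y) <= min_size:
        return _dtw_windowed(x, y, None, f)
    coarse_x = _halve(x)
    coarse_y = _halve(y)
    _, coarse_path = _fastdtw(coarse_x, coarse_y, radius, f)
    window = _expand_window(coarse_path, len(x), len(y), radius)
    return _dtw_windowed(x, y, window, f)


def _halve(s):
    n = len(s) // 2
    out = 0.5 * (s[: 2 * n : 2] + s[1 : 2 * n : 2])
    if len(s) % 2:
        out = np.append(out, s[-1])
    return out


def _expand_window(path, N, M, radius):
    cells = set()
    for i, j in path:
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                cells.add((i + di, j + dj))
    window = {}
    for i, j in cells:
        # project coarse cell (i, j) to the four fine cells it covers
        for fi in (2 * i, 2 * i + 1):
            if 0 <= fi < N:
                lo, hi = window.get(fi, (M, -1))
                jlo = max(0, 2 * j)
                jhi = min(M - 1, 2 * j + 1)
                if jlo <= jhi:
                    window[fi] = (min(lo, jlo), max(hi, jhi))
    # make the band monotone and gap-free so the DP stays connected
    prev_hi = 0
    for i in range(N):
        lo, hi = window.get(i, (prev_hi, prev_hi))
        lo = min(lo, prev_hi)
        window[i] = (lo, hi)
        prev_hi = hi
    return window


def _dtw_windowed(x, y, window, f):
    N, M = len(x), len(y)
    INF = np.inf
    D = np.full((N + 1, M + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, N + 1):
        if window is None:
            jlo, jhi = 1, M
        else:
            lo, hi = window[i - 1]
            jlo, jhi = lo + 1, hi + 1
        xi = x[i - 1]
        for j in range(jlo, jhi + 1):
            d = f(xi, y[j - 1])
            D[i, j] = d + min(D[i, j - 1], D[i - 1, j], D[i - 1, j - 1])
    # traceback for the path
    path = []
    i, j = N, M
    while i > 0 or j > 0:
        path.append((i - 1, j - 1))
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            steps = ((D[i - 1, j - 1], i - 1, j - 1),
                     (D[i - 1, j], i - 1, j),
                     (D[i, j - 1], i, j - 1))
            _, i, j = min(steps, key=lambda t: t[0])
    path.reverse()
    return D[N, M], path


# ---------------------------------------------------------------------------
# amplitude histograms
# ---------------------------------------------------------------------------

def amplitude_histogram(
    record: PairedRecord | np.ndarray, bins: int | np.ndarray | str = "fd"
) -> tuple[np.ndarray, np.ndarray]:
    """All-points amplitude histogram of the current row.

    Every sample contributes; modes sit at the conductance levels.  Returns
    ``(density, edges)`` with the density integrating to 1.  ``bins`` is
    anything :func:`numpy.histogram` accepts (default Freedman-Diaconis).
    """
    data = record.raw if isinstance(record, PairedRecord) else np.asarray(record, float)
    if data.size == 0:
        raise ValueError("record has no samples")
    edges = np.histogram_bin_edges(data, bins=bins)
    if edges[-1] <= edges[0]:
        raise ValueError("zero-width bin range (constant record?)")
    density, edges = np.histogram(data, bins=edges, density=True)
    return density, edges


def histogram_distance(
    a: PairedRecord | np.ndarray, b: PairedRecord | np.ndarray,
    bins: int | str = "fd",
) -> float:
    """Histogram intersection distance ``1 - sum(min(h1, h2))`` in [0, 1].

    Both records are binned on a shared grid built from the pooled data, and
    the histograms are normalised to unit mass so 0 means identical binned
    distributions and 1 means disjoint support.
    """
    xa = a.raw if isinstance(a, PairedRecord) else np.asarray(a, float)
    xb = b.raw if isinstance(b, PairedRecord) else np.asarray(b, float)
    pooled = np.concatenate([xa, xb])
    edges = np.histogram_bin_edges(pooled, bins=bins)
    if edges[-1] <= edges[0]:
        raise ValueError("zero-width bin range")
    ha, _ = np.histogram(xa, bins=edges)
    hb, _ = np.histogram(xb, bins=edges)
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(1.0 - np.minimum(pa, pb).sum())


def count_amplitude_peaks(
    data: np.ndarray, n_bins: int = 40, smooth: int = 3, prominence: float = 0.05
) -> int:
    """Count modes in an all-points amplitude histogram.

    The histogram is lightly smoothed with a moving average and peaks with
    relative prominence above ``prominence`` (fraction of the tallest bin)
    are counted; a two-level channel gives 2.
    """
    from scipy.signal import find_peaks

    data = np.asarray(data, float).ravel()
    h, _ = np.histogram(data, bins=n_bins)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        h = np.convolve(h, kernel, mode="same")
    peaks, _ = find_peaks(h, prominence=prominence * h.max())
    return int(len(peaks))


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Bundle of fidelity metrics between a real and a generated batch."""

    mmd: float
    dtw: float
    histogram_distance: float
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mmd": self.mmd,
            "dtw": self.dtw,
            "histogram_distance": self.histogram_distance,
            "parameters": self.parameters,
        }


def compare_batches(
    real: np.ndarray,
    generated: np.ndarray,
    bandwidth: float | None = None,
    dtw_pairs: int = 32,
    dtw_radius: int = 1,
    cost: str = "squared",
    bins: int | str = "fd",
    seed: int = 0,
) -> MetricReport:
    """Full fidelity report between two ``N x 2 x W`` scaled window batches.

    MMD is computed on flattened whole windows; DTW on the current row of
    ``dtw_pairs`` randomly paired real/generated windows (averaged);
    the histogram distance on all current-row samples pooled per batch.
    """
    real = np.asarray(real, float)
    generated = np.asarray(generated, float)
    Xf = real.reshape(len(real), -1)
    Yf = generated.reshape(len(generated), -1)
    bw = bandwidth if bandwidth is not None else median_heuristic_bandwidth(Xf, Yf)
    mmd_val = mmd(Xf, Yf, bw)

    rng = np.random.default_rng(seed)
    n_pairs = min(dtw_pairs, len(real), len(generated))
    ri = rng.choice(len(real), size=n_pairs, replace=False)
    gi = rng.choice(len(generated), size=n_pairs, replace=False)
    dtws = [
        dtw_approx(real[i, 0], generated[j, 0], radius=dtw_radius, cost=cost)
        for i, j in zip(ri, gi)
    ]
    hist_d = histogram_distance(real[:, 0, :].ravel(), generated[:, 0, :].ravel(), bins=bins)

    return MetricReport(
        mmd=mmd_val,
        dtw=float(np.mean(dtws)),
        histogram_distance=hist_d,
        parameters={
            "bandwidth": bw,
            "dtw_pairs": n_pairs,
            "dtw_radius": dtw_radius,
            "dtw_cost": cost,
            "bins": bins,
            "seed": seed,
        },
    )
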
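"""Dwell-time kinetic analysis of idealization rows.

Under Markov gating, the sojourn times a channel spends open or closed are
mixtures of exponentials whose time constants reflect the underlying rate
matrix.  This module run-length-encodes an idealization into open/closed
sojourns and fits exponential mixtures to them by maximum likelihood
(expectation-maximization with multistart), with BIC-based selection of the
number of components.

The first and last sojourns of a record are censored (their true length is
unknown) and excluded from fitting by default.  Fitting is on the raw
durations, not on binned histograms; a Sigworth-Sine style log-binned
histogram helper is provided for plotting only.  No missed-event (burst)
correction is applied: the minimum resolvable dwell is one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import PairedRecord

__all__ = [
    "DwellSet",
    "ExpMixFit",
    "extract_dwells",
    "fit_exp_mixture",
    "select_K",
    "log_binned_histogram",
]


@dataclass
class DwellSet:
    """Sojourn durations (s) for one conductance class of one record."""

    durations: np.ndarray          # uncensored sojourns, seconds
    sample_rate: float
    n_censored: int = 0            # first/last sojourns excluded
    channel_class: str = ""        # "open" | "closed"

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.size and self.durations.min() < 1.0 / self.sample_rate - 1e-12:
            raise ValueError("dwell shorter than one sample period")

    def __len__(self) -> int:
        return len(self.durations)


@dataclass
class ExpMixFit:
    """Maximum-likelihood exponential-mixture fit of a dwell set.

    Density ``f(t) = sum_k (w_k / tau_k) exp(-t / tau_k)`` with time
    constants ``taus`` ascending and weights summing to 1.
    """

    K: int
    taus: np.ndarray       # seconds, strictly increasing
    weights: np.ndarray
    log_likelihood: float
    bic: float
    n: int
    converged: bool = True

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "taus_ms": (self.taus * 1e3).tolist(),
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n": self.n,
            "converged": self.converged,
        }


def extract_dwells(record: PairedRecord) -> dict[str, DwellSet]:
    """Run-length-encode the label row into open and closed dwell sets.

    Samples with label >= 1 are "open" (all conducting levels aggregated),
    label 0 is "closed".  The first and last sojourns are censored and
    dropped from the returned durations; their count is recorded.
    """
    binary = (record.label >= 1).astype(np.int8)
    change = np.flatnonzero(np.diff(binary)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(binary)]])
    lengths = ends - starts
    classes = binary[starts]

    n_runs = len(lengths)
    censored = np.zeros(n_runs, dtype=bool)
    censored[0] = True
    censored[-1] = True

    out: dict[str, DwellSet] = {}
    for name, cls in (("closed", 0), ("open", 1)):
        keep = (classes == cls) & ~censored
        n_cens = int(np.sum((classes == cls) & censored))
        out[name] = DwellSet(
            durations=lengths[keep] / record.sample_rate,
            sample_rate=record.sample_rate,
            n_censored=n_cens,
            channel_class=name,
        )
    return out


# ---------------------------------------------------------------------------
# exponential mixture fitting
# ---------------------------------------------------------------------------

def _loglik(t: np.ndarray, taus: np.ndarray, w: np.ndarray) -> float:
    dens = (w / taus)[None, :] * np.exp(-t[:, None] / taus[None, :])
    return float(np.sum(np.log(np.maximum(dens.sum(axis=1), 1e-300))))


def _em(t: np.ndarray, taus0: np.ndarray, w0: np.ndarray,
        max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float, bool]:
    taus, w = taus0.copy(), w0.copy()
    ll_prev = _loglik(t, taus, w)
    converged = False
    for _ in range(max_iter):
        # E-step: responsibilities
        dens = (w / taus)[None, :] * np.exp(-t[:, None] / taus[None, :])
        total = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        r = dens / total
        # M-step
        rk = r.sum(axis=0)
        rk = np.maximum(rk, 1e-12)
        w = rk / len(t)
        taus = (r * t[:, None]).sum(axis=0) / rk
        taus = np.maximum(taus, 1e-12)
        ll = _loglik(t, taus, w)
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise RuntimeError("EM likelihood decreased — numerical fault")
        if ll - ll_prev < tol:
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
    return taus, w, ll_prev, converged


def fit_exp_mixture(
    dwells: DwellSet,
    K: int,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> ExpMixFit:
    """Fit a K-component exponential mixture to a dwell set by EM.

    Multistart: one quantile-spread initialisation plus ``n_starts - 1``
    seeded random perturbations; the best likelihood wins.  For K = 1 the
    MLE is the sample mean in closed form (EM reaches it in one step).
    Deterministic given ``seed``.
    """
    t = np.asarray(dwells.durations, dtype=float)
    n = len(t)
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 10 * K:
        raise ValueError(
            f"need at least {10 * K} uncensored dwells for K={K}, have {n}"
        )
    if K == 1:
        tau = float(np.mean(t))
        ll = _loglik(t, np.array([tau]), np.array([1.0]))
        return ExpMixFit(1, np.array([tau]), np.array([1.0]), ll,
                         _bic(ll, 1, n), n)

    rng = np.random.default_rng(seed)
    # quantile-based spread of initial taus across the duration range
    qs = np.quantile(t, np.linspace(0.15, 0.95, K))
    inits = [np.maximum(qs, 1e-9)]
    for _ in range(n_starts - 1):
        inits.append(np.maximum(qs * rng.lognormal(0.0, 0.5, size=K), 1e-9))

    best = None
    for taus0 in inits:
        w0 = np.full(K, 1.0 / K)
        try:
            taus, w, ll, conv = _em(t, np.sort(taus0), w0, max_iter, tol)
        except RuntimeError:
            continue
        if best is None or ll > best[2]:
            best = (taus, w, ll, conv)
    if best is None:
        raise RuntimeError("all EM starts failed")
    taus, w, ll, conv = best
    order = np.argsort(taus)
    taus, w = taus[order], w[order]
    # merge numerically identical components so taus stay strictly increasing
    taus, w = _merge_close(taus, w)
    Keff = len(taus)
    w = w / w.sum()
    return ExpMixFit(Keff, taus, w, ll, _bic(ll, Keff, n), n, converged=conv)


def _merge_close(taus: np.ndarray, w: np.ndarray, rtol: float = 1e-6):
    out_t, out_w = [taus[0]], [w[0]]
    for tau, wk in zip(taus[1:], w[1:]):
        if tau - out_t[-1] <= rtol * tau:
            tot = out_w[-1] + wk
            out_t[-1] = (out_t[-1] * out_w[-1] + tau * wk) / tot
            out_w[-1] = tot
        else:
            out_t.append(tau)
            out_w.append(wk)
    return np.array(out_t), np.array(out_w)


def _bic(ll: float, K: int, n: int) -> float:
    n_params = 2 * K - 1  # K taus + (K-1) free weights
    return float(-2.0 * ll + n_params * np.log(n))


def select_K(dwells: DwellSet, K_max: int = 4, seed: int = 0, **kw) -> ExpMixFit:
    """Fit K = 1..K_max mixtures and return the BIC-minimising fit."""
    best = None
    for K in range(1, K_max + 1):
        if len(dwells) < 10 * K:
            break
        fit = fit_exp_mixture(dwells, K, seed=seed, **kw)
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise ValueError(f"too few dwells ({len(dwells)}) to fit even K=1")
    return best


def log_binned_histogram(
    dwells: DwellSet, n_bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Square-root-ordinate log-binned dwell histogram for display.

    Returns ``(sqrt_density, log10_edges)``; on these axes each exponential
    component appears as a peak at its time constant, the conventional way
    dwell distributions are plotted.
    """
    t = dwells.durations
    if len(t) == 0:
        raise ValueError("empty dwell set")
    lo, hi = np.log10(t.min()), np.log10(t.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.log10(t), bins=edges)
    widths = np.diff(10**edges)
    density = counts / (len(t) * widths)
    return np.sqrt(density), edges
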
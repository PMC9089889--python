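"""Continuous-time Markov simulation of single-channel gating.

Channel gating is modelled as a continuous-time Markov chain over
conformational states, only some of which conduct.  Trajectories are drawn
by exact event-time (Gillespie) simulation and then snapped onto the uniform
sampling grid, so sojourns shorter than one sample are naturally censored —
the same bandwidth loss a real digitised recording suffers.  The raw current
is the conductance-level staircase plus Gaussian noise, low-pass filtered
with a 4-pole Butterworth applied forward only (an analog amplifier filter
is causal).

This simulator is the "traditional method" the generative model is compared
against, and the source of every synthetic fixture in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal
from scipy.sparse.csgraph import connected_components

from .signal_io import PairedRecord

__all__ = ["GatingModel", "equilibrium_distribution", "sample_trajectory", "two_state_model"]

_MAX_SAMPLES = 2**31 - 1


@dataclass
class GatingModel:
    """A Markov gating scheme plus the recording model around it.

    Parameters
    ----------
    state_names
        One identifier per Markov state.
    open_count
        Open-channel count of each state (0 = closed, k = k channels open).
    Q
        Transition-rate matrix in 1/s; off-diagonals >= 0, rows sum to 0.
    unitary_current
        Current step per open channel, pA (negative for inward current).
    baseline
        Closed-channel current level, pA.
    noise_sd
        SD of the Gaussian noise added to the trace, pA (before filtering
        by default).
    filter_cutoff
        Low-pass corner frequency in Hz (4-pole Butterworth, forward only);
        None disables filtering.
    sample_rate
        Digitisation rate, Hz.
    noise_after_filter
        If True, noise is added after the filter instead of before
        (amplifier-referred noise is the default).
    """

    state_names: list[str]
    open_count: np.ndarray
    Q: np.ndarray
    unitary_current: float = -5.0
    baseline: float = 0.0
    noise_sd: float = 1.0
    filter_cutoff: float | None = 1000.0
    sample_rate: float = 5000.0
    noise_after_filter: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.open_count = np.asarray(self.open_count, dtype=np.int64)
        n = len(self.state_names)
        if self.Q.shape != (n, n):
            raise ValueError(f"Q must be {n} x {n}, got {self.Q.shape}")
        if len(self.open_count) != n:
            raise ValueError("open_count must have one entry per state")
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("Q contains non-finite rates")
        off = self.Q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-9):
            raise ValueError("each row of Q must sum to 0")
        if not np.any(self.open_count == 0) or not np.any(self.open_count >= 1):
            raise ValueError("need at least one closed (0) and one open (>=1) state")
        if self.filter_cutoff is not None and not self.sample_rate > 2 * self.filter_cutoff:
            raise ValueError(
                f"sample_rate {self.sample_rate} must exceed twice the filter "
                f"cutoff {self.filter_cutoff}"
            )

    @property
    def n_states(self) -> int:
        return len(self.state_names)


def two_state_model(
    k_co: float = 50.0,
    k_oc: float = 100.0,
    unitary_current: float = -5.0,
    noise_sd: float = 1.0,
    filter_cutoff: float | None = 1000.0,
    sample_rate: float = 5000.0,
) -> GatingModel:
    """The default demo scheme: C <-> O with opening rate ``k_co`` and
    closing rate ``k_oc`` (defaults 50/s and 100/s, i.e. open probability
    1/3 and mean open time 10 ms).  A fixture choice, not a measured channel.
    """
    Q = np.array([[-k_co, k_co], [k_oc, -k_oc]])
    return GatingModel(
        state_names=["C", "O"],
        open_count=np.array([0, 1]),
        Q=Q,
        unitary_current=unitary_current,
        noise_sd=noise_sd,
        filter_cutoff=filter_cutoff,
        sample_rate=sample_rate,
    )


def equilibrium_distribution(model: GatingModel) -> np.ndarray:
    """Stationary distribution pi with ``pi Q = 0`` and ``sum(pi) = 1``.

    Raises if the chain is reducible, naming the disconnected states.
    """
    Q = model.Q
    n = model.n_states
    adj = (Q > 0) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(adj.astype(int), directed=True, connection="strong")
    if n_comp > 1:
        groups = [
            [model.state_names[i] for i in range(n) if labels[i] == c]
            for c in range(n_comp)
        ]
        raise ValueError(
            "rate matrix is reducible; states fall into disconnected groups: "
            + "; ".join("{" + ", ".join(g) + "}" for g in groups)
        )
    ns = linalg.null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError("rate matrix is defective: stationary space is not one-dimensional")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-12):
        raise ValueError("stationary solve produced negative probabilities")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def sample_trajectory(model: GatingModel, duration: float, seed: int = 0) -> PairedRecord:
    """Simulate ``duration`` seconds of labelled recording.

    Exact CTMC jump-chain simulation starting from the stationary
    distribution, snapped to the sample grid; the label row is the open
    count of the occupied state, the raw row is baseline + open_count x
    unitary_current + filtered Gaussian noise.  Identical seeds give
    identical records.
    """
    exit_rates = -np.diag(model.Q)
    if not np.all(np.isfinite(exit_rates)):
        raise ValueError("non-finite rates in Q")
    if duration < 10.0 / exit_rates.max():
        raise ValueError(
            f"duration {duration} s too short to contain events; need >= "
            f"{10.0 / exit_rates.max():.4g} s"
        )
    n_samples = int(round(duration * model.sample_rate))
    if n_samples > _MAX_SAMPLES:
        raise ValueError(f"{n_samples} samples exceeds addressable record length")

    rng = np.random.default_rng(seed)
    pi = equilibrium_distribution(model)
    state = int(rng.choice(model.n_states, p=pi))

    # jump chain: event times and states, until past the end of the record
    jump_times = [0.0]
    jump_states = [state]
    t = 0.0
    # transition probabilities out of each state
    n = model.n_states
    P = model.Q.copy()
    np.fill_diagonal(P, 0.0)
    with np.errstate(invalid="ignore"):
        P = P / P.sum(axis=1, keepdims=True)
    while t < duration:
        rate = exit_rates[state]
        if rate <= 0:  # absorbing state: stays forever
            break
        t += rng.exponential(1.0 / rate)
        state = int(rng.choice(n, p=P[state]))
        jump_times.append(t)
        jump_states.append(state)

    sample_times = np.arange(n_samples) / model.sample_rate
    idx = np.searchsorted(np.asarray(jump_times), sample_times, side="right") - 1
    states = np.asarray(jump_states)[idx]
    label = model.open_count[states]

    raw = model.baseline + label * model.unitary_current
    raw = raw.astype(float)
    if model.noise_sd > 0 and not model.noise_after_filter:
        raw = raw + rng.normal(0.0, model.noise_sd, size=n_samples)
    if model.filter_cutoff is not None:
        sos = signal.butter(4, model.filter_cutoff, fs=model.sample_rate, output="sos")
        raw = signal.sosfilt(sos, raw)
    if model.noise_sd > 0 and model.noise_after_filter:
        raw = raw + rng.normal(0.0, model.noise_sd, size=n_samples)

    meta = {
        "simulator": "ctmc-gillespie",
        "seed": seed,
        "duration_s": duration,
        "states": list(model.state_names),
    }
    return PairedRecord(raw, label, model.sample_rate, meta)
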
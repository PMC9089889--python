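"""Deep-convolutional GAN over paired (current, idealization) windows.

The generator maps a latent noise vector through a dense stack and three
transposed-convolution upsampling stages (LeakyReLU + batch normalisation
each, tanh output) to a 2 x W window; the discriminator downsamples with
strided convolutions (LeakyReLU, dropout 0.3 after every convolution except
the input one) to a single real/fake probability.  Both are trained
adversarially with logistic binary cross-entropy, the generator with the
non-saturating objective (maximise log D(fake)).

All randomness — weight init, latent draws, shuffling, dropout masks,
augmentation — descends from one seed, so training runs are reproducible
bit-for-bit on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .metrics import mmd, median_heuristic_bandwidth, dtw_approx
from .signal_io import (
    PairedRecord,
    ScalerParams,
    WindowBatch,
    crop_edges,
    inverse_scale,
    snap_labels,
)

__all__ = [
    "GanSpec", "TrainLog", "bce_loss", "discriminator_loss", "generator_loss",
    "build_generator", "build_discriminator", "train", "generate",
    "decode_labels", "save_checkpoint", "load_checkpoint",
]

_EPS = 1e-7


@dataclass
class GanSpec:
    """Architecture and training hyperparameters.

    ``window_length`` must be divisible by 8 (three stride-2 stages).
    ``latent_shape`` is "vector" (compact latent of ``latent_dim``, the
    default) or "image" (a flattened ``rows x window_length`` noise field).
    """

    window_length: int = 1280
    rows: int = 2
    latent_dim: int = 128
    latent_shape: str = "vector"
    base_channels: int = 16
    learning_rate: float = 1e-4
    adam_beta1: float = 0.5
    batch_size: int = 64
    epochs: int = 200
    dropout: float = 0.3
    leaky_alpha: float = 0.2
    augment_noise_fraction: float = 0.001
    d_steps: int = 1
    g_steps: int = 1
    eval_interval: int = 10
    checkpoint_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length % 8 != 0:
            raise ValueError("window_length must be divisible by 8")
        if self.latent_shape not in ("vector", "image"):
            raise ValueError("latent_shape must be 'vector' or 'image'")

    @property
    def latent_size(self) -> int:
        if self.latent_shape == "image":
            return self.rows * self.window_length
        return self.latent_dim

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GanSpec":
        return cls(**d)


@dataclass
class TrainLog:
    """Per-epoch loss history plus interval fidelity evaluations."""

    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    eval_epochs: list[int] = field(default_factory=list)
    eval_mmd: list[float] = field(default_factory=list)
    eval_dtw: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    best_mmd: float | None = None
    checkpoints: dict = field(default_factory=dict)
    aborted: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_loss(y, p) -> float:
    """Mean logistic binary cross-entropy, ``-[y log p + (1-y) log(1-p)]``.

    Probabilities are clipped to ``[1e-7, 1 - 1e-7]`` first.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def discriminator_loss(real_preds, fake_preds) -> float:
    """BCE against 1 on real predictions plus BCE against 0 on fakes."""
    return bce_loss(np.ones_like(np.asarray(real_preds, float)), real_preds) + \
        bce_loss(np.zeros_like(np.asarray(fake_preds, float)), fake_preds)


def generator_loss(fake_preds) -> float:
    """Non-saturating generator objective: BCE of fakes against 1."""
    return bce_loss(np.ones_like(np.asarray(fake_preds, float)), fake_preds)


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def build_generator(spec: GanSpec, rng: np.random.Generator) -> nn.Sequential:
    W8 = spec.window_length // 8
    c0 = 4 * spec.base_channels
    layers: list[nn.Layer] = [
        nn.Dense(spec.latent_size, c0 * W8, rng),
        nn.BatchNorm(c0 * W8),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.Reshape((c0, W8)),
        nn.ConvTranspose1d(c0, 2 * spec.base_channels, rng),
        nn.BatchNorm(2 * spec.base_channels),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.ConvTranspose1d(2 * spec.base_channels, spec.base_channels, rng),
        nn.BatchNorm(spec.base_channels),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.ConvTranspose1d(spec.base_channels, spec.rows, rng),
        nn.Tanh(),
    ]
    return nn.Sequential(layers)


def build_discriminator(spec: GanSpec, rng: np.random.Generator,
                        dropout_rng: np.random.Generator) -> nn.Sequential:
    bc = spec.base_channels
    W8 = spec.window_length // 8
    layers: list[nn.Layer] = [
        nn.Conv1d(spec.rows, bc, rng),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.Conv1d(bc, 2 * bc, rng),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.Dropout(spec.dropout, dropout_rng),
        nn.Conv1d(2 * bc, 4 * bc, rng),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.Dropout(spec.dropout, dropout_rng),
        nn.Flatten(),
        nn.Dense(4 * bc * W8, 1, rng),
    ]
    return nn.Sequential(layers)  # outputs a logit; sigmoid applied at the loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    batch_source: WindowBatch,
    spec: GanSpec,
    out_dir: str | Path | None = None,
    eval_windows: np.ndarray | None = None,
    eval_dtw_pairs: int = 8,
    resume_from: str | Path | None = None,
) -> TrainLog:
    """Adversarial training loop: one discriminator and one generator update
    per minibatch (ratios configurable via ``d_steps``/``g_steps``).

    ``eval_windows`` (held-out real windows, N x rows x W) enables interval
    MMD/DTW evaluation; the minimum-MMD epoch is checkpointed as ``best``
    when ``out_dir`` is given, alongside periodic ``latest`` checkpoints.
    Returns the :class:`TrainLog`.
    """
    data = np.asarray(batch_source.data, dtype=float)
    if len(data) == 0:
        raise ValueError("empty batch source")
    if len(data) < 2 * spec.batch_size:
        raise ValueError(
            f"need >= {2 * spec.batch_size} windows (2 x batch_size), have {len(data)}"
        )
    if data.shape[1] != spec.rows or data.shape[2] != spec.window_length:
        raise ValueError(
            f"data shape {data.shape[1:]} does not match spec "
            f"({spec.rows} x {spec.window_length})"
        )

    ss = np.random.SeedSequence(spec.seed)
    init_rng, drop_rng, loop_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    if resume_from is not None:
        G, D, _, _, opt_state = load_checkpoint(resume_from, with_optimizer=True)
    else:
        G = build_generator(spec, init_rng)
        D = build_discriminator(spec, init_rng, drop_rng)
        opt_state = None
    opt_g = nn.Adam(G.params(), lr=spec.learning_rate, beta1=spec.adam_beta1)
    opt_d = nn.Adam(D.params(), lr=spec.learning_rate, beta1=spec.adam_beta1)
    if opt_state is not None:
        opt_g.load_state(opt_state["g"])
        opt_d.load_state(opt_state["d"])
    if resume_from is not None:
        # a resumed discriminator needs its dropout source re-attached
        for layer in D.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = drop_rng

    log = TrainLog()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    n = len(data)
    bs = spec.batch_size
    bw_cache: float | None = None

    def _save(tag: str) -> None:
        if out_dir is None:
            return
        path = out_dir / tag
        save_checkpoint(path, G, D, spec, batch_source.scaler,
                        optimizer_state={"g": opt_g.state(), "d": opt_d.state()})
        log.checkpoints[tag] = str(path)

    for epoch in range(spec.epochs):
        order = loop_rng.permutation(n)
        epoch_data = data[order]
        if spec.augment_noise_fraction > 0:
            ptp = float(np.ptp(epoch_data[:, 0, :]))
            epoch_data = epoch_data.copy()
            epoch_data[:, 0, :] += loop_rng.normal(
                0.0, spec.augment_noise_fraction * ptp, size=epoch_data[:, 0, :].shape
            )
        d_losses, g_losses = [], []
        for start in range(0, n - bs + 1, bs):
            real = epoch_data[start : start + bs]

            for _ in range(spec.d_steps):
                z = loop_rng.standard_normal((bs, spec.latent_size))
                fake = G.forward(z, training=True)
                D.zero_grad()
                logit_r = D.forward(real, training=True)
                p_r = _sigmoid(logit_r)
                D.backward((p_r - 1.0) / bs)
                logit_f = D.forward(fake, training=True)
                p_f = _sigmoid(logit_f)
                D.backward(p_f / bs)
                opt_d.step()
                d_losses.append(discriminator_loss(p_r.ravel(), p_f.ravel()))

            for _ in range(spec.g_steps):
                z = loop_rng.standard_normal((bs, spec.latent_size))
                G.zero_grad()
                fake = G.forward(z, training=True)
                D.zero_grad()
                logit_f = D.forward(fake, training=True)
                p_f = _sigmoid(logit_f)
                dfake = D.backward((p_f - 1.0) / bs)
                D.zero_grad()  # generator step must not touch D parameters
                G.backward(dfake)
                opt_g.step()
                g_losses.append(generator_loss(p_f.ravel()))

        d_mean = float(np.mean(d_losses))
        g_mean = float(np.mean(g_losses))
        if not (np.isfinite(d_mean) and np.isfinite(g_mean)):
            log.aborted = True
            break
        log.d_loss.append(d_mean)
        log.g_loss.append(g_mean)

        last = epoch == spec.epochs - 1
        if eval_windows is not None and (
            (epoch + 1) % spec.eval_interval == 0 or last
        ):
            z = np.random.default_rng(spec.seed + 10_000 + epoch).standard_normal(
                (len(eval_windows), spec.latent_size)
            )
            gen = G.forward(z, training=False)
            Xf = np.asarray(eval_windows).reshape(len(eval_windows), -1)
            Yf = gen.reshape(len(gen), -1)
            if bw_cache is None:
                bw_cache = median_heuristic_bandwidth(Xf, Xf)
            m = mmd(Xf, Yf, bw_cache)
            k = min(eval_dtw_pairs, len(gen), len(eval_windows))
            dtws = [
                dtw_approx(eval_windows[i][0], gen[i][0], radius=1)
                for i in range(k)
            ]
            log.eval_epochs.append(epoch + 1)
            log.eval_mmd.append(float(m))
            log.eval_dtw.append(float(np.mean(dtws)))
            if log.best_mmd is None or m < log.best_mmd:
                log.best_mmd = float(m)
                log.best_epoch = epoch + 1
                _save("best")
        if (epoch + 1) % spec.checkpoint_interval == 0 or last:
            _save("latest")

    if out_dir is not None:
        (out_dir / "train_log.json").write_text(json.dumps(log.to_dict(), indent=2))
    log._generator = G  # type: ignore[attr-defined]  # in-memory handle
    log._discriminator = D  # type: ignore[attr-defined]
    return log


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, G: nn.Sequential, D: nn.Sequential,
                    spec: GanSpec, scaler: ScalerParams,
                    optimizer_state: dict | None = None) -> None:
    """Write parameter arrays + spec + scaler to a checkpoint directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, p in enumerate(G.params()):
        arrays[f"g_{i}"] = p.value
    for i, p in enumerate(D.params()):
        arrays[f"d_{i}"] = p.value
    for net, tag in ((G, "g"), (D, "d")):
        bn = [l for l in net.layers if isinstance(l, nn.BatchNorm)]
        for j, layer in enumerate(bn):
            arrays[f"{tag}_bn{j}_mean"] = layer.run_mean
            arrays[f"{tag}_bn{j}_var"] = layer.run_var
    if optimizer_state is not None:
        for tag in ("g", "d"):
            st = optimizer_state[tag]
            for i, (m, v) in enumerate(zip(st["m"], st["v"])):
                arrays[f"opt_{tag}_m_{i}"] = m
                arrays[f"opt_{tag}_v_{i}"] = v
            arrays[f"opt_{tag}_t"] = np.array(st["t"])
    np.savez(path / "params.npz", **arrays)
    (path / "spec.json").write_text(json.dumps(spec.to_dict(), indent=2))
    (path / "scaler.json").write_text(json.dumps(scaler.to_dict(), indent=2))


def load_checkpoint(path: str | Path, with_optimizer: bool = False):
    """Rebuild generator and discriminator from a checkpoint directory.

    Returns ``(G, D, spec, scaler)`` or, with ``with_optimizer``,
    ``(G, D, spec, scaler, optimizer_state)``.
    """
    path = Path(path)
    spec = GanSpec.from_dict(json.loads((path / "spec.json").read_text()))
    scaler = ScalerParams.from_dict(json.loads((path / "scaler.json").read_text()))
    rng = np.random.default_rng(0)
    G = build_generator(spec, rng)
    D = build_discriminator(spec, rng, np.random.default_rng(0))
    with np.load(path / "params.npz") as arrays:
        for i, p in enumerate(G.params()):
            saved = arrays[f"g_{i}"]
            if saved.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint/spec shape mismatch for generator param {i}: "
                    f"{saved.shape} vs {p.value.shape}"
                )
            p.value[...] = saved
        for i, p in enumerate(D.params()):
            saved = arrays[f"d_{i}"]
            if saved.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint/spec shape mismatch for discriminator param {i}: "
                    f"{saved.shape} vs {p.value.shape}"
                )
            p.value[...] = saved
        for net, tag in ((G, "g"), (D, "d")):
            bn = [l for l in net.layers if isinstance(l, nn.BatchNorm)]
            for j, layer in enumerate(bn):
                layer.run_mean = arrays[f"{tag}_bn{j}_mean"].copy()
                layer.run_var = arrays[f"{tag}_bn{j}_var"].copy()
        if with_optimizer:
            opt_state = {}
            for tag, net in (("g", G), ("d", D)):
                n_params = len(net.params())
                opt_state[tag] = {
                    "m": [arrays[f"opt_{tag}_m_{i}"].copy() for i in range(n_params)],
                    "v": [arrays[f"opt_{tag}_v_{i}"].copy() for i in range(n_params)],
                    "t": int(arrays[f"opt_{tag}_t"]),
                }
            return G, D, spec, scaler, opt_state
    return G, D, spec, scaler


# ---------------------------------------------------------------------------
# generation and decoding
# ---------------------------------------------------------------------------

def generate(
    checkpoint: str | Path | nn.Sequential,
    n_windows: int,
    seed: int = 0,
    spec: GanSpec | None = None,
    scaler: ScalerParams | None = None,
) -> WindowBatch:
    """Draw ``n_windows`` scaled windows from a trained generator.

    ``checkpoint`` may be a checkpoint directory or an in-memory generator
    (then ``spec`` and ``scaler`` are required).  Deterministic given
    (checkpoint, seed); outputs lie in the tanh range [-1, 1].
    """
    if isinstance(checkpoint, nn.Sequential):
        if spec is None or scaler is None:
            raise ValueError("spec and scaler required with an in-memory generator")
        G = checkpoint
    else:
        G, _, spec, scaler = load_checkpoint(checkpoint)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_windows, spec.latent_size))
    out = G.forward(z, training=False)
    return WindowBatch(out, spec.window_length, spec.window_length, scaler,
                       source="generated")


def decode_labels(
    batch: WindowBatch,
    scaler: ScalerParams | None = None,
    sample_rate: float = 5000.0,
    crop_fraction: float = 0.05,
) -> list[PairedRecord]:
    """Decode generated windows into physical-unit labelled records.

    The current row is inverse-scaled to pA; the continuous label row is
    snapped to the nearest level recorded in the scaler (ties to the lower
    level); window edges are cropped to drop upsampling artefacts.
    """
    scaler = scaler or batch.scaler
    records = []
    for win in batch.data:
        win = crop_edges(win, crop_fraction)
        raw, label_f = inverse_scale(win, scaler)
        label = snap_labels(label_f, scaler.label_levels)
        records.append(
            PairedRecord(raw, label, sample_rate, meta={"source": batch.source})
        )
    return records
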
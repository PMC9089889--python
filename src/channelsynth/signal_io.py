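"""Paired-record I/O, robust scaling, windowing, augmentation and edge cropping.

The currency of the whole pipeline is the :class:`PairedRecord`: a raw
current trace in pA and a perfectly synchronised integer idealization row
(number of open channels at each sample).  This module turns records into
the scaled ``N x 2 x W`` window batches the generative model trains on, and
back again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PairedRecord",
    "ScalerParams",
    "WindowBatch",
    "read_record",
    "write_record",
    "robust_scale",
    "inverse_scale",
    "snap_labels",
    "make_windows",
    "augment",
    "crop_edges",
]

CSV_HEADER = "time_index,current_pA,label"
_SAMPLE_RATE_KEY = "sample_rate_hz"


@dataclass
class PairedRecord:
    """A raw current trace with its sample-synchronous idealization.

    Parameters
    ----------
    raw
        Current in pA, one value per sample.
    label
        Open-channel count per sample (0 = all closed).
    sample_rate
        Sampling rate in Hz.
    meta
        Free-form provenance mapping (model parameters, seeds, ...).
    """

    raw: np.ndarray
    label: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.label = np.asarray(self.label)
        if self.raw.ndim != 1 or self.label.ndim != 1:
            raise ValueError("raw and label must be one-dimensional")
        if len(self.raw) != len(self.label):
            raise ValueError(
                f"raw and label lengths differ: {len(self.raw)} vs {len(self.label)}"
            )
        if not np.issubdtype(self.label.dtype, np.integer):
            rounded = np.rint(self.label)
            if not np.allclose(self.label, rounded, atol=1e-9):
                raise ValueError("label row must be integer-valued")
            self.label = rounded.astype(np.int64)
        else:
            self.label = self.label.astype(np.int64)
        if np.any(self.label < 0):
            raise ValueError("label values must be >= 0 (open-channel counts)")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.raw) / self.sample_rate


@dataclass
class ScalerParams:
    """Per-row scaling parameters: robust (median/IQR) for the current row,
    affine min/max-to-[-1, 1] for the label row.

    ``degenerate_label`` flags a record with a single label level, which is
    mapped to the constant -1.
    """

    center: float
    scale: float
    label_levels: list[int]
    degenerate_label: bool = False

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("raw-row scale (IQR) must be > 0")
        if not self.label_levels:
            raise ValueError("label_levels must be non-empty")
        self.label_levels = sorted(int(v) for v in self.label_levels)

    def to_dict(self) -> dict:
        return {
            "center": float(self.center),
            "scale": float(self.scale),
            "label_levels": list(self.label_levels),
            "degenerate_label": bool(self.degenerate_label),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            center=d["center"],
            scale=d["scale"],
            label_levels=d["label_levels"],
            degenerate_label=d.get("degenerate_label", False),
        )


@dataclass
class WindowBatch:
    """A batch of scaled ``2 x W`` windows (row 0 = current, row 1 = label)."""

    data: np.ndarray  # N x 2 x W
    window_length: int
    stride: int
    scaler: ScalerParams
    source: str = "real"  # "real" | "generated"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError(f"data must be N x 2 x W, got shape {self.data.shape}")
        if self.data.shape[2] != self.window_length:
            raise ValueError(
                f"window_length {self.window_length} does not match data width "
                f"{self.data.shape[2]}"
            )
        if self.source not in ("real", "generated"):
            raise ValueError("source must be 'real' or 'generated'")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_record(record: PairedRecord, path: str | Path, fmt: str | None = None) -> None:
    """Write a record to CSV (with a sample-rate comment line) or HDF5.

    Format is inferred from the extension when ``fmt`` is None
    (``.csv`` -> csv, ``.h5``/``.hdf5`` -> hdf5).
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        lines = [f"# {_SAMPLE_RATE_KEY}={float(record.sample_rate)!r}", CSV_HEADER]
        for i, (c, l) in enumerate(zip(record.raw, record.label)):
            lines.append(f"{i},{float(c)!r},{int(l)}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("current_pA", data=record.raw)
            f.create_dataset("label", data=record.label)
            f.attrs["sample_rate"] = record.sample_rate
            f.attrs["meta"] = json.dumps(record.meta, default=str)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'hdf5')")


def read_record(path: str | Path, fmt: str | None = None) -> PairedRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        sample_rate = None
        raw: list[float] = []
        label: list[int] = []
        with open(path) as f:
            header_seen = False
            for line in f:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ")
                    if body.startswith(_SAMPLE_RATE_KEY):
                        sample_rate = float(body.split("=", 1)[1])
                    continue
                if not header_seen:
                    cols = [c.strip() for c in line.split(",")]
                    if "current_pA" not in cols or "label" not in cols:
                        raise ValueError(
                            f"CSV header must name current_pA and label columns, got {cols}"
                        )
                    i_cur, i_lab = cols.index("current_pA"), cols.index("label")
                    header_seen = True
                    continue
                fields = line.split(",")
                if len(fields) <= max(i_cur, i_lab):
                    raise ValueError(
                        f"row has {len(fields)} fields, expected at least "
                        f"{max(i_cur, i_lab) + 1}: {line!r}"
                    )
                raw.append(float(fields[i_cur]))
                label.append(int(fields[i_lab]))
        if not header_seen:
            raise ValueError(f"{path}: no header row found")
        if sample_rate is None:
            raise ValueError(
                f"{path}: missing '# {_SAMPLE_RATE_KEY}=' comment line"
            )
        return PairedRecord(np.array(raw), np.array(label), sample_rate)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if "current_pA" not in f or "label" not in f:
                raise ValueError(f"{path}: needs 'current_pA' and 'label' datasets")
            if "sample_rate" not in f.attrs:
                raise ValueError(f"{path}: missing 'sample_rate' attribute")
            raw = f["current_pA"][:]
            label = f["label"][:]
            sample_rate = float(f.attrs["sample_rate"])
            meta = json.loads(f.attrs.get("meta", "{}"))
        if len(raw) != len(label):
            raise ValueError(
                f"{path}: current row has {len(raw)} samples but label row {len(label)}"
            )
        return PairedRecord(raw, label, sample_rate, meta)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'hdf5')")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer format from extension {suffix!r}")


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def robust_scale(record: PairedRecord) -> tuple[np.ndarray, ScalerParams]:
    """Scale a record into the generator's tanh range.

    The current row is robust-scaled, ``(x - median) / IQR``; the label row
    is mapped affinely so the lowest level present sits at -1 and the highest
    at +1.  Returns the scaled ``2 x L`` array and the parameters needed to
    invert the transform exactly.
    """
    q25, q75 = np.percentile(record.raw, [25, 75])
    center = float(np.median(record.raw))
    scale = float(q75 - q25)
    if scale <= 0:
        raise ValueError("raw row has zero interquartile range; cannot robust-scale")
    levels = sorted(int(v) for v in np.unique(record.label))
    degenerate = len(levels) == 1
    scaled_raw = (record.raw - center) / scale
    scaled_label = _encode_labels(record.label, levels)
    params = ScalerParams(center, scale, levels, degenerate_label=degenerate)
    return np.stack([scaled_raw, scaled_label]), params


def _encode_labels(label: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    lo, hi = levels[0], levels[-1]
    if hi == lo:
        return np.full(len(label), -1.0)
    return -1.0 + 2.0 * (label - lo) / (hi - lo)


def inverse_scale(scaled: np.ndarray, params: ScalerParams) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`robust_scale`; returns ``(raw_pA, label_float)``.

    The label row comes back on its original integer scale but as floats;
    use :func:`snap_labels` to discretise generated output.
    """
    scaled = np.asarray(scaled, dtype=float)
    if scaled.ndim != 2 or scaled.shape[0] != 2:
        raise ValueError(f"expected a 2 x L array, got shape {scaled.shape}")
    raw = scaled[0] * params.scale + params.center
    lo, hi = params.label_levels[0], params.label_levels[-1]
    if hi == lo:
        label = np.full(scaled.shape[1], float(lo))
    else:
        label = lo + (scaled[1] + 1.0) * (hi - lo) / 2.0
    return raw, label


def snap_labels(label_float: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    """Snap continuous label values to the nearest recorded level.

    Exact midpoints resolve to the lower level, so a generator output of
    0 with levels {0, 1} decodes as closed rather than open.
    """
    levels_arr = np.asarray(sorted(levels), dtype=float)
    vals = np.asarray(label_float, dtype=float)
    dists = np.abs(vals[..., None] - levels_arr)
    # argmin takes the first (lower) level on ties
    idx = np.argmin(dists, axis=-1)
    return levels_arr[idx].astype(np.int64)


# ---------------------------------------------------------------------------
# windowing, augmentation, cropping
# ---------------------------------------------------------------------------

def make_windows(
    record: PairedRecord,
    window_length: int = 1280,
    stride: int | None = None,
    scaler: ScalerParams | None = None,
    source: str = "real",
) -> WindowBatch:
    """Cut a record into contiguous scaled ``2 x W`` windows.

    ``N = floor((L - W) / stride) + 1`` windows are produced; nothing is
    ever padded.  By default ``stride = W`` (non-overlapping).  An external
    ``scaler`` may be supplied to scale several records commensurately.
    """
    W = int(window_length)
    stride = W if stride is None else int(stride)
    L = len(record)
    if L < W:
        raise ValueError(f"record length {L} is shorter than window length {W}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if scaler is None:
        scaled, scaler = robust_scale(record)
    else:
        scaled = np.stack(
            [
                (record.raw - scaler.center) / scaler.scale,
                _encode_labels(record.label, scaler.label_levels),
            ]
        )
    n = (L - W) // stride + 1
    starts = np.arange(n) * stride
    data = np.stack([scaled[:, s : s + W] for s in starts])
    return WindowBatch(data, W, stride, scaler, source=source)


def augment(batch: WindowBatch, noise_fraction: float = 0.001, seed: int = 0) -> WindowBatch:
    """Copy a batch, perturbing the current row with faint Gaussian noise.

    The noise SD is ``noise_fraction`` of the peak-to-peak amplitude of the
    scaled current row over the whole batch (default 0.1%, visually
    invisible).  The label row is left untouched.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    data = batch.data.copy()
    if noise_fraction > 0 and batch.n_windows > 0:
        rng = np.random.default_rng(seed)
        ptp = float(np.ptp(data[:, 0, :]))
        data[:, 0, :] += rng.normal(0.0, noise_fraction * ptp, size=data[:, 0, :].shape)
    return WindowBatch(data, batch.window_length, batch.stride, batch.scaler, batch.source)


def crop_edges(window: np.ndarray, crop_fraction: float = 0.05) -> np.ndarray:
    """Trim ``crop_fraction`` of the samples off each end of the last axis.

    Generated windows carry boundary artefacts from the transposed
    convolutions; analyses and exports crop them off first.
    """
    if not 0 <= crop_fraction < 0.5:
        raise ValueError(f"crop_fraction must be in [0, 0.5), got {crop_fraction}")
    window = np.asarray(window)
    W = window.shape[-1]
    k = int(crop_fraction * W)
    if k == 0:
        return window.copy()
    return window[..., k : W - k].copy()
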
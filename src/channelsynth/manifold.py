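"""Manifold projection of windowed records and a cluster-separation test.

Real and generated windows are embedded *jointly* (never per group) into
two dimensions with t-SNE or UMAP, and the question "are the two clouds
distinguishable?" is answered with a permutation test: the observed
statistic is the out-of-fold accuracy of a linear separator on the 2-D
coordinates, the null is built by shuffling the group labels at least 1000
times, and the p-value uses the add-one rule, so the smallest attainable
p is ``1 / (1 + n_permutations)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import WindowBatch

__all__ = ["EmbeddingResult", "ClusterTestResult", "embed", "cluster_separation_test"]


@dataclass
class EmbeddingResult:
    """Joint 2-D embedding of two window groups."""

    coords: np.ndarray          # P x 2
    group: np.ndarray           # P group ids (0 / 1) or names
    method: str
    seed: int
    window_length: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.group = np.asarray(self.group)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be P x 2, got {self.coords.shape}")
        if len(self.group) != len(self.coords):
            raise ValueError("one group label per embedded point required")


@dataclass
class ClusterTestResult:
    """Permutation cluster-separation test outcome."""

    statistic: float
    null_stats: np.ndarray
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def _window_matrix(batch: WindowBatch | np.ndarray, use_label_row: bool) -> np.ndarray:
    data = batch.data if isinstance(batch, WindowBatch) else np.asarray(batch, float)
    if data.ndim != 3:
        raise ValueError(f"expected N x 2 x W windows, got shape {data.shape}")
    if use_label_row:
        return data.reshape(len(data), -1)
    return data[:, 0, :]


def embed(
    group_a: WindowBatch | np.ndarray,
    group_b: WindowBatch | np.ndarray,
    method: str = "umap",
    seed: int = 0,
    use_label_row: bool = False,
    n_neighbors: int = 15,
    perplexity: float = 30.0,
) -> EmbeddingResult:
    """Jointly embed two identically-windowed datasets into 2-D.

    By default only the current row enters the projection; set
    ``use_label_row`` to feed flattened 2-row windows.  Both groups are
    concatenated and projected together so the embedding is shared.
    """
    Xa = _window_matrix(group_a, use_label_row)
    Xb = _window_matrix(group_b, use_label_row)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(
            f"groups must be windowed identically: widths {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    if len(Xa) < 10 or len(Xb) < 10:
        raise ValueError(
            f"need >= 10 windows per group, got {len(Xa)} and {len(Xb)}"
        )
    X = np.vstack([Xa, Xb])
    group = np.concatenate([np.zeros(len(Xa), int), np.ones(len(Xb), int)])

    if method == "tsne":
        from sklearn.manifold import TSNE

        perp = min(perplexity, (len(X) - 1) / 3.0)
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perp, init="pca"
        ).fit_transform(X)
    elif method == "umap":
        import umap

        nn = min(n_neighbors, len(X) - 1)
        coords = umap.UMAP(
            n_components=2, random_state=seed, n_neighbors=nn
        ).fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r}; use 'tsne' or 'umap'")

    W = Xa.shape[1] if not use_label_row else Xa.shape[1] // 2
    return EmbeddingResult(np.asarray(coords, float), group, method, seed, W)


# ---------------------------------------------------------------------------
# permutation cluster-separation test
# ---------------------------------------------------------------------------

def _lda_fold_accuracy(coords: np.ndarray, y: np.ndarray, n_folds: int,
                       rng: np.random.Generator) -> float:
    """Mean out-of-fold accuracy of a closed-form linear discriminant."""
    P = len(y)
    order = rng.permutation(P)
    folds = np.array_split(order, n_folds)
    correct = 0
    for f in folds:
        mask = np.ones(P, dtype=bool)
        mask[f] = False
        ytr, Xtr = y[mask], coords[mask]
        if ytr.min() == ytr.max():  # one-class training fold: predict that class
            correct += int(np.sum(y[f] == ytr[0]))
            continue
        mu0 = Xtr[ytr == 0].mean(axis=0)
        mu1 = Xtr[ytr == 1].mean(axis=0)
        Xc = np.vstack([Xtr[ytr == 0] - mu0, Xtr[ytr == 1] - mu1])
        cov = Xc.T @ Xc / max(len(Xc) - 2, 1) + 1e-9 * np.eye(coords.shape[1])
        w = np.linalg.solve(cov, mu1 - mu0)
        thresh = w @ (mu0 + mu1) / 2.0
        pred = (coords[f] @ w > thresh).astype(int)
        correct += int(np.sum(pred == y[f]))
    return correct / P


def cluster_separation_test(
    emb: EmbeddingResult,
    n_permutations: int = 1000,
    seed: int = 0,
    n_folds: int = 5,
) -> ClusterTestResult:
    """Test whether the two embedded groups form separable clusters.

    Observed statistic: mean out-of-fold accuracy of a linear separator on
    the 2-D coordinates (seeded ``n_folds``-fold split).  The null
    distribution shuffles the group labels ``n_permutations`` times
    (>= 1000 by default) and recomputes; the p-value is
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    groups = np.unique(emb.group)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    y = (emb.group == groups[1]).astype(int)
    coords = emb.coords

    if np.allclose(coords, coords[0]):  # degenerate cloud: nothing separates
        return ClusterTestResult(0.5, np.full(n_permutations, 0.5), 1.0, n_permutations)

    rng = np.random.default_rng(seed)
    observed = _lda_fold_accuracy(coords, y, n_folds, rng)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yb = rng.permutation(y)
        null[b] = _lda_fold_accuracy(coords, yb, n_folds, rng)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return ClusterTestResult(float(observed), null, float(p), n_permutations)
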
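"""Synthetic connectomes, datasets and fixtures.

Everything downstream — LEiDA, model fitting, in-silico stimulation — is
exercised on data generated here: modular bilateral connectomes, multi-
subject BOLD-like datasets produced by the Hopf model itself (with the
generating parameters recorded for recovery experiments), planted
eigenvector clusters, and Markov label chains.  The generators emulate the
model's own statistical structure only; they make no attempt to mimic
acquisition artifacts (motion, physiological noise, drift).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import RegionalTimeSeries, spawn_seeds
from .hopf import HopfParams, simulate

__all__ = [
    "Connectome",
    "generate_connectome",
    "generate_state_dataset",
    "generate_eigenvector_clusters",
    "generate_markov_labels",
]


@dataclass
class Connectome:
    """Symmetric non-negative coupling matrix with a homotopic-pair table.

    ``homotopic_pairs`` lists (left, right) index pairs — the bilateral
    stimulation scheme needs them declared explicitly.  The off-diagonal
    mean equals ``mean_weight`` (default 0.2, the working scale of the
    coupled model) to machine precision.
    """

    weights: np.ndarray
    region_names: list[str]
    homotopic_pairs: list[tuple[int, int]] | None = None
    mean_weight: float = 0.2
    name: str = "connectome"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.max(np.abs(w - w.T)) > 1e-9:
            raise ValueError("weights must be symmetric (tolerance 1e-9)")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if len(self.region_names) != w.shape[0]:
            raise ValueError("region_names length must match matrix size")
        if self.homotopic_pairs is not None:
            seen = [i for p in self.homotopic_pairs for i in p]
            if sorted(seen) != list(range(w.shape[0])):
                raise ValueError(
                    "homotopic pairs must partition the regions: every region "
                    "in exactly one (left, right) pair"
                )
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def offdiag_mean(self) -> float:
        n = self.n_regions
        off = ~np.eye(n, dtype=bool)
        return float(self.weights[off].mean())


def _normalize_mean(w: np.ndarray, mean_weight: float) -> np.ndarray:
    off = ~np.eye(w.shape[0], dtype=bool)
    m = w[off].mean()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    return w * (mean_weight / m)


def generate_connectome(
    n_regions: int,
    n_modules: int = 2,
    homotopic_strength: float = 1.0,
    seed: int = 0,
    mean_weight: float = 0.2,
) -> Connectome:
    """Modular bilateral connectome, normalized to a given off-diagonal mean.

    Regions 0..N/2-1 form the left hemisphere, N/2..N-1 the right; region i
    pairs with i + N/2.  Each hemisphere is split into ``n_modules``
    contiguous modules (mirrored across hemispheres): within-module
    connections are strong, between-module connections weak, and each
    homotopic pair receives an extra edge of relative strength
    ``homotopic_strength``.  Weights carry multiplicative jitter from
    ``seed`` and the whole matrix is rescaled so the off-diagonal mean is
    exactly ``mean_weight``.
    """
    if n_regions < 4:
        raise ValueError("n_regions must be >= 4")
    if n_regions % 2 != 0:
        raise ValueError(
            "n_regions must be even: bilateral stimulation requires every "
            "region to belong to exactly one left/right homotopic pair"
        )
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    half = n_regions // 2
    if n_modules > half:
        raise ValueError("n_modules cannot exceed regions per hemisphere")
    rng = np.random.default_rng(seed)

    module = np.empty(n_regions, dtype=int)
    for i in range(half):
        module[i] = module[i + half] = i * n_modules // half

    base = np.where(module[:, None] == module[None, :], 1.0, 0.15)
    jitter = rng.uniform(0.5, 1.5, size=(n_regions, n_regions))
    w = base * jitter
    w = 0.5 * (w + w.T)
    pairs = [(i, i + half) for i in range(half)]
    for left, right in pairs:
        w[left, right] += homotopic_strength
        w[right, left] = w[left, right]
    np.fill_diagonal(w, 0.0)
    w = _normalize_mean(w, mean_weight)

    names = [f"L{i + 1:02d}" for i in range(half)] + [
        f"R{i + 1:02d}" for i in range(half)
    ]
    return Connectome(
        weights=w,
        region_names=names,
        homotopic_pairs=pairs,
        mean_weight=mean_weight,
        name=f"synthetic-N{n_regions}-m{n_modules}-s{seed}",
    )


def generate_state_dataset(
    connectome: Connectome,
    params: HopfParams,
    n_subjects: int,
    duration_s: float,
    tr_s: float,
    seed: int,
    condition: str = "synthetic",
) -> tuple[list[RegionalTimeSeries], dict]:
    """Multi-subject dataset simulated from the Hopf model on a connectome.

    Each subject is an independent realization (its own noise stream,
    derived from ``seed``).  The ground-truth record stores the generating
    parameters so recovery experiments never re-derive them from file
    names.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = replace(params, tr_s=float(tr_s))
    n_samples = int(np.floor((duration_s - params.transient_s) / tr_s))
    if n_samples < 50:
        raise ValueError(
            f"only {n_samples} samples after transient; need >= 50 "
            "(increase duration_s or decrease tr_s)"
        )
    subject_seeds = spawn_seeds(seed, n_subjects)
    dataset = []
    for i, s in enumerate(subject_seeds):
        res = simulate(connectome, params, duration_s, s)
        ts = RegionalTimeSeries(
            res.series.values,
            tr_s=tr_s,
            subject_id=f"sub-{i:02d}",
            condition=condition,
        )
        dataset.append(ts)
    ground_truth = {
        "G": float(params.G),
        "a": params.a.tolist(),
        "omega": params.omega.tolist(),
        "beta": float(params.beta),
        "dt_s": float(params.dt_s),
        "tr_s": float(tr_s),
        "transient_s": float(params.transient_s),
        "duration_s": float(duration_s),
        "seed": int(seed),
        "subject_seeds": subject_seeds,
        "connectome": connectome.name,
        "condition": condition,
    }
    return dataset, ground_truth


def generate_eigenvector_clusters(
    k: int,
    n_regions: int,
    n_samples: int,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors drawn around k well-separated directions, with labels.

    Cluster centers are mutually orthogonal random directions (flipped to
    the majority-negative sign convention); each sample is the normalized
    sum of ``separation`` times its center plus isotropic Gaussian noise,
    so larger ``separation`` gives tighter clusters.  Every cluster receives
    at least one sample when ``n_samples >= k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_regions:
        raise ValueError("k cannot exceed n_regions (orthogonal centers)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_regions, k))
    q, _ = np.linalg.qr(raw)
    centers = q.T[:k]
    for c in centers:
        n_neg, n_pos = (c < 0).sum(), (c > 0).sum()
        if n_pos > n_neg or (n_pos == n_neg and c[np.argmax(np.abs(c))] > 0):
            c *= -1.0
    labels = np.arange(n_samples) % k
    rng.shuffle(labels)
    noise = rng.standard_normal((n_samples, n_regions))
    vectors = separation * centers[labels] + noise
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return vectors, labels


def generate_markov_labels(tpm, length: int, seed: int = 0) -> np.ndarray:
    """Sample a label sequence from a Markov chain started at stationarity.

    ``tpm`` must be row-stochastic.  The initial state is drawn from a
    stationary distribution obtained by power iteration from uniform (for a
    reducible chain, e.g. the identity, this is the uniform-mixture
    stationary point).
    """
    P = np.asarray(tpm, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("tpm must be square")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("tpm rows must be non-negative and sum to 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    k = P.shape[0]
    p = np.full(k, 1.0 / k)
    for _ in range(1000):
        nxt = P.T @ p
        if np.linalg.norm(nxt - p) < 1e-13:
            p = nxt
            break
        p = nxt
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    labels = np.empty(length, dtype=int)
    labels[0] = int(np.searchsorted(np.cumsum(p), u[0], side="right"))
    for t in range(1, length):
        labels[t] = int(np.searchsorted(cum[labels[t - 1]], u[t], side="right"))
    labels = np.minimum(labels, k - 1)  # guard against cumsum rounding at 1.0
    return labels
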
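"""Leading Eigenvector Dynamics Analysis (LEiDA).

Turns regional time series into a probabilistic metastable substate (PMS)
space: band-pass filter, Hilbert phases, instantaneous phase-coherence
matrices dFC(n,p,t) = cos(theta(n,t) - theta(p,t)), their leading
eigenvectors V1(t), k-means clustering of the pooled eigenvectors into k
substates, fractional occupancies, the substate switching matrix, and a
paired permutation test for between-condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import signal
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import RegionalTimeSeries, TransitionMatrix

__all__ = [
    "PhaseRepresentation",
    "CoherenceTensor",
    "EigenvectorSeries",
    "PMSModel",
    "PermutationTestResult",
    "bandpass_filter",
    "compute_phases",
    "phase_coherence_tensor",
    "leading_eigenvectors",
    "cluster_states",
    "select_k",
    "occupancy_probabilities",
    "switching_matrix",
    "assign_to_centroids",
    "permutation_paired_test",
    "leida_chain",
]

SIGN_CONVENTION = "majority-negative"


@dataclass
class PhaseRepresentation:
    """Hilbert phases and amplitudes of a filtered signal block.

    ``valid_range = (start, stop)`` marks the sample interval kept after
    trimming transform edge effects; everything downstream uses only this
    interval.
    """

    phases: np.ndarray  # (N, T), radians, wrapped to (-pi, pi]
    amplitudes: np.ndarray  # (N, T), >= 0
    tr_s: float
    valid_range: tuple[int, int]
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")
        start, stop = self.valid_range
        if not 0 <= start < stop <= self.phases.shape[1]:
            raise ValueError("valid_range is empty or out of bounds")

    @property
    def valid_phases(self) -> np.ndarray:
        start, stop = self.valid_range
        return self.phases[:, start:stop]


@dataclass
class CoherenceTensor:
    """Instantaneous phase-coherence matrices dFC(t), one N x N slice per sample."""

    values: np.ndarray  # (N, N, T')
    t_index: np.ndarray  # original sample index of each slice
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError("coherence tensor must be (N, N, T')")

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]


@dataclass
class EigenvectorSeries:
    """Leading eigenvectors V1(t), one unit-norm row per time point."""

    vectors: np.ndarray  # (T', N)
    sign_convention: str = SIGN_CONVENTION
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be (T', N)")


@dataclass
class PMSModel:
    """A brain state as a probabilistic metastable substate space.

    ``centroids`` are the k substate patterns V_c (rows), ``probabilities``
    their fractional occupancies, and ``tpm`` the substate switching matrix.
    """

    centroids: np.ndarray  # (k, N)
    probabilities: np.ndarray  # (k,), simplex
    tpm: TransitionMatrix
    k: int
    silhouette: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if self.probabilities.shape != (self.k,):
            raise ValueError("probabilities must have length k")
        if np.any(self.probabilities < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    @property
    def n_regions(self) -> int:
        return self.centroids.shape[1]


def bandpass_filter(
    ts: RegionalTimeSeries,
    f_low: float = 0.02,
    f_high: float = 0.1,
) -> RegionalTimeSeries:
    """Zero-phase second-order Butterworth band-pass, per region.

    The per-region mean is removed first; filtering is forward-backward
    (``sosfiltfilt``) so phases are not distorted — essential because the
    Hilbert phase is the analysis quantity.
    """
    nyq = 0.5 / ts.tr_s
    if not 0 < f_low < f_high:
        raise ValueError("require 0 < f_low < f_high")
    if f_high >= nyq:
        raise ValueError(
            f"f_high = {f_high} Hz is not below the Nyquist frequency "
            f"{nyq:.4f} Hz for tr_s = {ts.tr_s}; achievable band is "
            f"(0, {nyq:.4f}) Hz"
        )
    demeaned = ts.values - ts.values.mean(axis=1, keepdims=True)
    sos = signal.butter(2, [f_low, f_high], btype="bandpass", fs=1.0 / ts.tr_s, output="sos")
    filtered = signal.sosfiltfilt(sos, demeaned, axis=1)
    return RegionalTimeSeries(
        filtered, tr_s=ts.tr_s, subject_id=ts.subject_id, condition=ts.condition
    )


def compute_phases(ts: RegionalTimeSeries, trim: int = 3) -> PhaseRepresentation:
    """Analytic-signal phase and amplitude per region via the Hilbert transform.

    ``trim`` samples at each end are excluded from ``valid_range`` to guard
    against transform edge effects.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if ts.n_samples <= 2 * trim:
        raise ValueError(
            f"series of {ts.n_samples} samples too short for trim = {trim}"
        )
    demeaned = ts.values - ts.values.mean(axis=1, keepdims=True)
    analytic = signal.hilbert(demeaned, axis=1)
    return PhaseRepresentation(
        phases=np.angle(analytic),
        amplitudes=np.abs(analytic),
        tr_s=ts.tr_s,
        valid_range=(trim, ts.n_samples - trim),
        subject_id=ts.subject_id,
        condition=ts.condition,
    )


def phase_coherence_tensor(phases: PhaseRepresentation) -> CoherenceTensor:
    """dFC(n, p, t) = cos(theta(n, t) - theta(p, t)) over the valid interval.

    Each slice is symmetric with unit diagonal; entries run from 1 (regions
    in phase) through 0 (90 degrees apart) to -1 (anti-phase).
    """
    theta = phases.valid_phases
    values = np.cos(theta[:, None, :] - theta[None, :, :])
    start, stop = phases.valid_range
    return CoherenceTensor(
        values=values,
        t_index=np.arange(start, stop),
        subject_id=phases.subject_id,
        condition=phases.condition,
    )


def _apply_sign_convention(vectors: np.ndarray) -> np.ndarray:
    """Flip rows so most elements are negative; ties put the largest-magnitude
    element on the negative side.  A fixed convention is required because
    eigenvectors are defined up to sign and k-means is not sign-invariant."""
    out = vectors.copy()
    n_neg = (out < 0).sum(axis=1)
    n_pos = (out > 0).sum(axis=1)
    flip = n_pos > n_neg
    tie = n_pos == n_neg
    if np.any(tie):
        lead = np.take_along_axis(
            out, np.argmax(np.abs(out), axis=1)[:, None], axis=1
        )[:, 0]
        flip = flip | (tie & (lead > 0))
    out[flip] *= -1.0
    return out


def leading_eigenvectors(
    tensor: CoherenceTensor, sym_tol: float = 1e-9
) -> EigenvectorSeries:
    """Unit leading eigenvector (largest-magnitude eigenvalue) of each slice.

    V1(t) V1(t)^T is the best rank-1 approximation of dFC(t), so V1(t)
    captures the instantaneous dominant coherence pattern at 1/N of the cost
    of keeping the full matrix.
    """
    arr = np.moveaxis(tensor.values, 2, 0)  # (T', N, N)
    asym = np.max(np.abs(arr - np.swapaxes(arr, 1, 2)))
    if asym > sym_tol:
        raise ValueError(f"coherence slices asymmetric beyond tolerance ({asym:.2e})")
    eigvals, eigvecs = np.linalg.eigh(arr)
    lead = np.argmax(np.abs(eigvals), axis=1)
    rows = np.arange(arr.shape[0])
    v1 = eigvecs[rows, :, lead]
    v1 = _apply_sign_convention(v1)
    return EigenvectorSeries(
        vectors=v1, subject_id=tensor.subject_id, condition=tensor.condition
    )


def _pool(eigs) -> tuple[np.ndarray, list[int]]:
    series = [eigs] if isinstance(eigs, EigenvectorSeries) else list(eigs)
    lengths = [s.vectors.shape[0] for s in series]
    return np.vstack([s.vectors for s in series]), lengths


def cluster_states(
    eigs,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[PMSModel, list[np.ndarray]]:
    """k-means over pooled leading eigenvectors -> PMS space.

    ``eigs`` may be a single :class:`EigenvectorSeries` or a list pooled
    across subjects and conditions (the default analysis clusters the
    collapsed data).  Euclidean k-means with k-means++ seeding; the best of
    ``n_restarts`` restarts is kept.  Returns the fitted model plus the
    per-series label sequences (occupancies are pooled; transitions are
    counted within series only, never across a subject boundary).
    """
    pooled, lengths = _pool(eigs)
    if k < 1:
        raise ValueError("k must be >= 1")
    if pooled.shape[0] < k:
        raise ValueError(f"k = {k} exceeds the {pooled.shape[0]} pooled samples")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31))
    flat_labels = km.fit_predict(pooled)
    labels = _split(flat_labels, lengths)
    model = PMSModel(
        centroids=km.cluster_centers_,
        probabilities=occupancy_probabilities(flat_labels, k),
        tpm=switching_matrix(labels, k),
        k=k,
        metadata={
            "inertia": float(km.inertia_),
            "n_restarts": int(n_restarts),
            "seed": int(seed),
            "sign_convention": SIGN_CONVENTION,
        },
    )
    return model, labels


def _split(flat: np.ndarray, lengths: list[int]) -> list[np.ndarray]:
    out, i = [], 0
    for ln in lengths:
        out.append(flat[i : i + ln].copy())
        i += ln
    return out


def select_k(
    eigs,
    k_range: tuple[int, int] = (2, 8),
    n_restarts: int = 20,
    seed: int = 0,
):
    """Silhouette score for each candidate k; the recommended k is the argmax.

    Returns ``(table, best_k)`` where ``table`` is a list of
    ``{"k": k, "silhouette": s}`` records in ascending k.
    """
    pooled, _ = _pool(eigs)
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi >= pooled.shape[0] or k_lo > k_hi:
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    table = []
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31))
        lab = km.fit_predict(pooled)
        table.append({"k": k, "silhouette": float(silhouette_score(pooled, lab))})
    best = max(table, key=lambda r: r["silhouette"])["k"]
    return table, best


def occupancy_probabilities(labels, k: int) -> np.ndarray:
    """Fractional occupancy: epochs in each substate / total epochs.

    ``labels`` is one integer sequence in ``[0, k)`` or a list of them
    (pooled).  The result is an exact rational simplex vector.
    """
    seqs = [labels] if np.ndim(labels[0] if len(labels) else 0) == 0 else list(labels)
    flat = np.concatenate([np.asarray(s, dtype=int) for s in seqs]) if seqs else np.array([], int)
    if flat.size == 0:
        raise ValueError("no labels supplied")
    if flat.min() < 0 or flat.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    return np.bincount(flat, minlength=k) / flat.size


def switching_matrix(labels, k: int) -> TransitionMatrix:
    """Row-normalized counts of consecutive substate pairs.

    Transitions are counted within each supplied sequence only; boundaries
    between sequences (subjects/sessions) contribute nothing.  A substate
    with no observed outgoing transition gets a NaN row, flagged via
    ``visited``.
    """
    seqs = [labels] if np.ndim(labels[0] if len(labels) else 0) == 0 else list(labels)
    counts = np.zeros((k, k))
    total_len = 0
    for seq in seqs:
        s = np.asarray(seq, dtype=int)
        total_len += s.size
        if s.size and (s.min() < 0 or s.max() >= k):
            raise ValueError(f"labels must lie in [0, {k})")
        if s.size >= 2:
            np.add.at(counts, (s[:-1], s[1:]), 1)
    if total_len < 2:
        raise ValueError("need at least 2 labels to count transitions")
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    values = np.full((k, k), np.nan)
    values[visited] = counts[visited] / row_sums[visited, None]
    return TransitionMatrix(values=values, visited=visited)


def assign_to_centroids(eigs, centroids: np.ndarray):
    """Nearest-centroid (Euclidean) labels for new eigenvectors.

    Used to project simulated dynamics onto an empirically defined PMS
    space.  Exact distance ties resolve to the lowest centroid index.
    Returns one label array, or a list when ``eigs`` is a list.
    """
    centroids = np.asarray(centroids, dtype=float)
    single = isinstance(eigs, EigenvectorSeries)
    series = [eigs] if single else list(eigs)
    out = []
    for s in series:
        if s.vectors.shape[1] != centroids.shape[1]:
            raise ValueError(
                f"eigenvector dimension {s.vectors.shape[1]} does not match "
                f"centroid dimension {centroids.shape[1]}"
            )
        out.append(np.argmin(cdist(s.vectors, centroids), axis=1))
    return out[0] if single else out


@dataclass
class PermutationTestResult:
    p_value: float
    statistic: float
    n_perm: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _paired_t(diffs: np.ndarray) -> float:
    m = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0 if m == 0 else np.inf * np.sign(m)
    return float(m / (sd / np.sqrt(diffs.size)))


def permutation_paired_test(
    values_a,
    values_b,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationTestResult:
    """Permutation-based paired t test (two-sided).

    The statistic is the paired t on per-subject differences; the null is
    built by independent within-pair sign flips of the differences (the
    exchangeable permutation for paired designs).  When ``2**n_pairs`` does
    not exceed ``n_perm`` the flip set is enumerated exhaustively and the
    p-value is exact; otherwise ``n_perm`` random flip patterns are drawn
    and the observed statistic is included in the null.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    t_obs = _paired_t(d)
    if np.all(d == 0):
        return PermutationTestResult(1.0, 0.0, 0, alpha)

    thresh = abs(t_obs) - 1e-12
    if 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        t_null = np.array([_paired_t(s * d) for s in signs])
        p = float(np.mean(np.abs(t_null) >= thresh))
        n_used = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        t_null = np.array([_paired_t(s * d) for s in signs])
        p = float((1 + np.sum(np.abs(t_null) >= thresh)) / (n_perm + 1))
        n_used = n_perm
    return PermutationTestResult(p, float(t_obs), n_used, alpha)


def leida_chain(
    ts: RegionalTimeSeries,
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
) -> EigenvectorSeries:
    """Convenience: filter -> phases -> coherence tensor -> leading eigenvectors."""
    filtered = bandpass_filter(ts, *band)
    phases = compute_phases(filtered, trim=trim)
    return leading_eigenvectors(phase_coherence_tensor(phases))
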
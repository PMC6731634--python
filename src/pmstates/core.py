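"""Shared containers and seed plumbing.

The two types defined here cross module boundaries: regional time series are
produced by the simulator and consumed by the LEiDA chain, and transition
matrices are produced by the LEiDA chain and consumed by the entropy-rate
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegionalTimeSeries", "TransitionMatrix", "spawn_seeds"]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed.

    All randomness in the package flows through explicit integer seeds; this
    is the single documented derivation, so any stage of a pipeline can be
    reproduced in isolation from the top-level seed.
    """
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s % np.uint32(2**31)) for s in state]


@dataclass
class RegionalTimeSeries:
    """An N x T block of regional signals sampled every ``tr_s`` seconds.

    ``values[n, t]`` is the signal of region ``n`` at sample ``t``; units are
    arbitrary (simulated x_n or empirical BOLD).
    """

    values: np.ndarray
    tr_s: float
    subject_id: str = "sub-00"
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (regions x samples) array")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at region {bad[0]}, sample {bad[1]}"
            )
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.tr_s


@dataclass
class TransitionMatrix:
    """Row-stochastic substate switching matrix.

    Rows index the current substate, columns the next one.  A substate with
    no observed outgoing transition has an all-NaN row and ``visited`` False
    for that index — it is flagged, never silently filled with a uniform row.
    """

    values: np.ndarray
    visited: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("transition matrix must be square")
        if self.visited is None:
            self.visited = ~np.all(np.isnan(self.values), axis=1)
        self.visited = np.asarray(self.visited, dtype=bool)
        rows = self.values[self.visited]
        if rows.size:
            if np.any(rows < -1e-12) or np.any(rows > 1 + 1e-12):
                raise ValueError("transition probabilities must lie in [0, 1]")
            sums = rows.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("visited rows must sum to 1 within 1e-9")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def fully_stochastic(self) -> bool:
        return bool(np.all(self.visited))
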
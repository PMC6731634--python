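"""In-silico stimulation: forcing transitions between brain states.

Stimulating a region in the Hopf model is shifting its local bifurcation
parameter: positive shifts (the *synchronization* protocol) push the node
into sustained oscillation, promoting whole-brain synchrony; negative
shifts (the *noise* protocol) deepen the fixed point, promoting noisy
desynchronized dynamics.  Stimulation is bilateral — one "site" is one
homotopic left/right pair, both members shifted identically — and tonic
(sustained for the whole simulation).

Two search strategies are provided: an exhaustive scan over sites x
stimulation intensities scoring each cell by the KL distance of the
perturbed model's PMS occupancies to a target state, and a greedy multisite
search that accumulates sites at a weak fixed intensity, tracking fit to
both target and source states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import spawn_seeds
from .fitting import _chain, pms_kl
from .hopf import HopfParams, HopfSystem, simulate
from .leida import (
    PMSModel,
    assign_to_centroids,
    leading_eigenvectors,
    occupancy_probabilities,
)

__all__ = [
    "PerturbationSpec",
    "TransitionMap",
    "GreedyTrace",
    "apply_perturbation",
    "transition_scan",
    "greedy_multisite",
]

PROTOCOLS = ("synchronization", "noise")

# Default intensity grids bracket the regimes where bilateral stimulation is
# effective: weak positive shifts for synchronization, stronger negative
# shifts for noise (the noise protocol needs larger absolute intensities).
DEFAULT_SYNC_GRID = np.round(np.arange(0.0, 0.2001, 0.02), 10)
DEFAULT_NOISE_GRID = np.round(np.arange(0.0, -0.6001, -0.05), 10)


@dataclass
class PerturbationSpec:
    """Which homotopic pairs to stimulate, how, and how strongly."""

    protocol: str
    pair_indices: tuple[int, ...]
    delta_a: float

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        self.pair_indices = tuple(int(i) for i in self.pair_indices)
        if not self.pair_indices:
            raise ValueError("at least one homotopic pair must be selected")
        if self.protocol == "synchronization" and self.delta_a < 0:
            raise ValueError("synchronization protocol requires delta_a >= 0")
        if self.protocol == "noise" and self.delta_a > 0:
            raise ValueError("noise protocol requires delta_a <= 0")


@dataclass
class TransitionMap:
    """KL-to-target over (homotopic pair x stimulation intensity)."""

    kl_values: np.ndarray  # (n_pairs, n_intensities)
    intensity_grid: np.ndarray
    baseline_kl: float
    protocol: str
    pair_labels: list[str] = field(default_factory=list)

    def best_site(self) -> tuple[int, int]:
        """(pair, intensity) index of the lowest KL to target."""
        return tuple(np.unravel_index(np.argmin(self.kl_values), self.kl_values.shape))


@dataclass
class GreedyTrace:
    """Trajectory of the greedy multisite search.

    Entry 0 of every per-step vector is the unperturbed baseline; entry s
    corresponds to stimulating the first s chosen pairs.
    """

    chosen_pairs: list[int]
    kl_to_target: np.ndarray
    kl_to_source: np.ndarray
    substate_probabilities: np.ndarray  # (steps + 1, k) vs target centroids
    best_step: int
    delta_a: float


def _resolve_pairs(pairs, indices):
    pairs = [tuple(int(i) for i in p) for p in pairs]
    for i in indices:
        if not 0 <= i < len(pairs):
            raise ValueError(
                f"unknown homotopic pair index {i}; table has {len(pairs)} pairs"
            )
    return pairs


def apply_perturbation(
    params: HopfParams,
    spec: PerturbationSpec,
    homotopic_pairs,
) -> HopfParams:
    """Shift the bifurcation parameter of both members of each selected pair.

    Returns a new parameter set: ``a[n] += delta_a`` for the 2 x |pairs|
    stimulated nodes, everything else untouched.
    """
    pairs = _resolve_pairs(homotopic_pairs, spec.pair_indices)
    a = params.a.copy()
    for i in spec.pair_indices:
        left, right = pairs[i]
        a[left] += spec.delta_a
        a[right] += spec.delta_a
    return params.with_a(a)


def _occupancies(sim_results, model: PMSModel, band, trim) -> np.ndarray:
    labels = []
    for res in sim_results:
        _, _, tensor = _chain(res.series, band, trim)
        eigs = leading_eigenvectors(tensor)
        labels.append(assign_to_centroids(eigs, model.centroids))
    return occupancy_probabilities(labels, model.k)


def transition_scan(
    source_system: HopfSystem,
    target_model: PMSModel,
    protocol: str = "synchronization",
    intensity_grid=None,
    n_runs: int = 3,
    duration_s: float = 300.0,
    seed: int = 0,
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
) -> TransitionMap:
    """Exhaustive bilateral stimulation scan of the source-state model.

    Every homotopic pair is stimulated separately at every intensity on the
    grid; each cell's KL distance between the perturbed model's occupancies
    and the target state's is recorded.  All cells — and the unperturbed
    baseline — use the same ``n_runs`` simulation seeds, so comparisons are
    on common noise, and a grid point at intensity 0 reproduces the baseline
    exactly.
    """
    if intensity_grid is None:
        intensity_grid = (
            DEFAULT_SYNC_GRID if protocol == "synchronization" else DEFAULT_NOISE_GRID
        )
    grid = np.asarray(intensity_grid, dtype=float)
    if protocol == "synchronization" and np.any(grid < 0):
        raise ValueError("synchronization grid must be non-negative")
    if protocol == "noise" and np.any(grid > 0):
        raise ValueError("noise grid must be non-positive")
    pairs = _resolve_pairs(source_system.homotopic_pairs, [])
    weights = source_system.weights
    params = source_system.params
    run_seeds = spawn_seeds(seed, n_runs)

    def kl_for(p: HopfParams) -> float:
        sims = [simulate(weights, p, duration_s, s) for s in run_seeds]
        probs = _occupancies(sims, target_model, band, trim)
        return pms_kl(target_model.probabilities, probs)

    baseline_kl = kl_for(params)
    kl_values = np.empty((len(pairs), grid.size))
    for pi in range(len(pairs)):
        for gi, delta in enumerate(grid):
            if delta == 0.0:
                kl_values[pi, gi] = baseline_kl
                continue
            spec = PerturbationSpec(protocol, (pi,), float(delta))
            kl_values[pi, gi] = kl_for(
                apply_perturbation(params, spec, pairs)
            )
    names = getattr(source_system.connectome, "region_names", None)
    labels = (
        [f"{names[l]}|{names[r]}" for l, r in pairs]
        if names is not None
        else [f"pair{p}" for p in range(len(pairs))]
    )
    return TransitionMap(
        kl_values=kl_values,
        intensity_grid=grid,
        baseline_kl=baseline_kl,
        protocol=protocol,
        pair_labels=labels,
    )


def greedy_multisite(
    source_system: HopfSystem,
    target_model: PMSModel,
    source_model: PMSModel,
    delta_a: float,
    max_steps: int,
    n_runs: int = 3,
    duration_s: float = 300.0,
    seed: int = 0,
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
) -> GreedyTrace:
    """Greedy accumulation of stimulation sites at one weak intensity.

    At each step every not-yet-chosen homotopic pair is tentatively added to
    the stimulated set; the pair minimizing the KL distance to the target
    state is kept and remains stimulated in later steps (ties resolve to the
    lowest pair index).  Fit to the source state and the occupancy vector on
    the target centroids are recorded at every step; candidates at every
    step share the same simulation seeds.  The typical signature of a
    successful forced transition is a U-shaped target-KL curve (best at a
    few sites, worse as more are added) with monotonically worsening
    source-KL.
    """
    pairs = _resolve_pairs(source_system.homotopic_pairs, [])
    if max_steps > len(pairs):
        raise ValueError(f"max_steps = {max_steps} exceeds the {len(pairs)} pairs")
    protocol = "synchronization" if delta_a >= 0 else "noise"
    weights = source_system.weights
    params = source_system.params
    run_seeds = spawn_seeds(seed, n_runs)

    def score(active: tuple[int, ...]):
        if active:
            spec = PerturbationSpec(protocol, active, float(delta_a))
            p = apply_perturbation(params, spec, pairs)
        else:
            p = params
        sims = [simulate(weights, p, duration_s, s) for s in run_seeds]
        probs_t = _occupancies(sims, target_model, band, trim)
        probs_s = _occupancies(sims, source_model, band, trim)
        return (
            pms_kl(target_model.probabilities, probs_t),
            pms_kl(source_model.probabilities, probs_s),
            probs_t,
        )

    kl_t0, kl_s0, probs0 = score(())
    chosen: list[int] = []
    kl_t, kl_s, probs = [kl_t0], [kl_s0], [probs0]
    for _ in range(max_steps):
        best_pair, best_result = None, None
        for cand in range(len(pairs)):
            if cand in chosen:
                continue
            result = score(tuple(chosen) + (cand,))
            if best_result is None or result[0] < best_result[0]:
                best_pair, best_result = cand, result
        chosen.append(best_pair)
        kl_t.append(best_result[0])
        kl_s.append(best_result[1])
        probs.append(best_result[2])
    return GreedyTrace(
        chosen_pairs=chosen,
        kl_to_target=np.asarray(kl_t),
        kl_to_source=np.asarray(kl_s),
        substate_probabilities=np.asarray(probs),
        best_step=int(np.argmin(kl_t)),
        delta_a=float(delta_a),
    )
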
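"""Scoring simulated dynamics against an empirical brain state, and fitting.

The model is scored on four complementary observables:

* static FC — Pearson correlation between upper-triangular entries of the
  grand-averaged functional-connectivity matrices;
* FCD — Kolmogorov-Smirnov distance between the pooled upper-triangular
  entries of empirical and simulated functional-connectivity-dynamics
  matrices (cosine similarity of dFC patterns over time-point pairs);
* PMS — symmetrized Kullback-Leibler distance between empirical and
  simulated substate occupancy probabilities, evaluated on the *empirical*
  centroids (the headline fit criterion);
* TPM — absolute difference of Markov entropy rates of the two switching
  matrices.

Two fitting loops are provided: an exhaustive sweep of the global coupling
G selecting the minimum of the PMS KL distance, and a gradient-descent
update of effective connectivity that moves each connection by
``epsilon * (FC_phases_emp - FC_phases_model)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .core import RegionalTimeSeries, TransitionMatrix, spawn_seeds
from .hopf import HopfParams, SimulationResult, simulate
from .leida import (
    CoherenceTensor,
    PhaseRepresentation,
    PMSModel,
    assign_to_centroids,
    bandpass_filter,
    compute_phases,
    leading_eigenvectors,
    occupancy_probabilities,
    phase_coherence_tensor,
    switching_matrix,
)

__all__ = [
    "FitResult",
    "ECState",
    "SweepResult",
    "static_fc",
    "fc_fit",
    "grand_average_phase_fc",
    "fcd_matrix",
    "fcd_samples",
    "fcd_ks",
    "pms_kl",
    "stationary_distribution",
    "markov_entropy_rate",
    "entropy_distance",
    "empirical_references",
    "evaluate_model",
    "ec_update",
    "sweep_coupling",
    "optimize_ec",
]

PROB_FLOOR = 1e-6  # occupancy floor before KL, so unvisited substates stay finite


@dataclass
class FitResult:
    kl_pms: float
    ks_fcd: float
    fc_corr: float
    entropy_distance: float
    sim_probabilities: np.ndarray
    sim_tpm: TransitionMatrix
    n_runs: int
    seeds: list[int] = field(default_factory=list)


@dataclass
class ECState:
    """Effective connectivity after gradient-descent refinement."""

    weights: np.ndarray
    iteration: int
    fit_history: list[tuple[int, float]]
    epsilon: float

    @property
    def objective(self) -> float:
        return self.fit_history[-1][1]


@dataclass
class SweepResult:
    table: pd.DataFrame
    g_star_pms: float
    g_star_fcd: float
    results: list[FitResult]


# ---------------------------------------------------------------- metrics


def static_fc(ts: RegionalTimeSeries) -> np.ndarray:
    """Pearson correlation matrix of the regional signals."""
    stds = ts.values.std(axis=1)
    if np.any(stds == 0):
        bad = int(np.argmax(stds == 0))
        raise ValueError(
            f"region {bad} is constant; its correlations are undefined"
        )
    return np.corrcoef(ts.values)


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def fc_fit(emp_fc: np.ndarray, sim_fc: np.ndarray) -> float:
    """Pearson r over strictly-upper-triangular FC entries."""
    emp_fc = np.asarray(emp_fc, float)
    sim_fc = np.asarray(sim_fc, float)
    if emp_fc.shape != sim_fc.shape:
        raise ValueError("FC matrices must share shape")
    return float(stats.pearsonr(_upper(emp_fc), _upper(sim_fc))[0])


def grand_average_phase_fc(phases: PhaseRepresentation) -> np.ndarray:
    """FC_ij = < cos(phi_j(t) - phi_i(t)) >_t over the valid interval."""
    theta = phases.valid_phases
    return np.cos(theta[:, None, :] - theta[None, :, :]).mean(axis=2)


def fcd_matrix(tensor: CoherenceTensor) -> np.ndarray:
    """Cosine similarity between dFC(t1) and dFC(t2) upper triangles.

    Blocks of elevated similarity along the diagonal mark epochs of stable
    coherence configuration.
    """
    n = tensor.values.shape[0]
    iu = np.triu_indices(n, k=1)
    vecs = tensor.values[iu].T  # (T', n_pairs)
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        t = int(np.argmax(norms == 0))
        raise ValueError(f"dFC slice {t} has a zero upper triangle")
    unit = vecs / norms[:, None]
    return unit @ unit.T


def fcd_samples(tensors: list[CoherenceTensor]) -> np.ndarray:
    """Pooled strictly-upper-triangular FCD entries across sessions."""
    out = []
    for t in tensors:
        out.append(_upper(fcd_matrix(t)))
    return np.concatenate(out)


def fcd_ks(emp, sim) -> float:
    """Two-sample KS statistic between pooled empirical and simulated FCD entries.

    Arguments may be lists of :class:`CoherenceTensor` or pre-pooled 1-D
    sample vectors.
    """
    emp_s = emp if isinstance(emp, np.ndarray) else fcd_samples(emp)
    sim_s = sim if isinstance(sim, np.ndarray) else fcd_samples(sim)
    return float(stats.ks_2samp(emp_s, sim_s).statistic)


def pms_kl(p_emp, p_sim, floor: float = PROB_FLOOR) -> float:
    """Symmetrized KL distance between two substate occupancy vectors.

    0.5 * [sum_i P(i) ln(P(i)/Q(i)) + sum_i Q(i) ln(Q(i)/P(i))], natural
    log.  Probabilities are floored at ``floor`` and renormalized first, so
    a substate never visited in a short simulation yields a large but finite
    distance.
    """
    p = np.asarray(p_emp, dtype=float)
    q = np.asarray(p_sim, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("probability vectors must be 1-D with equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    p = np.maximum(p, floor)
    q = np.maximum(q, floor)
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


def stationary_distribution(tpm) -> np.ndarray:
    """Stationary distribution p solving P^T p = p.

    Taken as the eigenvector of P^T with eigenvalue closest to 1 (which must
    be within 1e-8 of 1), refined by power iteration until the residual
    ||P^T p - p|| drops below 1e-12.  Requires an irreducible chain; a
    reducible one has no unique stationary distribution and raises, naming
    the disconnected state groups.
    """
    P = _tpm_values(tpm)
    k = P.shape[0]
    n_comp, labels = connected_components(P > 0, directed=True, connection="strong")
    if n_comp > 1:
        groups = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise ValueError(
            f"transition matrix is reducible; mutually unreachable state "
            f"groups: {groups}"
        )
    eigvals, eigvecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    if abs(eigvals[idx] - 1.0) > 1e-8:
        p = np.full(k, 1.0 / k)
    else:
        p = np.abs(np.real(eigvecs[:, idx]))
        p = p / p.sum()
    for _ in range(10_000):
        nxt = P.T @ p
        nxt = nxt / nxt.sum()
        if np.linalg.norm(nxt - p) < 1e-12:
            p = nxt
            break
        p = nxt
    return p


def _tpm_values(tpm) -> np.ndarray:
    if isinstance(tpm, TransitionMatrix):
        if not tpm.fully_stochastic:
            missing = list(np.flatnonzero(~tpm.visited))
            raise ValueError(
                f"states {missing} have no observed outgoing transitions; "
                "the matrix is not row-stochastic"
            )
        P = tpm.values
    else:
        P = np.asarray(tpm, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("rows must be non-negative and sum to 1")
    return P


def markov_entropy_rate(tpm) -> float:
    """Entropy rate S = -sum_i p(i) sum_j P(i,j) ln P(i,j), natural log.

    p is the stationary distribution; 0 ln 0 is taken as 0.  A chain that
    barely switches has low rate entropy, a uniformly switching chain the
    maximal ln k.
    """
    P = _tpm_values(tpm)
    p = stationary_distribution(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(-(p * plogp.sum(axis=1)).sum())


def entropy_distance(tpm_a, tpm_b) -> float:
    """|S_a - S_b|: absolute difference of Markov entropy rates."""
    return abs(markov_entropy_rate(tpm_a) - markov_entropy_rate(tpm_b))


# ---------------------------------------------------------- evaluation


def _chain(ts: RegionalTimeSeries, band, trim):
    filtered = bandpass_filter(ts, *band)
    phases = compute_phases(filtered, trim=trim)
    tensor = phase_coherence_tensor(phases)
    return filtered, phases, tensor


def empirical_references(
    ts_list: list[RegionalTimeSeries],
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
) -> dict:
    """Reference observables of an empirical dataset, for model scoring.

    Returns mean static FC (of the band-passed series), pooled FCD samples,
    mean grand-average phase FC, and the per-session eigenvector series.
    """
    fcs, tensors, eig_list, phase_fcs = [], [], [], []
    for ts in ts_list:
        filtered, phases, tensor = _chain(ts, band, trim)
        fcs.append(static_fc(filtered))
        phase_fcs.append(grand_average_phase_fc(phases))
        tensors.append(tensor)
        eig_list.append(leading_eigenvectors(tensor))
    return {
        "fc": np.mean(fcs, axis=0),
        "fcd_samples": fcd_samples(tensors),
        "phase_fc": np.mean(phase_fcs, axis=0),
        "eigenvectors": eig_list,
    }


def evaluate_model(
    sim_results: list[SimulationResult],
    empirical_model: PMSModel,
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
    empirical_fc: np.ndarray | None = None,
    empirical_fcd_samples: np.ndarray | None = None,
) -> FitResult:
    """Score simulated runs against an empirical PMS model.

    Each run goes through the LEiDA chain; its eigenvectors are assigned to
    the *empirical* centroids, yielding simulated occupancies and a
    simulated switching matrix pooled over runs.  ``kl_pms`` compares the
    occupancy vectors, ``entropy_distance`` the switching matrices (NaN if
    either is not a stochastic irreducible chain), and ``ks_fcd`` /
    ``fc_corr`` are filled only when the empirical references are supplied.
    """
    if not sim_results:
        raise ValueError("no simulation results supplied")
    k = empirical_model.k
    labels, sim_fcs, sim_tensors = [], [], []
    for res in sim_results:
        filtered, _, tensor = _chain(res.series, band, trim)
        eigs = leading_eigenvectors(tensor)
        labels.append(assign_to_centroids(eigs, empirical_model.centroids))
        sim_fcs.append(static_fc(filtered))
        sim_tensors.append(tensor)

    sim_probs = occupancy_probabilities(labels, k)
    sim_tpm = switching_matrix(labels, k)
    kl = pms_kl(empirical_model.probabilities, sim_probs)
    try:
        s_dist = entropy_distance(empirical_model.tpm, sim_tpm)
    except ValueError:
        s_dist = float("nan")
    fc_corr = (
        fc_fit(empirical_fc, np.mean(sim_fcs, axis=0))
        if empirical_fc is not None
        else float("nan")
    )
    ks = (
        fcd_ks(empirical_fcd_samples, fcd_samples(sim_tensors))
        if empirical_fcd_samples is not None
        else float("nan")
    )
    return FitResult(
        kl_pms=kl,
        ks_fcd=ks,
        fc_corr=fc_corr,
        entropy_distance=s_dist,
        sim_probabilities=sim_probs,
        sim_tpm=sim_tpm,
        n_runs=len(sim_results),
        seeds=[r.seed for r in sim_results],
    )


# ------------------------------------------------------------- fitting


def sweep_coupling(
    connectome,
    params_template: HopfParams,
    g_grid,
    empirical_model: PMSModel,
    n_runs: int = 3,
    duration_s: float = 300.0,
    seed: int = 0,
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
    empirical_fc: np.ndarray | None = None,
    empirical_fcd_samples: np.ndarray | None = None,
) -> SweepResult:
    """Exhaustive scan of the global coupling G against an empirical state.

    For every G on the grid the model is simulated ``n_runs`` times (with
    the same run seeds at every G, so grid points are compared on common
    noise) and scored with :func:`evaluate_model`.  Two optima are reported
    separately, mirroring the two fit criteria: ``g_star_pms`` minimizes the
    PMS KL distance (the selection criterion) and ``g_star_fcd`` minimizes
    the FCD KS distance.
    """
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.size == 0:
        raise ValueError("g_grid is empty")
    if np.any(np.diff(g_grid) <= 0):
        raise ValueError("g_grid must be strictly ascending")
    run_seeds = spawn_seeds(seed, n_runs)
    rows, results = [], []
    for g in g_grid:
        params = HopfParams(
            a=params_template.a,
            omega=params_template.omega,
            G=float(g),
            beta=params_template.beta,
            dt_s=params_template.dt_s,
            tr_s=params_template.tr_s,
            transient_s=params_template.transient_s,
        )
        sims = [simulate(connectome, params, duration_s, s) for s in run_seeds]
        fit = evaluate_model(
            sims,
            empirical_model,
            band=band,
            trim=trim,
            empirical_fc=empirical_fc,
            empirical_fcd_samples=empirical_fcd_samples,
        )
        results.append(fit)
        rows.append(
            {
                "G": float(g),
                "kl_pms": fit.kl_pms,
                "ks_fcd": fit.ks_fcd,
                "fc_corr": fit.fc_corr,
                "entropy_distance": fit.entropy_distance,
            }
        )
    table = pd.DataFrame(rows)
    g_star_pms = float(table.loc[table["kl_pms"].idxmin(), "G"])
    ks_col = table["ks_fcd"]
    g_star_fcd = (
        float(table.loc[ks_col.idxmin(), "G"]) if ks_col.notna().any() else float("nan")
    )
    return SweepResult(table=table, g_star_pms=g_star_pms, g_star_fcd=g_star_fcd, results=results)


def ec_update(
    weights: np.ndarray,
    fc_emp: np.ndarray,
    fc_mod: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """One effective-connectivity correction step.

    Every off-diagonal connection moves by ``epsilon * (FC_emp - FC_mod)``;
    the result is clamped at zero and re-symmetrized.  Zero residual is an
    exact fixed point.
    """
    update = epsilon * (np.asarray(fc_emp, float) - np.asarray(fc_mod, float))
    np.fill_diagonal(update, 0.0)
    out = np.maximum(weights + update, 0.0)
    return 0.5 * (out + out.T)


def optimize_ec(
    connectome,
    params: HopfParams,
    empirical_phase_fc: np.ndarray,
    epsilon: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-3,
    n_runs: int = 3,
    duration_s: float = 300.0,
    seed: int = 0,
    band: tuple[float, float] = (0.02, 0.1),
    trim: int = 3,
) -> ECState:
    """Gradient-descent refinement of effective connectivity.

    Iterates: simulate with the current weights, compute the model's
    grand-average phase-coherence matrix, and move every off-diagonal
    connection by ``epsilon * (FC_emp - FC_model)``.  Weights are clamped at
    zero and kept symmetric (both FC matrices are symmetric, so symmetry is
    preserved up to the clamp; it is enforced by averaging).  The descent
    objective is the Frobenius distance between the off-diagonal parts of
    the two phase-FC matrices; iteration stops when the best objective fails
    to improve by ``tol`` for 3 consecutive iterations, or at ``max_iter``.
    Doubling of the objective from its running minimum raises, suggesting a
    smaller ``epsilon``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    target = np.asarray(empirical_phase_fc, dtype=float)
    C = np.asarray(getattr(connectome, "weights", connectome), dtype=float).copy()
    if C.shape != target.shape:
        raise ValueError("connectome and target phase FC must share shape")
    np.fill_diagonal(C, 0.0)
    off = ~np.eye(C.shape[0], dtype=bool)
    run_seeds = spawn_seeds(seed, n_runs)
    history: list[tuple[int, float]] = []
    best = np.inf
    best_C = C.copy()
    stall = 0
    it = 0
    for it in range(1, max_iter + 1):
        fc_mods = []
        for s in run_seeds:
            res = simulate(C, params, duration_s, s)
            filtered = bandpass_filter(res.series, *band)
            phases = compute_phases(filtered, trim=trim)
            fc_mods.append(grand_average_phase_fc(phases))
        fc_mod = np.mean(fc_mods, axis=0)
        residual = target - fc_mod
        obj = float(np.linalg.norm(residual[off]))
        history.append((it, obj))
        if np.isfinite(best) and obj > 2.0 * best:
            raise RuntimeError(
                f"EC optimization diverged at iteration {it} "
                f"(objective {obj:.4f} vs best {best:.4f}); try a smaller epsilon"
            )
        if obj < best - tol:
            best, best_C, stall = obj, C.copy(), 0
        else:
            stall += 1
            if best == np.inf:
                best, best_C = obj, C.copy()
            if stall >= 3:
                break
        C = ec_update(C, target, fc_mod, epsilon)
    return ECState(weights=best_C, iteration=it, fit_history=history, epsilon=epsilon)
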
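"""Network-coupled Stuart-Landau (Hopf normal form) whole-brain model.

Each region n is a noisy oscillator at the edge of a supercritical Hopf
bifurcation, with local bifurcation parameter a_n and intrinsic angular
frequency omega_n:

    dx_n = [a_n - x_n^2 - y_n^2] x_n - omega_n y_n
           + G sum_p C_np (x_p - x_n) + beta eta_n(t)
    dy_n = [a_n - x_n^2 - y_n^2] y_n + omega_n x_n
           + G sum_p C_np (y_p - y_n) + beta eta_n(t)

For a_n > 0 an uncoupled noise-free node settles on a limit cycle of radius
sqrt(a_n) at frequency omega_n / 2 pi; for a_n < 0 it decays to a stable
fixed point and, with noise, produces low-amplitude fluctuations.  The x
channel stands in for the regional BOLD signal.  Coupling is diffusive
("difference coupling") through the connectome C, scaled by the single
global coupling weight G.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import RegionalTimeSeries

__all__ = [
    "HopfParams",
    "SimulationResult",
    "HopfSystem",
    "simulate",
    "estimate_intrinsic_frequencies",
]


@dataclass
class HopfParams:
    """Local and global parameters of the coupled-oscillator model.

    Parameters
    ----------
    a : (N,) array
        Local bifurcation parameters (dimensionless).  Zero places every
        node at the bifurcation edge, the working point used for fitted
        models; stimulation protocols shift entries positive
        (synchronization) or negative (noise).
    omega : (N,) array
        Intrinsic angular frequencies in rad/s (omega = 2 pi f).
    G : float
        Global coupling weight scaling the connectome, >= 0.
    beta : float
        Additive Gaussian noise standard deviation (default 0.02).
    dt_s, tr_s, transient_s : float
        Integration step, output sampling period and discarded initial
        transient, all in seconds.
    """

    a: np.ndarray
    omega: np.ndarray
    G: float = 0.0
    beta: float = 0.02
    dt_s: float = 0.1
    tr_s: float = 2.0
    transient_s: float = 60.0

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.a.shape != self.omega.shape or self.a.ndim != 1:
            raise ValueError("a and omega must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.omega))):
            raise ValueError("a and omega must be finite")
        if self.G < 0 or self.beta < 0:
            raise ValueError("G and beta must be non-negative")
        if not 0 < self.dt_s <= self.tr_s:
            raise ValueError("require 0 < dt_s <= tr_s")
        if self.transient_s < 0:
            raise ValueError("transient_s must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]

    def with_a(self, a: np.ndarray) -> "HopfParams":
        return replace(self, a=np.asarray(a, dtype=float).copy())

    @classmethod
    def uniform(
        cls,
        n_regions: int,
        a: float = 0.0,
        f_hz: float = 0.05,
        **kwargs,
    ) -> "HopfParams":
        """Homogeneous parameters: every node at ``a`` oscillating at ``f_hz``."""
        return cls(
            a=np.full(n_regions, float(a)),
            omega=np.full(n_regions, 2.0 * np.pi * float(f_hz)),
            **kwargs,
        )


@dataclass
class SimulationResult:
    series: RegionalTimeSeries
    seed: int
    params_snapshot: HopfParams
    connectome_id: str = ""


@dataclass
class HopfSystem:
    """A connectome (structural or effective) bundled with model parameters.

    This is the object the perturbation machinery operates on: ``connectome``
    must expose ``weights`` (N x N) and, for bilateral stimulation,
    ``homotopic_pairs``.
    """

    connectome: object
    params: HopfParams

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(getattr(self.connectome, "weights", self.connectome), float)

    @property
    def homotopic_pairs(self):
        pairs = getattr(self.connectome, "homotopic_pairs", None)
        if pairs is None:
            raise ValueError(
                "bilateral stimulation requires a connectome with a "
                "homotopic-pair table"
            )
        return pairs


def _coerce_weights(connectome, n: int) -> np.ndarray:
    w = np.asarray(getattr(connectome, "weights", connectome), dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectome weights must be a square matrix")
    if w.shape[0] != n:
        raise ValueError(
            f"connectome size {w.shape[0]} does not match parameter vectors ({n})"
        )
    return w


def simulate(
    connectome,
    params: HopfParams,
    duration_s: float,
    seed: int,
) -> SimulationResult:
    """Integrate the coupled model and return the x channel.

    The integrator is Euler-Maruyama with a rotation splitting: each step of
    size ``params.dt_s`` first applies an Euler update of the radial,
    coupling and noise terms (independent standard Gaussian increments
    scaled by ``beta * sqrt(dt)`` drive the x and y equations of every
    node), then rotates each node's (x, y) by exactly ``omega_n * dt``.
    Treating the stiff harmonic part exactly removes the spurious amplitude
    growth of a naive explicit Euler step, so the noise-free uncoupled
    limit-cycle radius equals sqrt(a) at the default step size.  After
    discarding ``transient_s`` seconds the x variable is decimated to one
    sample per ``tr_s`` (no anti-alias filter: the analysis band-pass
    downstream handles it).  Output length is
    ``floor((duration_s - transient_s) / tr_s)``.
    """
    n = params.n_regions
    weights = _coerce_weights(connectome, n)
    if duration_s <= params.transient_s:
        raise ValueError("duration_s must exceed transient_s")

    dt = params.dt_s
    steps_per_tr = int(round(params.tr_s / dt))
    if abs(steps_per_tr * dt - params.tr_s) > 1e-9:
        raise ValueError("tr_s must be an integer multiple of dt_s")
    n_out = int(np.floor((duration_s - params.transient_s) / params.tr_s))
    if n_out < 1:
        raise ValueError("duration too short: no output samples after transient")
    transient_steps = int(round(params.transient_s / dt))
    total_steps = transient_steps + (n_out - 1) * steps_per_tr

    rng = np.random.default_rng(seed)
    x = 0.1 * rng.standard_normal(n)
    y = 0.1 * rng.standard_normal(n)

    coupled = params.G > 0 and np.any(weights)
    if coupled:
        gC = params.G * weights
        g_row = gC.sum(axis=1)
    noise_scale = params.beta * np.sqrt(dt)
    cos_w = np.cos(params.omega * dt)
    sin_w = np.sin(params.omega * dt)

    out = np.empty((n, n_out))
    j = 0
    if transient_steps == 0:
        out[:, j] = x
        j += 1
    # overflow inside a diverging trajectory is caught by the guard below
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(1, total_steps + 1):
            lam = params.a - (x * x + y * y)
            dx = lam * x
            dy = lam * y
            if coupled:
                dx += gC @ x - g_row * x
                dy += gC @ y - g_row * y
            if params.beta > 0:
                eta = rng.standard_normal((2, n))
                x = x + dt * dx + noise_scale * eta[0]
                y = y + dt * dy + noise_scale * eta[1]
            else:
                x = x + dt * dx
                y = y + dt * dy
            x, y = cos_w * x - sin_w * y, sin_w * x + cos_w * y
            if step >= transient_steps and (step - transient_steps) % steps_per_tr == 0:
                if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
                    raise FloatingPointError(
                        f"integration diverged at step {step} "
                        f"(t = {step * dt:.1f} s); try a smaller dt_s"
                    )
                out[:, j] = x
                j += 1
                if j == n_out:
                    break

    series = RegionalTimeSeries(out, tr_s=params.tr_s, condition="simulated")
    return SimulationResult(
        series=series,
        seed=int(seed),
        params_snapshot=replace(params, a=params.a.copy(), omega=params.omega.copy()),
        connectome_id=str(getattr(connectome, "name", "")),
    )


def estimate_intrinsic_frequencies(
    dataset: list[RegionalTimeSeries],
    band: tuple[float, float] = (0.04, 0.07),
) -> np.ndarray:
    """Per-region intrinsic angular frequency from narrowband spectral peaks.

    For each subject the periodogram of every regional signal is evaluated
    and its peak located inside ``band``; the peak frequencies are averaged
    across subjects and returned as omega = 2 pi f (rad/s).  The search is
    restricted to the band, so even broadband input yields estimates inside
    it.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    f_lo, f_hi = band
    n = dataset[0].n_regions
    peaks = np.zeros((len(dataset), n))
    for s, ts in enumerate(dataset):
        if ts.n_regions != n:
            raise ValueError("all subjects must share the region count")
        fs = 1.0 / ts.tr_s
        if f_hi > fs / 2:
            raise ValueError(
                f"band upper edge {f_hi} Hz exceeds Nyquist {fs / 2:.4f} Hz"
            )
        freqs, psd = signal.periodogram(
            ts.values - ts.values.mean(axis=1, keepdims=True), fs=fs, axis=1
        )
        in_band = (freqs >= f_lo) & (freqs <= f_hi)
        if not np.any(in_band):
            raise ValueError(
                "no spectral bins inside the requested band; "
                "series too short for this resolution"
            )
        fb = freqs[in_band]
        peaks[s] = fb[np.argmax(psd[:, in_band], axis=1)]
    return 2.0 * np.pi * peaks.mean(axis=0)
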
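# Methods

This note records the models, numerical choices and experiment designs
behind `pmstates`, at the level of detail a user needs to judge what the
package's tests do and do not establish.

## Brain states as probabilistic metastable substate (PMS) spaces

A brain state is summarized by the recurrent patterns of instantaneous
phase coherence in regional BOLD-like signals. The chain is:

1. **Band-pass filter** each regional series to 0.02–0.1 Hz (zero-phase
   second-order Butterworth, per-region mean removed first). Zero-phase
   filtering matters because the subsequent analysis lives entirely in the
   Hilbert phase; a causal filter would shift phases by a
   frequency-dependent lag.
2. **Hilbert transform** per region gives the analytic signal
   x(t) = A(t)·cos θ(t); we keep θ(n,t) and A(n,t). Three samples at each
   end are discarded by default (`trim=3`) to guard against transform edge
   effects; the value is configurable and deliberately conservative for
   the session lengths we simulate.
3. **Phase-coherence tensor** dFC(n,p,t) = cos(θ(n,t) − θ(p,t)): 1 for
   regions moving together, 0 at 90°, −1 in anti-phase.
4. **Leading eigenvector** V1(t) of each N×N slice (largest-magnitude
   eigenvalue). V1·V1ᵀ is the best rank-1 approximation of the slice, so
   V1 is a 1/N-size summary of the instantaneous coherence pattern.
   Eigenvectors are defined up to sign; we flip each so that most elements
   are negative (ties: the largest-magnitude element is made negative).
   Any fixed convention works; without one, k-means would see v and −v as
   different patterns.
5. **k-means** (Euclidean, k-means++ seeding, 20 restarts, best inertia
   kept) over the pooled V1(t) of all subjects and conditions yields k
   centroids — the substates — plus per-sample labels. The silhouette
   score over a k range (default 2–8) guides the choice of k.
6. **Occupancies and switching.** Fractional occupancy is the fraction of
   samples assigned to each substate; the switching matrix is the
   row-normalized count of consecutive label pairs. Transitions are never
   counted across subject/session boundaries. A substate with no observed
   outgoing transition keeps a NaN row and is flagged, never silently
   replaced by a uniform row.

Between-condition differences in occupancy or transition probabilities are
assessed with a permutation-based paired t test: the statistic is the
paired t on per-subject differences, the null is built by within-pair sign
flips (1000 permutations by default, α = 0.05). When 2^n_pairs does not
exceed the requested permutation count the flip set is enumerated and the
p-value is exact.

## The whole-brain Hopf model

Each region is a Stuart–Landau oscillator — the normal form of a
supercritical Hopf bifurcation — coupled diffusively through the
connectome C:

    dx_n = [a_n − x_n² − y_n²]x_n − ω_n y_n + G Σ_p C_np (x_p − x_n) + β η_n(t)
    dy_n = [a_n − x_n² − y_n²]y_n + ω_n x_n + G Σ_p C_np (y_p − y_n) + β η_n(t)

For a_n > 0 the uncoupled noise-free node sits on a limit cycle of radius
√a_n at frequency ω_n/2π; for a_n < 0 it decays to a fixed point and, with
noise, emits low-amplitude fluctuations. x_n stands in for the regional
BOLD signal. Defaults follow the regime the model family is normally
operated in: noise SD β = 0.02, connectome off-diagonal mean ⟨C⟩ = 0.2,
intrinsic frequencies in the 0.04–0.07 Hz band (estimated from data as the
subject-averaged in-band periodogram peak per region), baseline a_n = 0
for fitted models (the bifurcation edge, where the model transitions
between noisy and oscillatory dynamics), TR = 2 s output sampling.

**Integration.** Euler–Maruyama with dt = 0.1 s and a rotation splitting:
each step applies an Euler update of the radial, coupling and noise terms,
then rotates each node's (x, y) exactly by ω_n·dt. A naive explicit Euler
step adds energy to the harmonic part (≈ +6% radius at a = 0.04, worse at
smaller a, at this dt), violating the √a limit-cycle radius; treating the
rotation exactly removes that bias, so the noise-free radius is correct at
the default step and halving dt changes the post-transient radius by well
under 0.5%. Noise enters as independent standard Gaussian increments in
the x and y equations of every node, scaled by β√dt. The first 60 s are
discarded by default; the x channel is decimated to one sample per TR
without an anti-alias filter, since the analysis band-pass follows
immediately. Divergence (non-finite or |x| > 1e6) raises with the step at
which it occurred.

## Fitting a model to an empirical state

Four complementary observables score a simulated model against an
empirical reference:

* **Static FC**: Pearson r between the strictly-upper-triangular entries
  of the grand-averaged correlation matrices.
* **FCD / KS**: the functional-connectivity-dynamics matrix is the cosine
  similarity between the upper triangles of dFC(t1) and dFC(t2); the
  statistic is the two-sample Kolmogorov–Smirnov distance between the
  pooled upper-triangular FCD entries of the empirical and simulated sets.
* **PMS / KL**: simulated eigenvectors are assigned to the *empirical*
  centroids (nearest Euclidean centroid; ties to the lowest index), and
  the symmetrized Kullback–Leibler distance
  0.5·[Σ P ln(P/Q) + Σ Q ln(Q/P)] (natural log) compares occupancy
  vectors. Probabilities are floored at 1e−6 and renormalized first: a
  substate never visited in a short simulation then contributes a large
  but finite penalty instead of an infinity. This clamp is why scan
  baselines saturate at a finite ceiling.
* **Markov entropy distance**: |S_emp − S_sim| where
  S = −Σ_i p(i) Σ_j P(i,j) ln P(i,j) and p is the stationary distribution
  solving Pᵀp = p (eigenvector of Pᵀ nearest eigenvalue 1, refined by
  power iteration to residual < 1e−12; 0·ln 0 := 0; natural log
  throughout, for consistency with the KL distance). Reducible chains have
  no unique stationary distribution and raise, naming the disconnected
  state groups; a fit result records NaN in that case rather than a
  fabricated value.

**Coupling sweep.** `sweep_coupling` scans G over a grid, simulating
`n_runs` sessions per grid point with the *same* run seeds everywhere so
grid points are compared on common noise. Two optima are reported:
`g_star_pms` (argmin of the PMS KL — the selection criterion) and
`g_star_fcd` (argmin of the FCD KS), which need not coincide.

**Effective connectivity.** Starting from the structural matrix,
`optimize_ec` iterates: simulate, compute the grand-average phase
coherence FC_ij = ⟨cos(φ_j − φ_i)⟩, and move every off-diagonal connection
by ε·(FC_emp − FC_model) with ε = 0.01, clamping at zero and
re-symmetrizing (both FC matrices are symmetric, so symmetry is preserved
up to the clamp). The descent objective is the Frobenius distance between
off-diagonal phase-FC parts; iteration stops when the best objective fails
to improve by `tol` for three consecutive iterations or at `max_iter`, and
a doubling of the objective from its running minimum aborts with a
suggestion to reduce ε. Updated weights are not re-normalized to
⟨C⟩ = 0.2; the learned deviations *are* the effective connectivity.

Evaluation budgets default to 3 runs per fit evaluation; experiments state
their own sizes below.

## In-silico stimulation

Stimulating a region means shifting its local bifurcation parameter:
positive shifts (synchronization protocol) push the node into sustained
oscillation, negative shifts (noise protocol) deepen its fixed point.
Stimulation is bilateral — one site is one homotopic pair, both members
shifted identically — and tonic (held for the whole simulation). The
scan evaluates every pair × intensity cell by the KL distance of the
perturbed model's occupancies to the target state, with all cells and the
baseline sharing run seeds; the greedy search accumulates sites at one
weak intensity, keeping at each step the pair that minimizes the KL to the
target (ties to the lowest pair index) and recording the fit to both
target and source states. Default intensity grids are 0–0.2 (step 0.02)
for synchronization and 0 to −0.6 (step −0.05) for noise.

## Synthetic data: what it emulates and what it does not

The generators produce connectomes (modular block structure plus explicit
homotopic pairs, normalized to ⟨C⟩ = 0.2 exactly), multi-subject datasets
simulated from the Hopf model itself (independent noise streams per
subject; generating parameters stored in a ground-truth record), planted
unit-vector clusters for clustering tests, and Markov label chains started
from a stationary distribution for occupancy/entropy oracles. All
randomness flows from one integer seed per call through a documented
derivation (`spawn_seeds`), so any stage reproduces in isolation.

The synthetic data emulates only the model's own statistical structure.
It contains no head motion, physiological noise, scanner drift,
hemodynamic convolution or parcellation error. Passing tests therefore
demonstrate that the algorithms are implemented correctly and that the
inference loops can recover planted ground truth under the model's own
assumptions — not that the pipeline is robust to the artifacts of real
fMRI.

## Recovery experiments (the checkable analogue of data-bound results)

Empirical optima (a fitted G, a KL fit value, named effective stimulation
sites) are properties of the cohort they were measured on and cannot be
reproduced without those recordings. The package instead verifies the
machinery by recovery on planted ground truth. Each experiment fixes an
architecture in which the planted quantity demonstrably leaves a footprint
in phase-coherence dynamics; sizes were chosen as the smallest that give
stable recovery.

**Coupling recovery.** 20 regions, 4 modules with weak (0.02)
between-module weights, homotopic strength 0.5, module-specific frequency
niches (0.042/0.05/0.058/0.066 Hz ± 0.001 jitter), a = 0, β = 0.02.
Data: 10 subjects × 1060 s at G_true = 0.5; sweep grid 0:1:0.1 with 3 runs
per point. Weak between-module coupling keeps the network below global
locking, and the frequency niches make cross-module alignment — hence the
occupancy vector — responsive to G through the whole grid; with uniform
frequencies or strong inter-module edges the occupancies saturate into a
single globally coherent substate and the KL curve flattens. The recovery
criterion is |G* − G_true| ≤ one grid step.

**EC recovery.** 16 regions, same modular architecture; ground-truth EC =
structural matrix with 5 between-module links strengthened by +0.4
(between-module links are where structural and effective connectivity
genuinely diverge, which is also why the update rule exists). The
"empirical" phase FC is the mean over 5 independent sessions of 660 s;
descent runs ε = 0.01, up to 150 iterations, 2 runs × 660 s per
iteration. Criterion: off-diagonal correlation of the recovered EC with
the truth exceeds the structural baseline correlation.

**Transition-site recovery (scan).** The source state is a two-rhythm
network: 7 background pairs oscillating supercritically (a = +0.3) at a
common 0.04 Hz — the dominant rhythm — and 3 "community" pairs held below
the bifurcation (a = −0.2) at 0.08 Hz, internally wired at 0.3, tied to
the background only weakly (0.03). Subthreshold nodes have their phases
slaved to the background rhythm (phase pull scales inversely with
amplitude), so the baseline shows a single globally aligned substate. The
target is the source with Δa = +0.6 added to the three community pairs:
ignited, they form a second strong rhythm that cannot lock across a
0.04 Hz detuning, and the community block rotates through
aligned/orthogonal/anti-phase configurations — three balanced substates
with the community's signature in the centroid loadings. Stimulating a
planted pair reproduces that rotation (the pair ignites and entrains its
community); stimulating a background pair only changes amplitudes, which
the phase-based analysis cannot see, so those cells sit exactly at the
baseline KL ceiling. The noise protocol (grid −0.05…−0.2, magnitudes
below the background's supercriticality so no background pair can be
pushed subcritical) likewise cannot create the rotation and never improves
on baseline. Criteria: the three planted pairs rank lowest-KL at the
matching intensity; min over the noise grid ≥ baseline.

**Greedy recovery.** Same two-rhythm logic with 2 independent detuned
rotor pairs (0.075 and 0.09 Hz, cross-wiring 0.012) and the background
pairs spread over 0.036–0.048 Hz so they lock into a compromise rhythm
with non-trivial phase lags. The target plants Δa = +0.45 on both rotor
pairs; the greedy search runs at the weaker Δa = +0.3. Igniting a rotor
is the only move that creates its anti-phase substate, so the two planted
pairs are chosen first; after both are ignited the remaining candidates
are background pairs, whose stimulation doubles their amplitude and shifts
the background's lag pattern away from the one frozen into *both* models'
centroids — target KL rises (the U shape) and source KL keeps rising
(monotone worsening). Target model k = 5 (fine enough to expose the lag
substates the late steps disturb), source model k = 2.

## Numerical and design choices worth knowing

* Filter band edges, trim, k, restarts, dt, TR, transient, β, ε and all
  grids are explicit parameters with the defaults above.
* The Methods-level choice between high-pass and band-pass filtering is
  resolved as band-pass 0.02–0.1 Hz; both edges are configuration keys.
* k-means uses the seed passed by the caller; identical seeds give
  identical labels.
* `pms_kl` flooring at 1e−6 bounds any single missing-substate penalty at
  about 0.5·p·ln(p·10⁶).
* Exact distance ties in centroid assignment and KL ties in the greedy
  selection resolve to the lowest index; both rules are documented
  behavior, not accidents of sort order.
* Degenerate inputs fail loudly: constant regions in correlation FC,
  reducible switching matrices in the entropy rate, asymmetric coherence
  slices, rows off the simplex in serialized models.

## Known limitations

* LEiDA is amplitude-blind: any change that only scales signal amplitudes
  (without moving phase relations) is invisible to occupancy-based fits.
  The recovery experiments are designed around this; users fitting real
  data should keep it in mind when interpreting null results.
* The KL-over-occupancies objective is a coarse summary; distinct
  dynamical regimes can produce similar occupancy vectors (and the scan
  can therefore be less site-specific at excessive intensities).
* Euler–Maruyama with exact rotation is first-order in the radial
  dynamics; dt = 0.1 s is adequate for the 0.01–0.1 Hz regimes used here
  but should be reduced for much faster oscillators.
* The synthetic generator's realism caveats above apply to every green
  test: correctness and recoverability are demonstrated, field robustness
  is not.
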
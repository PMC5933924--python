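# Methods

## Model

Dynamics are represented as a discrete-time Markov chain over M
conformational states at lag time τ: a row-stochastic transition matrix
**T**(τ) with stationary distribution π. All estimators in this package
impose detailed balance, π_i T_ij = π_j T_ji, which guarantees a real
spectrum, a top eigenvalue of exactly one, and that the top eigenvector is
the equilibrium distribution. Relaxation is summarized by the implied
timescales t_i = −τ / ln λ_i of the non-unit eigenvalues; eigenvalues are
computed from the symmetric similarity diag(π)^{1/2} T diag(π)^{−1/2},
which is exactly symmetric under detailed balance and numerically stable.
Eigenvalues ≥ 1 are reported as infinite timescales and eigenvalues ≤ 0 as
NaN (undefined at this lag).

## Supervised step

- **Features and metric.** Frames carry (Q, r): the fraction of native
  contacts (dimensionless, [0, 1]) and the donor–acceptor distance (Å).
  Clustering operates in the (Q, ε) plane with the Euclidean metric, where
  ε(r) = 1/(Λ + (r/R₀)⁶); both coordinates are order-one and
  dimensionless, so no extra scaling is applied.
- **Regular-space clustering** makes a single pass in input order: the
  first frame seeds the first center, and a frame becomes a new center iff
  it lies farther than the radius from every existing center. The
  implementation is a vectorized sweep that is exactly equivalent (a
  center never affects the decision of an earlier point) and is tested
  against the naive sequential loop. Re-clustering the centers at the same
  radius is the identity. Assignment is nearest-center with ties broken to
  the lowest index. The cluster radius is the resolution dial: 0.08 is a
  sensible default for dense simulation data; the synthetic benchmark uses
  0.15 so that per-state feature noise (σ_Q = 0.01, σ_r = 0.5 Å) cannot
  spawn satellite clusters.
- **Counting** uses a sliding window at lag τ (every pair s_t, s_{t+L}
  with L = τ/Δt), maximizing data use at long lags; trajectories are never
  concatenated, and trajectories shorter than L+1 frames are skipped with
  a warning. Estimation is restricted to the largest strongly connected
  component of the positive-count graph — weak connectivity is not enough
  for a stationary chain.
- **Reversible MLE.** The likelihood ∏ T_ij^{C_ij} is maximized under
  detailed balance by a fixed-point iteration on the equilibrium fluxes
  x_ij = π_i T_ij: x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j). The
  iterate is symmetric by construction, so every sweep satisfies detailed
  balance to machine precision; iteration stops when the normalized fluxes
  change by < 1e-12 (cap 10⁶ sweeps, with a logged residual on
  non-convergence).

## Emission model

A state s emits donor and acceptor photons in a τ-window as independent
Poisson counts with means n(1−ε_s)τ and n·ε_s·τ. The constant total rate n
encodes a gamma factor of one; it is estimated from data as total photons
divided by total observation time (default ~650 photons/ms territory for
high-illumination experiments, i.e. nτ ≈ 0.13 at τ = 200 ns). The window
probability is evaluated in log space via log-gamma; the equivalent
factorization into a total-count Poisson times a binomial split is kept as
an independent cross-check. Per-state efficiencies are clamped to
[1e-9, 1−1e-9]: a state at ε = 1 would assign zero probability to any
window containing a donor photon and the likelihood would be −∞ on legal
data. Efficiencies derive from per-state mean distances through
ε′ = 1/(Λ + (r/R₀)⁶) with Λ ≥ 1 (Λ = 1 is the weak-excitation Förster
form; Λ = 1.065 is appropriate under strong illumination). R₀ defaults to
56 Å and absorbs the orientation factor; the isotropic average κ² = 2/3 is
provided as a seeded Monte-Carlo estimator over uniform dipole
orientations (separation direction fixed along z by rotational symmetry),
converging as n^{−1/2}.

## Unsupervised step (Baum-Welch with detailed balance)

The photon window width must equal the MSM lag — that identity is what
couples the two data streams, and it is enforced, not assumed. The forward
recursion uses per-window scaling plus a per-window max-shift of the
emission row, which keeps every scale strictly positive for any counts;
agreement with a log-sum-exp evaluation and with exhaustive path
enumeration is tested to 1e-10.

Per EM iteration the E-step accumulates expected transition counts and
initial-state posteriors by forward–backward (vectorized over sequences of
equal length; emission probabilities are precomputed once since they never
change). The M-step reuses the reversible estimator on the expected
counts, so detailed balance holds after every iteration and π is re-derived
from T. Because the start distribution is π(T) rather than a free
parameter, the initial-state posteriors a_i must enter the M-step
objective (Σ_i a_i ln π_i + Σ_ij c_ij ln T_ij); the fixed point
generalizes to x_ij ← (C_ij + C_ji) / ((c_i−a_i)/x_i + (c_j−a_j)/x_j +
2A/S) with A = Σ a_i and S the total flux. With this term the EM bound is
exact and the log-likelihood is provably non-decreasing; a decrease beyond
1e-8 relative aborts with a diagnostic, since it can only be an
implementation bug. Convergence is declared at a relative log-likelihood
change below 1e-10 (default cap 10,000 iterations); both are configurable.

Baum-Welch never resurrects a zero transition probability, so the initial
matrix is noise-relaxed: uniform noise in (0, magnitude), default 1e-6, is
added to every entry, rows are renormalized, and the matrix is projected
back onto the reversible family by symmetrizing its equilibrium flux. The
same projection builds random initial matrices for the
local-minimum-comparison experiment. Emission parameters are held fixed
throughout: ε_s comes from simulation geometry and n from photon
statistics, and states sharing the same ε_s are not identifiable from
photons alone — the simulation-derived initial matrix is what breaks that
symmetry, which is the point of the two-step design.

## Synthetic benchmark

The generator stands in for both the simulation and the experiment, with a
known ground truth:

- **True model**: a linear folding chain of M states (unfolded → folded).
  The stationary distribution is a double well, π_i ∝ exp(−4h·x_i(1−x_i))
  with x_i = i/(M−1) and barrier h = 1.5 (in kT), giving basin populations
  ≈ 0.45/0.10/0.45 at M = 3. Nearest-neighbour transitions follow a
  Metropolis rule with base attempt probability 0.01 per τ-step, placing
  the slowest implied timescale near 450 τ ≈ 90 μs at τ = 200 ns — the
  folding timescale regime seen in high-illumination smFRET. Default
  per-state efficiencies are spread from 0.2 to 0.85 (spacing ≥ 0.15 for
  identifiability), with mean distances back-computed from ε and std 0.5 Å.
- **Biased model**: each row is mixed with weight `bias_strength` toward a
  jump into a spurious high-ε non-folded state (index M−2), then projected
  back to detailed balance. This both concentrates the equilibrium on the
  spurious state and makes the chain fast-mixing — reproducing the
  signature of force-field bias: a single sharp high-efficiency peak in
  the measured-efficiency histogram where the data show two.
- **Photon emission** follows the emission model exactly (Poisson counts
  per window); default nτ = 0.13, with 0.5 used in the recovery benchmarks
  for better per-window statistics. **Feature trajectories** draw (Q, r)
  from per-state Gaussians around the state observables (clamped to the
  physical ranges) while states evolve under the biased model.

What the generator does *not* emulate: within-state distance dynamics
(frames are i.i.d. around the state mean), dye photophysics (blinking,
background, gamma ≠ 1), non-Markovian memory, and the continuous
degeneracy of real conformational space. Passing tests therefore
demonstrate correctness of the estimators and the refinement mechanism
under the model's own assumptions, not robustness to model violations in
real data.

## Transition-path theory

Committors solve the dense linear system (I − T_II) q_I = T_IB·1 with
q = 0 on the source (unfolded) set and 1 on the sink (folded) set; the
dense solve is appropriate for the few hundred states typical here, and a
residual above 1e-10 (or a singular system, e.g. an absorbing
intermediate) raises with a diagnosis. The transition-state ensemble is
the committor band 0.4–0.6, excluding the boundary sets. Net reactive flux
is f⁺_ij = max(f_ij − f_ji, 0) with f_ij = π_i(1−q_i)T_ij q_j. "Largest
pathways" are extracted by the standard bottleneck decomposition: a
Dijkstra-style widest-path search (ties toward the lower state index)
finds the source→sink path maximizing the minimum edge flux, the path is
assigned its bottleneck flux, that flux is subtracted from its edges, and
the search repeats until the requested fraction of the total flux
(committor-weighted source outflow) is accounted for. For reversible
chains f⁺ is acyclic along increasing committor, so the full decomposition
conserves flux to rounding.

## Validation

Measured efficiency E = N_A/(N_A + N_D) is histogrammed per window on 50
uniform bins over [0, 1] (left-inclusive, last bin closed); windows are
re-aggregated by summation to larger widths (trailing partial groups are
dropped), and zero-photon windows are excluded (E is 0/0 there; exclusion
is logged). Histogram distance is the mean over bins of squared density
differences. Model-side histograms come from emulated datasets matching
the lengths of the real sequences, with independent realizations for error
bars. Mode counting smooths with a fixed 3-bin moving average and counts
peaks with a 5% relative topographic-prominence threshold — strict raw
local maxima on the flat valley of a finite-sample histogram are noise
wiggles, not modes.

k-fold cross-validation splits at the sequence level (sequences are the
independent units of the likelihood), refines on k−1 folds, and reports
held-out log-likelihood plus histogram MSE on both folds. Emulation for
the MSE uses the full dataset size on both sides so the emulation noise is
symmetric and the train/test contrast reflects the data side only.

## Problem sizes and numerical choices

The recovery and bias-correction benchmarks use 500 sequences × 2000
windows at nτ = 0.5 with up to 300 EM iterations — enough for ≈ 10³
basin-exchange events in the data, which determines how well the slow
timescale can be recovered (observed ≈ 5% at these sizes). The supervised
recovery uses 50 trajectories × 10⁴ steps. The cross-validation diagnostic
runs on a fast-mixing variant of the benchmark (base rate 0.2): with the
slow chain, sequences shorter than the basin dwell time make each fold's
basin composition a ~20-draw binomial and the fold-mean MSE heavy-tailed,
which measures sampling noise rather than overfitting.

## Known limitations

- Binned, constant-width photon counting only; photon-by-photon
  likelihoods and continuous-time chains are out of scope.
- States with equal emission efficiencies are unidentifiable from photons;
  results inherit the initial model's resolution of such degeneracies.
- The committor solver is dense (O(M³)); adequate for M up to a few
  hundred.
- The generator's independence assumptions (above) mean test performance
  bounds real-data performance only from the optimistic side.
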
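"""Stochastic MSM simulation, virtual photon emission, and the synthetic
ground-truth benchmark.

The benchmark emulates the study design end to end: a "true" folding-like
chain generates photon data (standing in for the experiment), while a
"biased" variant of the same chain plays the role of the simulation-derived
initial model whose transition probabilities over-emphasize a spurious
compact unfolded state.  Refining the biased model against photons emitted
from the true model should move it back toward the truth.

Benchmark construction.  States 0..M−1 form a linear folding chain from
unfolded (low ε) to folded (high ε).  The true stationary distribution is a
double well, π_i ∝ exp(−U_i) with U_i = 4·h·x_i(1−x_i) and x_i = i/(M−1):
both chain ends are populated basins and the middle is a low-population
transition state (barrier height h in units of kT).  Nearest-neighbour
transition probabilities follow a Metropolis rule with a base attempt
probability per τ-step, which gives detailed balance by construction; the
default base rate 0.01 puts the slowest implied timescale near 450 τ
(≈ 90 μs at τ = 200 ns, the folding scale seen in the photon data).  The
biased model mixes every row toward a jump into the spurious state
(index M−2: high ε yet not folded) and re-imposes detailed balance, which
both concentrates its equilibrium on that state and makes it fast-mixing —
the single-peaked efficiency histogram signature of the initial model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fret_physics import DEFAULT_R0, EmissionModel
from .hmm_refine import PhotonWindowSequence, _reversible_projection
from .msm_build import DiscreteTrajectory, FeatureTrajectory, MarkovStateModel

__all__ = [
    "BenchmarkScenario",
    "simulate_states",
    "simulate_state_ensemble",
    "emit_photons",
    "make_benchmark",
    "generate_feature_trajectories",
    "generate_photon_dataset",
]

#: Photon-window width / MSM lag used by the benchmark, ns.
BENCHMARK_LAG_NS = 200.0


@dataclass
class BenchmarkScenario:
    """Ground-truth and biased models sharing states and emission physics."""

    true_model: MarkovStateModel
    biased_model: MarkovStateModel
    emission: EmissionModel
    seed: int

    def __post_init__(self) -> None:
        if self.true_model.n_states != self.biased_model.n_states:
            raise ValueError("true and biased models must share the state space")
        if not np.isclose(self.true_model.lag, self.biased_model.lag):
            raise ValueError("true and biased models must share the lag time")


def _sample_chain(
    T: np.ndarray, pi: np.ndarray, n_steps: int, n_chains: int,
    rng: np.random.Generator, start: int | None,
) -> np.ndarray:
    """Inverse-CDF sampling of ``n_chains`` independent state paths."""
    cum_T = np.cumsum(T, axis=1)
    # Guard against rounding: the last column must close the unit interval.
    cum_T[:, -1] = 1.0
    out = np.empty((n_chains, n_steps), dtype=np.int64)
    if start is None:
        cum_pi = np.cumsum(pi)
        cum_pi[-1] = 1.0
        state = np.searchsorted(cum_pi, rng.random(n_chains), side="right")
    else:
        state = np.full(n_chains, start, dtype=np.int64)
    out[:, 0] = state
    u = rng.random((n_chains, n_steps - 1)) if n_steps > 1 else None
    for t in range(1, n_steps):
        rows = cum_T[state]
        state = (rows < u[:, t - 1, None]).sum(axis=1)
        out[:, t] = state
    return out


def simulate_states(
    model: MarkovStateModel,
    n_steps: int,
    seed: int | None = None,
    start: int | None = None,
) -> DiscreteTrajectory:
    """Sample a state trajectory from T(τ): at every step a uniform random
    number selects the next state by the inverse CDF of the current row.
    The initial state is drawn from π unless ``start`` is given."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    path = _sample_chain(
        model.transition_matrix, model.stationary, n_steps, 1, rng, start
    )[0]
    return DiscreteTrajectory(states=path, time_step=model.lag)


def simulate_state_ensemble(
    model: MarkovStateModel,
    n_trajs: int,
    n_steps: int,
    seed: int | None = None,
    start: int | None = None,
) -> np.ndarray:
    """Sample ``n_trajs`` independent state paths at once; returns an
    (n_trajs, n_steps) index array."""
    if n_steps < 1 or n_trajs < 1:
        raise ValueError("n_trajs and n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_chain(
        model.transition_matrix, model.stationary, n_steps, n_trajs, rng, start
    )


def emit_photons(
    states: DiscreteTrajectory | np.ndarray,
    emission: EmissionModel,
    seed: int | None = None,
) -> PhotonWindowSequence:
    """Virtually emit photons from a state trajectory: per window,
    N_D ~ Poisson(n(1−ε_s)τ) and N_A ~ Poisson(n ε_s τ), independently."""
    s = states.states if isinstance(states, DiscreteTrajectory) else np.asarray(states)
    if s.size == 0:
        raise ValueError("state trajectory is empty")
    rng = np.random.default_rng(seed)
    n_d = rng.poisson(emission.mean_donor_counts[s])
    n_a = rng.poisson(emission.mean_acceptor_counts[s])
    return PhotonWindowSequence(
        windows=np.column_stack([n_d, n_a]), window_width=emission.window
    )


def _double_well_stationary(M: int, barrier: float) -> np.ndarray:
    x = np.linspace(0.0, 1.0, M)
    pi = np.exp(-4.0 * barrier * x * (1.0 - x))
    return pi / pi.sum()


def _metropolis_chain(pi: np.ndarray, base_rate: float) -> np.ndarray:
    """Nearest-neighbour birth–death chain with Metropolis acceptance:
    T_{i,i±1} = base_rate · min(1, π_{i±1}/π_i); reversible w.r.t. π."""
    M = pi.size
    T = np.zeros((M, M))
    for i in range(M):
        if i + 1 < M:
            T[i, i + 1] = base_rate * min(1.0, pi[i + 1] / pi[i])
        if i - 1 >= 0:
            T[i, i - 1] = base_rate * min(1.0, pi[i - 1] / pi[i])
        T[i, i] = 1.0 - T[i].sum()
    return T


def make_benchmark(
    M: int = 3,
    bias_strength: float = 0.5,
    seed: int = 0,
    efficiencies: Sequence[float] | None = None,
    n_tau: float = 0.13,
    barrier: float = 1.5,
    base_rate: float = 0.01,
    lag: float = BENCHMARK_LAG_NS,
    r0: float = DEFAULT_R0,
) -> BenchmarkScenario:
    """Build the folding-chain benchmark (see module docstring).

    Parameters
    ----------
    M : int
        Number of states (≥ 3): state 0 unfolded, state M−1 folded, middle
        states intermediate; index M−2 doubles as the spurious state.
    bias_strength : float in [0, 1)
        Row-mixing weight toward a jump into the spurious state; 0 makes the
        biased model identical to the truth.
    efficiencies : optional sequence of M values
        Per-state expected FRET efficiencies; default linspace(0.2, 0.85, M).
    n_tau : float
        Expected total photons per window (default 0.13 ≈ 650 photons/ms at
        a 200 ns window).
    barrier, base_rate : float
        Double-well barrier height (kT) and Metropolis attempt probability
        per step of the true chain.
    """
    if M < 3:
        raise ValueError("the benchmark needs at least 3 states")
    if not (0.0 <= bias_strength < 1.0):
        raise ValueError("bias_strength must lie in [0, 1)")
    eps = (
        np.linspace(0.2, 0.85, M)
        if efficiencies is None
        else np.asarray(efficiencies, dtype=float)
    )
    if eps.shape != (M,):
        raise ValueError("efficiencies must have length M")
    pi_true = _double_well_stationary(M, barrier)
    T_true = _metropolis_chain(pi_true, base_rate)
    # State observables: Q along the chain; mean r back-computed from ε.
    q_centers = np.linspace(0.05, 0.95, M)
    mean_r = r0 * ((1.0 - eps) / eps) ** (1.0 / 6.0)
    std_r = np.full(M, 0.5)
    centers = np.column_stack([q_centers, eps])
    true_model = MarkovStateModel(
        transition_matrix=T_true, lag=lag, stationary=pi_true,
        state_centers=centers, state_mean_r=mean_r, state_std_r=std_r,
    )
    spurious = M - 2
    if bias_strength == 0.0:
        biased_model = MarkovStateModel(
            transition_matrix=T_true.copy(), lag=lag, stationary=pi_true.copy(),
            state_centers=centers, state_mean_r=mean_r, state_std_r=std_r,
        )
    else:
        jump = np.zeros((M, M))
        jump[:, spurious] = 1.0
        T_biased = (1.0 - bias_strength) * T_true + bias_strength * jump
        biased_model = _reversible_projection(T_biased, lag)
        biased_model.state_centers = centers
        biased_model.state_mean_r = mean_r
        biased_model.state_std_r = std_r
    emission = EmissionModel(
        efficiencies=eps, total_rate=n_tau / lag, window=lag, r0=r0
    )
    return BenchmarkScenario(
        true_model=true_model, biased_model=biased_model,
        emission=emission, seed=seed,
    )


def generate_feature_trajectories(
    scenario: BenchmarkScenario,
    n_trajs: int,
    n_steps: int,
    seed: int | None = None,
    q_spread: float = 0.01,
    r_spread: float = 0.5,
) -> list[FeatureTrajectory]:
    """Surrogate feature trajectories for the supervised step.

    Simulates states from the biased model (the stand-in for force-field
    dynamics) and draws per-frame (Q, r) from per-state Gaussians centred at
    the state observables, clamping Q to [0, 1] and r to ≥ 0.
    """
    if n_trajs < 1 or n_steps < 1:
        raise ValueError("n_trajs and n_steps must be >= 1")
    model = scenario.biased_model
    if model.state_centers is None or model.state_mean_r is None:
        raise ValueError("scenario models need state observables")
    rng = np.random.default_rng(seed)
    paths = _sample_chain(
        model.transition_matrix, model.stationary, n_steps, n_trajs, rng, None
    )
    out = []
    for k in range(n_trajs):
        s = paths[k]
        q = model.state_centers[s, 0] + rng.normal(0.0, q_spread, size=n_steps)
        r = model.state_mean_r[s] + rng.normal(0.0, r_spread, size=n_steps)
        out.append(
            FeatureTrajectory(
                time_step=model.lag,
                q=np.clip(q, 0.0, 1.0),
                r=np.maximum(r, 0.0),
                id=f"traj{k:04d}",
            )
        )
    return out


def generate_photon_dataset(
    model: MarkovStateModel,
    emission: EmissionModel,
    n_seqs: int,
    n_windows: int,
    seed: int | None = None,
) -> list[PhotonWindowSequence]:
    """Emit ``n_seqs`` photon sequences of ``n_windows`` windows each from a
    model: states are simulated in one vectorized batch, photons drawn per
    window from the per-state Poisson rates."""
    rng = np.random.default_rng(seed)
    paths = _sample_chain(
        model.transition_matrix, model.stationary, n_windows, n_seqs, rng, None
    )
    n_d = rng.poisson(emission.mean_donor_counts[paths])
    n_a = rng.poisson(emission.mean_acceptor_counts[paths])
    return [
        PhotonWindowSequence(
            windows=np.column_stack([n_d[k], n_a[k]]),
            window_width=emission.window,
            id=f"seq{k:05d}",
        )
        for k in range(n_seqs)
    ]
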
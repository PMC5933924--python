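"""Refinement of T(τ) against photon time series by constrained Baum-Welch.

The unsupervised step treats the simulation-derived MSM states as hidden
states of an HMM whose observations are donor/acceptor photon counts in
τ-windows.  The total log-likelihood over K independent photon sequences,

    ln L(T) = Σ_k ln Σ_{s_1..s_I} π(s_1) h(o_1|s_1) Π_i T_{s_{i-1} s_i} h(o_i|s_i),

is maximized over T alone (the emission model stays fixed: per-state
efficiencies come from the simulation geometry, the total count rate from
photon statistics).  Each M-step re-estimates a *reversible* transition
matrix from the expected transition counts, so detailed balance holds after
every iteration and π — which doubles as the start distribution p(s₁) — is
always the equilibrium distribution of the current T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fret_physics import EmissionModel
from .msm_build import MarkovStateModel, estimate_reversible_T

__all__ = [
    "PhotonWindowSequence",
    "RefinementResult",
    "bin_photons",
    "forward_loglik",
    "baum_welch",
    "perturb_initial",
    "random_initial",
    "read_photon_file",
    "read_binned_file",
    "write_binned_file",
]

logger = logging.getLogger(__name__)


@dataclass
class PhotonWindowSequence:
    """Donor/acceptor photon counts per τ-window of one photon trajectory."""

    windows: np.ndarray
    window_width: float
    id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=np.int64)
        if w.ndim != 2 or w.shape[1] != 2 or w.shape[0] < 1:
            raise ValueError("windows must be a nonempty (I, 2) integer array")
        if np.any(w < 0):
            raise ValueError("photon counts must be non-negative")
        self.windows = w
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def total_photons(self) -> int:
        return int(self.windows.sum())


@dataclass
class RefinementResult:
    """Outcome of a Baum-Welch refinement run.

    ``loglik_trace[i]`` is the total log-likelihood of the parameters at the
    start of iteration i (so trace[0] belongs to the initial model);
    ``db_residual_trace[i]`` the detailed-balance residual after the i-th
    M-step.
    """

    refined_model: MarkovStateModel
    loglik_trace: np.ndarray
    db_residual_trace: np.ndarray
    n_iterations: int
    converged: bool


def bin_photons(
    arrivals: Sequence[tuple[float, str]],
    window_width: float,
    n_windows: int | None = None,
    id: str = "",
) -> PhotonWindowSequence:
    """Bin photon arrivals into contiguous half-open windows [kw, (k+1)w).

    ``arrivals`` are (time_ns, channel) pairs with channel 'D' or 'A' and
    nondecreasing times measured from the segment origin t = 0.  Empty
    interior windows are retained as (0, 0).  ``n_windows`` forces the total
    span (required when the sequence may end with empty windows or contains
    no photons at all).
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    times = np.array([t for t, _ in arrivals], dtype=float)
    channels = [c for _, c in arrivals]
    bad = sorted({c for c in channels} - {"D", "A"})
    if bad:
        raise ValueError(f"unknown photon channel code(s): {bad}")
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("photon arrival times must be nondecreasing")
    if times.size and times[0] < 0:
        raise ValueError("photon arrival times must be non-negative")
    idx = np.floor_divide(times, window_width).astype(np.int64) if times.size else np.array([], dtype=np.int64)
    needed = int(idx[-1]) + 1 if idx.size else 0
    if n_windows is None:
        n_windows = needed
        if n_windows == 0:
            raise ValueError("no photons and no n_windows given: span unknown")
    elif needed > n_windows:
        raise ValueError("photon arrival beyond the requested span")
    counts = np.zeros((n_windows, 2), dtype=np.int64)
    is_donor = np.array([c == "D" for c in channels], dtype=bool)
    np.add.at(counts[:, 0], idx[is_donor], 1)
    np.add.at(counts[:, 1], idx[~is_donor], 1)
    return PhotonWindowSequence(windows=counts, window_width=window_width, id=id)


# ---------------------------------------------------------------------------
# Forward / forward-backward machinery
# ---------------------------------------------------------------------------

def _check_coupling(model: MarkovStateModel, seq: PhotonWindowSequence) -> None:
    # The photon window width must equal the MSM lag time: the HMM advances
    # one T(τ) step per window, which is what couples the two data streams.
    if not np.isclose(seq.window_width, model.lag, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"photon window width ({seq.window_width} ns) must equal the MSM "
            f"lag time ({model.lag} ns)"
        )


def _scaled_emissions(emission: EmissionModel, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Emission probabilities rescaled by their per-window maximum.

    Returns (B, m) with B = exp(logB − m[:, None]); the log of the true
    likelihood is recovered by adding Σ m to the accumulated log scales.
    """
    logB = emission.log_emission_matrix(windows)
    m = logB.max(axis=-1)
    return np.exp(logB - m[..., None]), m


def forward_loglik(
    model: MarkovStateModel, emission: EmissionModel, seq: PhotonWindowSequence
) -> float:
    """Log-likelihood ln L_k of one photon sequence under (T, π, h).

    Forward recursion with per-window scaling; the initial distribution is
    the model's stationary vector π.  Finite for any input because emission
    probabilities are strictly positive.
    """
    _check_coupling(model, seq)
    if model.n_states != emission.n_states:
        raise ValueError("model and emission disagree on the number of states")
    B, m = _scaled_emissions(emission, seq.windows)
    T = model.transition_matrix
    alpha = model.stationary * B[0]
    c = alpha.sum()
    ll = np.log(c) + m[0]
    alpha = alpha / c
    for i in range(1, len(seq)):
        alpha = (alpha @ T) * B[i]
        c = alpha.sum()
        ll += np.log(c) + m[i]
        alpha = alpha / c
    return float(ll)


def _forward_backward_batch(
    T: np.ndarray, pi: np.ndarray, B: np.ndarray, m: np.ndarray
) -> tuple[float, np.ndarray]:
    """E-step over a batch of equal-length sequences.

    Parameters
    ----------
    B, m : arrays of shape (K, I, M) and (K, I)
        Max-rescaled emission probabilities and their log offsets.

    Returns
    -------
    loglik : float
        Total log-likelihood of the batch.
    counts : (M, M) array
        Expected transition counts summed over sequences and steps.
    initial : (M,) array
        Summed initial-state posteriors Σ_k γ_1(k, ·).
    """
    K, I, M = B.shape
    alpha = np.empty((K, I, M))
    c = np.empty((K, I))
    a = pi[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for i in range(1, I):
        a = (alpha[:, i - 1, :] @ T) * B[:, i, :]
        c[:, i] = a.sum(axis=1)
        alpha[:, i, :] = a / c[:, i, None]
    loglik = float(np.log(c).sum() + m.sum())
    # Backward pass with on-the-fly accumulation of the pair counts
    # G_ab = Σ_{k,i} α̂_a(k,i) · B_b(k,i+1) β̂_b(k,i+1) / c(k,i+1);
    # expected transition counts are then T ∘ G.
    G = np.zeros((M, M))
    beta = np.ones((K, M))
    for i in range(I - 2, -1, -1):
        w = B[:, i + 1, :] * beta / c[:, i + 1, None]
        G += alpha[:, i, :].T @ w
        beta = w @ T.T
    gamma1 = (alpha[:, 0, :] * beta).sum(axis=0)
    return loglik, T * G, gamma1


def _group_by_length(sequences: Sequence[PhotonWindowSequence]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for k, s in enumerate(sequences):
        groups.setdefault(len(s), []).append(k)
    return groups


def baum_welch(
    T_init: MarkovStateModel,
    sequences: Sequence[PhotonWindowSequence],
    emission: EmissionModel,
    max_iter: int = 10_000,
    tol: float = 1e-10,
    seed: int | None = None,
) -> RefinementResult:
    """Baum-Welch EM under the detailed-balance constraint.

    E-step: forward-backward expected transition counts, summed over all
    sequences (vectorized over sequences of equal length).  M-step: the
    reversible maximum-likelihood estimator on the expected counts, so
    detailed balance holds exactly after every iteration and π is re-derived
    as the equilibrium distribution of the updated T.  The initial-state
    posteriors enter the M-step objective through the stationary vector
    (π is not a free parameter but a function of T), which keeps the EM
    bound exact.  Emission parameters are held fixed throughout.

    Stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations.  A log-likelihood decrease beyond 1e-8
    relative slack raises ``RuntimeError`` — EM guarantees monotonicity, so
    a violation indicates an implementation defect, not a data problem.
    ``seed`` is accepted for interface uniformity; the algorithm itself is
    deterministic.
    """
    if not sequences:
        raise ValueError("no photon sequences given")
    for s in sequences:
        _check_coupling(T_init, s)
    if T_init.n_states != emission.n_states:
        raise ValueError("model and emission disagree on the number of states")
    # Emission probabilities never change during EM: precompute per batch.
    groups = _group_by_length(sequences)
    batches = []
    for length, idxs in sorted(groups.items()):
        windows = np.stack([sequences[k].windows for k in idxs])
        logB = emission.log_emission_matrix(windows.reshape(-1, 2)).reshape(
            len(idxs), length, emission.n_states
        )
        m = logB.max(axis=-1)
        batches.append((np.exp(logB - m[..., None]), m))

    model = T_init
    ll_trace: list[float] = []
    db_trace: list[float] = []
    converged = False
    n_done = 0
    for _ in range(max_iter):
        total_ll = 0.0
        counts = np.zeros((model.n_states, model.n_states))
        init_counts = np.zeros(model.n_states)
        for B, m in batches:
            ll, cnt, gamma1 = _forward_backward_batch(
                model.transition_matrix, model.stationary, B, m
            )
            total_ll += ll
            counts += cnt
            init_counts += gamma1
        if ll_trace and total_ll < ll_trace[-1] - 1e-8 * abs(ll_trace[-1]):
            raise RuntimeError(
                "EM log-likelihood decreased beyond tolerance "
                f"({ll_trace[-1]:.6f} -> {total_ll:.6f}); this indicates an "
                "implementation bug"
            )
        improved = bool(ll_trace) and abs(total_ll - ll_trace[-1]) <= tol * abs(
            ll_trace[-1]
        )
        ll_trace.append(total_ll)
        if improved:
            converged = True
            break
        new_model = estimate_reversible_T(
            counts, lag=model.lag, initial_counts=init_counts
        )
        new_model.state_centers = T_init.state_centers
        new_model.state_mean_r = T_init.state_mean_r
        new_model.state_std_r = T_init.state_std_r
        db_trace.append(new_model.detailed_balance_residual())
        model = new_model
        n_done += 1
    return RefinementResult(
        refined_model=model,
        loglik_trace=np.array(ll_trace),
        db_residual_trace=np.array(db_trace),
        n_iterations=n_done,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

def _stationary_of(T: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reversible_projection(T: np.ndarray, lag: float) -> MarkovStateModel:
    """Project a row-stochastic matrix onto the reversible family by
    symmetrizing its equilibrium flux x_ij = π_i T_ij."""
    pi = _stationary_of(T)
    x = pi[:, None] * T
    x = 0.5 * (x + x.T)
    pi_new = x.sum(axis=1)
    T_new = x / pi_new[:, None]
    T_new /= T_new.sum(axis=1, keepdims=True)
    return MarkovStateModel(
        transition_matrix=T_new, lag=lag, stationary=pi_new / pi_new.sum()
    )


def perturb_initial(
    model: MarkovStateModel, magnitude: float = 1e-6, seed: int | None = None
) -> MarkovStateModel:
    """Noise-relaxed initial condition for Baum-Welch.

    Baum-Welch keeps zero transition probabilities at zero forever, freezing
    the connectivity of the initial matrix.  Adding very weak uniform noise
    in (0, magnitude) to every entry, renormalizing rows and re-imposing
    detailed balance (reversible flux projection) makes all entries strictly
    positive while perturbing the model by at most O(magnitude).
    """
    if not (0 < magnitude < 1):
        raise ValueError("magnitude must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    T = model.transition_matrix + rng.uniform(0.0, magnitude, size=model.transition_matrix.shape)
    T /= T.sum(axis=1, keepdims=True)
    out = _reversible_projection(T, model.lag)
    out.state_centers = model.state_centers
    out.state_mean_r = model.state_mean_r
    out.state_std_r = model.state_std_r
    return out


def random_initial(M: int, seed: int | None = None, lag: float = 1.0) -> MarkovStateModel:
    """Row-normalized positive random matrix projected to detailed balance;
    the initial condition for the local-minimum comparison experiment."""
    if M < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    T = rng.uniform(0.0, 1.0, size=(M, M)) + 1e-12
    T /= T.sum(axis=1, keepdims=True)
    return _reversible_projection(T, lag)


# ---------------------------------------------------------------------------
# File formats: photon TSVs
# ---------------------------------------------------------------------------

def read_photon_file(path: str | Path, window_width: float) -> list[PhotonWindowSequence]:
    """Read raw photon arrivals (TSV: trajectory_id, time_ns, channel) and
    bin each trajectory into τ-windows.  Arrival times are taken relative to
    each trajectory's own origin (its times must start within the first
    window of the segment)."""
    df = pd.read_csv(path, sep="\t", dtype={"trajectory_id": str})
    required = {"trajectory_id", "time_ns", "channel"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    seqs = []
    for tid, grp in df.groupby("trajectory_id", sort=False):
        arrivals = list(zip(grp["time_ns"].to_numpy(dtype=float), grp["channel"]))
        seqs.append(bin_photons(arrivals, window_width, id=str(tid)))
    if not seqs:
        raise ValueError(f"{path}: no photon trajectories found")
    return seqs


def read_binned_file(path: str | Path, window_width: float) -> list[PhotonWindowSequence]:
    """Read pre-binned counts (TSV: trajectory_id, window_index, n_donor,
    n_acceptor); missing window indices are zero-count windows."""
    df = pd.read_csv(path, sep="\t", dtype={"trajectory_id": str})
    required = {"trajectory_id", "window_index", "n_donor", "n_acceptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    seqs = []
    for tid, grp in df.groupby("trajectory_id", sort=False):
        idx = grp["window_index"].to_numpy(dtype=np.int64)
        if np.any(idx < 0):
            raise ValueError(f"{path}: negative window index in {tid}")
        counts = np.zeros((int(idx.max()) + 1, 2), dtype=np.int64)
        counts[idx, 0] = grp["n_donor"].to_numpy(dtype=np.int64)
        counts[idx, 1] = grp["n_acceptor"].to_numpy(dtype=np.int64)
        seqs.append(PhotonWindowSequence(windows=counts, window_width=window_width, id=str(tid)))
    if not seqs:
        raise ValueError(f"{path}: no photon trajectories found")
    return seqs


def write_binned_file(seqs: Sequence[PhotonWindowSequence], path: str | Path) -> None:
    frames = []
    for k, s in enumerate(seqs):
        tid = s.id or f"seq{k:05d}"
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": tid,
                    "window_index": np.arange(len(s)),
                    "n_donor": s.windows[:, 0],
                    "n_acceptor": s.windows[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
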
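"""Supervised construction of a Markov state model from feature trajectories.

The pipeline discretizes simulation trajectories, described per frame by the
fraction of native contacts Q and the donor–acceptor distance r, into states
by regular-space clustering in the (Q, ε) plane (ε the expected FRET
efficiency of the frame), counts lag-τ transitions between states with a
sliding window, and estimates a transition matrix T(τ) that maximizes the
Markov-chain likelihood subject to detailed balance.  Model quality is probed
through the implied timescales t_i = −τ / ln λ_i of the eigenvalues of T(τ).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .fret_physics import DEFAULT_LAMBDA, DEFAULT_R0, generalized_efficiency

__all__ = [
    "FeatureTrajectory",
    "ClusterModel",
    "DiscreteTrajectory",
    "CountMatrix",
    "MarkovStateModel",
    "expected_efficiency_trajectory",
    "regular_space_cluster",
    "assign_states",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible_T",
    "implied_timescales",
    "build_msm",
    "read_feature_trajectory",
    "write_feature_trajectory",
    "save_msm",
    "load_msm",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTrajectory:
    """Per-frame (Q, r) features of one simulation trajectory.

    ``q`` is the fraction of native contacts (dimensionless, in [0, 1]),
    ``r`` the donor–acceptor distance in Å, ``time_step`` the frame spacing
    in ns.
    """

    time_step: float
    q: np.ndarray
    r: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.q.shape != self.r.shape or self.q.ndim != 1:
            raise ValueError("q and r must be 1-D arrays of equal length")
        if self.q.size < 2:
            raise ValueError("a feature trajectory needs at least 2 frames")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("native-contact fractions must lie in [0, 1]")
        if np.any(self.r < 0):
            raise ValueError("donor-acceptor distances must be non-negative")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class ClusterModel:
    """Regular-space cluster centers in the (Q, ε) plane with a shared
    exclusion radius."""

    centers: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[0] == 0:
            raise ValueError("centers must be a nonempty (k, d) array")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class DiscreteTrajectory:
    """State-index sequence of one trajectory at fixed time step (ns)."""

    states: np.ndarray
    time_step: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D index sequence")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class CountMatrix:
    """Lag-τ transition counts between discrete states."""

    counts: np.ndarray
    lag: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lag <= 0:
            raise ValueError("lag must be positive")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class MarkovStateModel:
    """Discrete-state Markov model: row-stochastic T(τ) with stationary
    distribution π and optional per-state observables.

    ``state_centers`` are (Q, ε) coordinates, ``state_mean_r``/``state_std_r``
    the mean and standard deviation of the donor–acceptor distance within
    each state (Å).  π doubles as the initial-state distribution p(s₁) of
    the photon-sequence likelihood.
    """

    transition_matrix: np.ndarray
    lag: float
    stationary: np.ndarray
    state_centers: np.ndarray | None = None
    state_mean_r: np.ndarray | None = None
    state_std_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < -1e-15) or np.any(T > 1.0 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowdev = np.max(np.abs(T.sum(axis=1) - 1.0))
        if rowdev > 1e-12:
            raise ValueError(f"rows of T must sum to 1 (max deviation {rowdev:.2e})")
        self.transition_matrix = np.clip(T, 0.0, 1.0)
        pi = np.asarray(self.stationary, dtype=float)
        if pi.shape != (T.shape[0],):
            raise ValueError("stationary vector has wrong shape")
        if np.any(pi < -1e-15) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("stationary vector must be a probability distribution")
        self.stationary = np.clip(pi, 0.0, 1.0)
        for name in ("state_centers", "state_mean_r", "state_std_r"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def detailed_balance_residual(self) -> float:
        """max_ij |π_i T_ij − π_j T_ji| — zero for a reversible chain."""
        flux = self.stationary[:, None] * self.transition_matrix
        return float(np.max(np.abs(flux - flux.T)))


def expected_efficiency_trajectory(
    traj: FeatureTrajectory,
    r0: float = DEFAULT_R0,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Per-frame expected FRET efficiency ε computed from the trajectory's
    donor–acceptor distances via Förster theory (saturation parameter Λ)."""
    return np.asarray(generalized_efficiency(traj.r, r0=r0, lam=lam))


def regular_space_cluster(points: np.ndarray, radius: float) -> ClusterModel:
    """Regular-space clustering: partition feature space equidistantly.

    A single pass in input order; the first point seeds the first center and
    a point becomes a new center iff its Euclidean distance to every existing
    center exceeds ``radius``.  Implemented with an equivalent vectorized
    sweep (a center added later never affects the decision for an earlier
    point).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] == 0:
        raise ValueError("cannot cluster an empty point set")
    if radius <= 0:
        raise ValueError("radius must be positive")
    center_idx = [0]
    dmin = np.linalg.norm(pts - pts[0], axis=1)
    while True:
        outside = np.nonzero(dmin > radius)[0]
        if outside.size == 0:
            break
        j = int(outside[0])
        center_idx.append(j)
        np.minimum(dmin, np.linalg.norm(pts - pts[j], axis=1), out=dmin)
    return ClusterModel(centers=pts[center_idx], radius=radius)


def assign_states(points: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Map each point to the nearest cluster center (Voronoi assignment).

    Ties are broken toward the lowest center index (argmin convention).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return np.argmin(cdist(pts, model.centers), axis=1)


def assign_trajectory(
    traj: FeatureTrajectory,
    model: ClusterModel,
    r0: float = DEFAULT_R0,
    lam: float = DEFAULT_LAMBDA,
) -> DiscreteTrajectory:
    """Discretize a feature trajectory in (Q, ε) space with a cluster model."""
    eps = expected_efficiency_trajectory(traj, r0=r0, lam=lam)
    pts = np.column_stack([traj.q, eps])
    return DiscreteTrajectory(states=assign_states(pts, model), time_step=traj.time_step)


def count_transitions(
    dtrajs: Sequence[DiscreteTrajectory], lag: float, n_states: int
) -> CountMatrix:
    """Sliding-window transition counts at lag time ``lag``.

    Every pair (s_t, s_{t+L}) within one trajectory increments the count
    matrix, where L = lag / time_step must be a positive integer;
    trajectories are never concatenated.  Trajectories shorter than L+1
    frames contribute nothing (a warning is logged).
    """
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for k, dtraj in enumerate(dtrajs):
        ratio = lag / dtraj.time_step
        L = int(round(ratio))
        if L < 1 or abs(ratio - L) > 1e-9:
            raise ValueError(
                f"lag {lag} is not a positive integer multiple of time step {dtraj.time_step}"
            )
        s = dtraj.states
        if s.size < L + 1:
            logger.warning("trajectory %d shorter than lag+1 frames; skipped", k)
            continue
        np.add.at(C, (s[:-L], s[L:]), 1)
    return CountMatrix(counts=C, lag=lag)


def largest_connected_set(counts: CountMatrix) -> tuple[np.ndarray, CountMatrix]:
    """Largest strongly connected component of the positive-count graph.

    Returns the kept (original) state indices in ascending order and the
    count matrix restricted to them; positions in the returned index array
    define the remapped 0-based state labels.
    """
    C = counts.counts
    if not np.any(C > 0):
        raise ValueError("count matrix has no transitions")
    n_comp, labels = connected_components(
        csr_matrix((C > 0).astype(np.int8)), directed=True, connection="strong"
    )
    sizes = np.bincount(labels, minlength=n_comp)
    # Tie-break toward the component containing the lowest state index.
    best = int(np.argmax(sizes))
    keep = np.nonzero(labels == best)[0]
    sub = CountMatrix(counts=C[np.ix_(keep, keep)], lag=counts.lag)
    return keep, sub


def estimate_reversible_T(
    counts: CountMatrix | np.ndarray,
    lag: float | None = None,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    initial_counts: np.ndarray | None = None,
) -> MarkovStateModel:
    """Maximum-likelihood reversible transition matrix from transition counts.

    Maximizes ∏_ij T_ij^{C_ij} under detailed balance π_i T_ij = π_j T_ji by
    fixed-point iteration on the unnormalized equilibrium fluxes
    x_ij = π_i T_ij:

        x_ij ← (C_ij + C_ji) / (c_i / x_i + c_j / x_j)

    with c_i the row sums of C and x_i = Σ_j x_ij.  The iteration preserves
    the symmetry of x, so the returned chain satisfies detailed balance to
    machine precision at every sweep; convergence is declared when the
    normalized fluxes change by less than ``tol`` (default 1e-12) or after
    ``max_iter`` sweeps, in which case the residual is reported.

    Accepts real-valued (expected) counts, as produced by the E-step of
    Baum-Welch.  ``initial_counts`` (a_i ≥ 0) adds an equilibrium term
    Σ_i a_i ln π_i to the objective — the initial-state term of an HMM whose
    start distribution is the stationary vector.  The fixed point then
    becomes x_ij ← (C_ij + C_ji) / ((c_i−a_i)/x_i + (c_j−a_j)/x_j + 2A/S)
    with A = Σ a_i and S the total flux; including it keeps Baum-Welch
    monotone exactly.
    """
    if isinstance(counts, CountMatrix):
        C = counts.counts.astype(float)
        lag = counts.lag if lag is None else lag
    else:
        C = np.asarray(counts, dtype=float)
        if lag is None:
            raise ValueError("lag must be given when counts is a bare array")
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    n_comp, _ = connected_components(
        csr_matrix((C > 0).astype(np.int8)), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ValueError(
            "count matrix is not strongly connected; restrict to the "
            "largest connected set first"
        )
    c_row = C.sum(axis=1)
    if initial_counts is None:
        a = np.zeros_like(c_row)
    else:
        a = np.asarray(initial_counts, dtype=float)
        if a.shape != c_row.shape or np.any(a < 0):
            raise ValueError("initial_counts must be a non-negative length-M vector")
    A = a.sum()
    sym = C + C.T
    x = sym / sym.sum()
    converged = False
    for _ in range(max_iter):
        x_i = x.sum(axis=1)
        q = (c_row - a) / x_i
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = sym / (q[:, None] + q[None, :] + 2.0 * A)
        x_new[sym == 0] = 0.0
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "reversible estimator did not reach tol=%.1e in %d sweeps "
            "(last change %.3e)", tol, max_iter, delta,
        )
    pi = x.sum(axis=1)
    T = x / pi[:, None]
    T /= T.sum(axis=1, keepdims=True)
    pi = pi / pi.sum()
    return MarkovStateModel(transition_matrix=T, lag=float(lag), stationary=pi)


def implied_timescales(msm: MarkovStateModel, k: int) -> np.ndarray:
    """The k slowest implied timescales t_i = −τ / ln λ_i (ns).

    λ_i are the k largest-magnitude nontrivial eigenvalues of T(τ), computed
    through the symmetric matrix diag(π)^{1/2} T diag(π)^{-1/2} (a similarity
    transform that is exactly symmetric under detailed balance).  Timescales
    are returned sorted descending; eigenvalues ≥ 1 map to +inf and
    eigenvalues ≤ 0 to NaN (undefined at this lag).
    """
    if k >= msm.n_states:
        raise ValueError("k must be smaller than the number of states")
    pi = np.where(msm.stationary > 0, msm.stationary, 1e-300)
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * msm.transition_matrix / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    lam = np.linalg.eigvalsh(S)
    lam = lam[np.argsort(-np.abs(lam))]
    nontrivial = lam[1 : k + 1]
    out = np.empty(k)
    for i, ev in enumerate(nontrivial):
        if ev >= 1.0:
            out[i] = np.inf
        elif ev <= 0.0:
            out[i] = np.nan
        else:
            out[i] = -msm.lag / np.log(ev)
    return out


def build_msm(
    trajs: Sequence[FeatureTrajectory],
    radius: float,
    lag: float,
    r0: float = DEFAULT_R0,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[MarkovStateModel, ClusterModel]:
    """Full supervised step: cluster, assign, count, estimate.

    Clusters the pooled (Q, ε) frames by regular-space clustering at
    ``radius``, discretizes each trajectory, counts sliding-window
    transitions at lag ``lag`` (ns), restricts to the largest strongly
    connected state set and estimates the reversible transition matrix.
    Per-state mean and standard deviation of r are computed from the frames
    assigned to each kept state.

    Returns the model and the cluster model (cluster indices refer to the
    kept, remapped states).
    """
    eps_list = [expected_efficiency_trajectory(t, r0=r0, lam=lam) for t in trajs]
    points = np.concatenate(
        [np.column_stack([t.q, e]) for t, e in zip(trajs, eps_list)], axis=0
    )
    cluster = regular_space_cluster(points, radius)
    dtrajs = [
        DiscreteTrajectory(
            states=assign_states(np.column_stack([t.q, e]), cluster),
            time_step=t.time_step,
        )
        for t, e in zip(trajs, eps_list)
    ]
    counts = count_transitions(dtrajs, lag, cluster.n_clusters)
    keep, sub = largest_connected_set(counts)
    msm = estimate_reversible_T(sub)
    # Per-state r statistics over the frames assigned to each kept state.
    all_states = np.concatenate([d.states for d in dtrajs])
    all_r = np.concatenate([t.r for t in trajs])
    mean_r = np.empty(keep.size)
    std_r = np.empty(keep.size)
    for new, orig in enumerate(keep):
        mask = all_states == orig
        mean_r[new] = all_r[mask].mean() if mask.any() else np.nan
        std_r[new] = all_r[mask].std() if mask.any() else np.nan
    msm.state_centers = cluster.centers[keep]
    msm.state_mean_r = mean_r
    msm.state_std_r = std_r
    return msm, cluster


# ---------------------------------------------------------------------------
# File formats: feature TSV and MSM JSON
# ---------------------------------------------------------------------------

def read_feature_trajectory(path: str | Path) -> FeatureTrajectory:
    """Read a feature TSV with columns ``time_ns  q  r_angstrom``."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_ns", "q", "r_angstrom"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    t = df["time_ns"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        raise ValueError(f"{path}: time stamps must be uniformly increasing")
    return FeatureTrajectory(
        time_step=float(dt[0]),
        q=df["q"].to_numpy(dtype=float),
        r=df["r_angstrom"].to_numpy(dtype=float),
        id=Path(path).stem,
    )


def write_feature_trajectory(traj: FeatureTrajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_ns": np.arange(len(traj)) * traj.time_step,
            "q": traj.q,
            "r_angstrom": traj.r,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def save_msm(msm: MarkovStateModel, path: str | Path) -> None:
    """Write an MSM to JSON (keys: lag_ns, transition_matrix, stationary,
    states)."""
    states = []
    for i in range(msm.n_states):
        entry: dict = {"index": i}
        if msm.state_centers is not None:
            entry["q_center"] = float(msm.state_centers[i, 0])
            entry["eps_center"] = float(msm.state_centers[i, 1])
        if msm.state_mean_r is not None:
            entry["mean_r"] = float(msm.state_mean_r[i])
        if msm.state_std_r is not None:
            entry["std_r"] = float(msm.state_std_r[i])
        states.append(entry)
    payload = {
        "lag_ns": msm.lag,
        "transition_matrix": msm.transition_matrix.tolist(),
        "stationary": msm.stationary.tolist(),
        "states": states,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_msm(path: str | Path) -> MarkovStateModel:
    payload = json.loads(Path(path).read_text())
    states = payload.get("states", [])
    have = lambda key: states and all(key in s for s in states)  # noqa: E731
    centers = (
        np.array([[s["q_center"], s["eps_center"]] for s in states])
        if have("q_center") and have("eps_center")
        else None
    )
    mean_r = np.array([s["mean_r"] for s in states]) if have("mean_r") else None
    std_r = np.array([s["std_r"] for s in states]) if have("std_r") else None
    return MarkovStateModel(
        transition_matrix=np.array(payload["transition_matrix"], dtype=float),
        lag=float(payload["lag_ns"]),
        stationary=np.array(payload["stationary"], dtype=float),
        state_centers=centers,
        state_mean_r=mean_r,
        state_std_r=std_r,
    )
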
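"""Transition-path theory: committors, reactive flux, pathway decomposition.

For a reversible MSM with source set A (unfolded) and sink set B (folded),
the committor q_i (p_fold) is the probability that a trajectory started in
state i reaches B before A.  It solves the linear system

    q_i = Σ_j T_ij q_j   for i ∉ A ∪ B,   q = 0 on A,  q = 1 on B.

The reactive (A→B) probability current is f_ij = π_i (1−q_i) T_ij q_j; the
net flux f⁺_ij = max(f_ij − f_ji, 0) is decomposed into individual pathways
by repeatedly extracting the widest (maximum-bottleneck) A→B path with a
Dijkstra-style search and subtracting its bottleneck flux from every edge
on the path.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .msm_build import MarkovStateModel

__all__ = [
    "CommittorResult",
    "PathwayDecomposition",
    "committors",
    "transition_state_ensemble",
    "net_flux",
    "total_reactive_flux",
    "top_pathways",
]


@dataclass
class CommittorResult:
    """Folding probabilities p_fold with their boundary sets."""

    p_fold: np.ndarray
    source: frozenset
    sink: frozenset

    def __post_init__(self) -> None:
        self.p_fold = np.asarray(self.p_fold, dtype=float)
        self.source = frozenset(int(i) for i in self.source)
        self.sink = frozenset(int(i) for i in self.sink)


@dataclass
class PathwayDecomposition:
    """Ranked folding pathways and their fluxes (probability per τ)."""

    pathways: list[tuple[list[int], float]]
    total_flux: float
    cumulative_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.cumulative_fraction = np.asarray(self.cumulative_fraction, dtype=float)


def _check_sets(n: int, source, sink) -> tuple[frozenset, frozenset]:
    src = frozenset(int(i) for i in source)
    snk = frozenset(int(i) for i in sink)
    if not src or not snk:
        raise ValueError("source and sink must be nonempty")
    if src & snk:
        raise ValueError("source and sink must be disjoint")
    if any(i < 0 or i >= n for i in src | snk):
        raise ValueError("state index out of range")
    return src, snk


def committors(model: MarkovStateModel, source, sink) -> CommittorResult:
    """Solve the discrete committor (p_fold) linear system by a dense solve.

    Raises ``ValueError`` with a diagnosis if the system is singular (the
    sink is unreachable from some intermediate state).
    """
    n = model.n_states
    src, snk = _check_sets(n, source, sink)
    T = model.transition_matrix
    q = np.zeros(n)
    for i in snk:
        q[i] = 1.0
    inter = np.array(sorted(set(range(n)) - src - snk), dtype=int)
    if inter.size:
        A = np.eye(inter.size) - T[np.ix_(inter, inter)]
        b = T[np.ix_(inter, sorted(snk))].sum(axis=1)
        try:
            q_inter = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "committor system is singular: the sink is unreachable from "
                "part of the intermediate state space"
            ) from exc
        q[inter] = q_inter
        residual = np.max(np.abs(A @ q_inter - b))
        if not np.isfinite(residual) or residual > 1e-10:
            raise ValueError(
                f"committor solve failed (residual {residual:.3e}); check "
                "connectivity between source and sink"
            )
    return CommittorResult(p_fold=q, source=src, sink=snk)


def transition_state_ensemble(
    committor: CommittorResult, lo: float = 0.4, hi: float = 0.6
) -> set[int]:
    """States with lo ≤ p_fold ≤ hi, excluding the source and sink sets."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    q = committor.p_fold
    boundary = committor.source | committor.sink
    return {
        int(i) for i in range(q.size)
        if lo <= q[i] <= hi and i not in boundary
    }


def net_flux(model: MarkovStateModel, committor: CommittorResult) -> np.ndarray:
    """Net reactive flux matrix f⁺_ij = max(f_ij − f_ji, 0) with
    f_ij = π_i (1−q_i) T_ij q_j (diagonal zero)."""
    if committor.p_fold.size != model.n_states:
        raise ValueError("committor does not match the model")
    q = committor.p_fold
    f = model.stationary[:, None] * (1.0 - q)[:, None] * model.transition_matrix * q[None, :]
    np.fill_diagonal(f, 0.0)
    return np.maximum(f - f.T, 0.0)


def total_reactive_flux(flux: np.ndarray, source) -> float:
    """Total A→B flux as the net outflow of the source set."""
    src = sorted(set(int(i) for i in source))
    others = [j for j in range(flux.shape[0]) if j not in src]
    return float(flux[np.ix_(src, others)].sum() - flux[np.ix_(others, src)].sum())


def _widest_path(F: np.ndarray, source: frozenset, sink: frozenset) -> list[int] | None:
    """Maximum-bottleneck path from the source set to the sink set.

    Dijkstra-style search maximizing the minimum edge flux along the path;
    ties are broken toward the lower state index (heap ordering).  Edges
    into the source and out of the sink are ignored.
    """
    n = F.shape[0]
    width = np.full(n, -np.inf)
    pred = np.full(n, -1, dtype=int)
    done = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = []
    for s in sorted(source):
        width[s] = np.inf
        heapq.heappush(heap, (-np.inf, s))
    while heap:
        neg_w, u = heapq.heappop(heap)
        if done[u] or -neg_w < width[u]:
            continue
        done[u] = True
        if u in sink:
            path = [int(u)]
            while pred[path[-1]] >= 0:
                path.append(int(pred[path[-1]]))
            return path[::-1]
        for v in range(n):
            if done[v] or v in source or F[u, v] <= 0.0:
                continue
            w = min(width[u], F[u, v])
            if w > width[v]:
                width[v] = w
                pred[v] = u
                heapq.heappush(heap, (-w, v))
    return None


def top_pathways(
    flux: np.ndarray, source, sink, stop_fraction: float = 0.5
) -> PathwayDecomposition:
    """Iterative widest-path decomposition of the net flux matrix.

    Repeatedly extracts the maximum-bottleneck source→sink path, assigns it
    its bottleneck flux, subtracts that flux from every edge on the path and
    continues until the accumulated pathway flux reaches
    ``stop_fraction`` × total flux or no path remains.
    """
    if not (0.0 < stop_fraction <= 1.0):
        raise ValueError("stop_fraction must lie in (0, 1]")
    F = np.array(flux, dtype=float)
    if F.ndim != 2 or F.shape[0] != F.shape[1]:
        raise ValueError("flux must be a square matrix")
    src, snk = _check_sets(F.shape[0], source, sink)
    total = total_reactive_flux(F, src)
    if total <= 0.0:
        raise ValueError("total reactive flux is zero; nothing to decompose")
    pathways: list[tuple[list[int], float]] = []
    cumulative = 0.0
    fractions: list[float] = []
    while cumulative + 1e-15 * total < stop_fraction * total:
        path = _widest_path(F, src, snk)
        if path is None:
            break
        edges = list(zip(path[:-1], path[1:]))
        bottleneck = min(F[u, v] for u, v in edges)
        if bottleneck <= 0.0:
            break
        for u, v in edges:
            F[u, v] -= bottleneck
        pathways.append((path, float(bottleneck)))
        cumulative += bottleneck
        fractions.append(cumulative / total)
    return PathwayDecomposition(
        pathways=pathways,
        total_flux=total,
        cumulative_fraction=np.array(fractions),
    )
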
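"""Förster-theory observables and the photon-count emission model.

Energy transfer between a donor and an acceptor dye attached to a protein
reports on the donor–acceptor distance r through the transfer efficiency

    ε(r) = 1 / (1 + (r / R0)^6)

where R0 is the Förster radius (the distance of 50% transfer).  Outside the
weak-excitation limit the efficiency generalizes to ε'(r) = 1 / (Λ + (r/R0)^6)
with a saturation parameter Λ ≥ 1 (Λ = 1 recovers the weak-field form).  R0
itself depends on the relative dye orientation through the factor κ²; for
freely rotating dyes the isotropic average κ² = 2/3 applies.

Photon detection in a time window of width τ is modelled as two independent
Poisson processes: a state s with efficiency ε_s emits donor photons at rate
n(1−ε_s) and acceptor photons at rate n·ε_s, with the total count rate n
shared by all states (the gamma-factor-one condition).  The resulting window
observation probability is the product of two Poisson laws, equivalently a
Poisson law for the total count times a binomial split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DEFAULT_R0",
    "DEFAULT_LAMBDA",
    "KAPPA2_ISOTROPIC",
    "DEFAULT_TOTAL_RATE_PER_MS",
    "forster_efficiency",
    "generalized_efficiency",
    "DipolePair",
    "orientation_factor",
    "Kappa2Estimate",
    "isotropic_kappa2",
    "EmissionModel",
    "window_emission_logprob",
    "window_emission_logprob_factored",
    "estimate_total_rate",
]

#: Förster radius of the Alexa 488 / Alexa 594 pair, in Å.
DEFAULT_R0 = 56.0
#: Weak-excitation limit.
DEFAULT_LAMBDA = 1.0
#: Isotropic orientation-factor average.
KAPPA2_ISOTROPIC = 2.0 / 3.0
#: Typical high-illumination total count rate, photons per millisecond.
DEFAULT_TOTAL_RATE_PER_MS = 650.0

# Efficiencies are clamped away from {0, 1}: an efficiency of exactly 1 would
# give a zero donor rate and assign zero probability to any window containing
# a donor photon, making the likelihood −inf for otherwise legal data.
_EPS_CLAMP = 1e-9


def forster_efficiency(r, r0: float = DEFAULT_R0):
    """Weak-excitation FRET efficiency ε = 1 / (1 + (r/R0)^6).

    Parameters
    ----------
    r : float or array_like
        Donor–acceptor distance in Å; must be non-negative.
    r0 : float
        Förster radius in Å; must be positive.
    """
    r = np.asarray(r, dtype=float)
    if r0 <= 0:
        raise ValueError(f"Förster radius must be positive, got {r0}")
    if np.any(r < 0):
        raise ValueError("donor-acceptor distances must be non-negative")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return out if out.ndim else float(out)


def generalized_efficiency(r, r0: float = DEFAULT_R0, lam: float = DEFAULT_LAMBDA):
    """Efficiency beyond the weak-excitation limit, ε' = 1 / (Λ + (r/R0)^6).

    ``lam`` is the saturation parameter Λ ≥ 1; Λ = 1 reproduces
    :func:`forster_efficiency` bit-for-bit.
    """
    r = np.asarray(r, dtype=float)
    if r0 <= 0:
        raise ValueError(f"Förster radius must be positive, got {r0}")
    if lam < 1.0:
        raise ValueError(f"saturation parameter must satisfy Λ >= 1, got {lam}")
    if np.any(r < 0):
        raise ValueError("donor-acceptor distances must be non-negative")
    if lam == 1.0:
        return forster_efficiency(r, r0)
    out = 1.0 / (lam + (r / r0) ** 6)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DipolePair:
    """Unit transition-dipole directions of donor and acceptor plus the
    direction of their separation vector."""

    donor_direction: np.ndarray
    acceptor_direction: np.ndarray
    separation_direction: np.ndarray

    def __post_init__(self) -> None:
        for name in ("donor_direction", "acceptor_direction", "separation_direction"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must have unit length")
            object.__setattr__(self, name, v)


def orientation_factor(pair: DipolePair) -> float:
    """Squared orientation factor κ² of a donor/acceptor dipole pair.

    κ = d_D·d_A − 3 (d_D·u)(d_A·u) with u the separation direction;
    the return value κ² lies in [0, 4].
    """
    d, a, u = pair.donor_direction, pair.acceptor_direction, pair.separation_direction
    kappa = float(d @ a - 3.0 * (d @ u) * (a @ u))
    return kappa * kappa


@dataclass(frozen=True)
class Kappa2Estimate:
    mean: float
    stderr: float
    n_samples: int


def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def isotropic_kappa2(n_samples: int, seed: int) -> Kappa2Estimate:
    """Monte-Carlo estimate of the isotropic κ² average (exact value 2/3).

    Donor and acceptor dipole directions are drawn independently and
    uniformly on the sphere (normalized Gaussian draws); the separation
    direction is fixed along z, which is equivalent by rotational symmetry.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    d = _uniform_directions(rng, n_samples)
    a = _uniform_directions(rng, n_samples)
    kappa = d[:, 0] * a[:, 0] + d[:, 1] * a[:, 1] - 2.0 * d[:, 2] * a[:, 2]
    k2 = kappa**2
    mean = float(k2.mean())
    stderr = float(k2.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else float("inf")
    return Kappa2Estimate(mean=mean, stderr=stderr, n_samples=n_samples)


@dataclass
class EmissionModel:
    """Per-state photon emission probabilities for τ-windows.

    Parameters
    ----------
    efficiencies : array of shape (M,)
        Expected transfer efficiency ε_s of each discrete state; clamped to
        [1e-9, 1−1e-9] so every observation keeps finite probability.
    total_rate : float
        Total photon count rate n in photons/ns, shared by all states.
    window : float
        Window width τ in ns (equals the MSM lag time).
    r0, lam, kappa2 : float
        Förster radius (Å), saturation parameter Λ and orientation factor κ²
        used when efficiencies are derived from distances; stored for
        provenance.
    """

    efficiencies: np.ndarray
    total_rate: float
    window: float
    r0: float = DEFAULT_R0
    lam: float = DEFAULT_LAMBDA
    kappa2: float = KAPPA2_ISOTROPIC

    def __post_init__(self) -> None:
        eps = np.clip(np.asarray(self.efficiencies, dtype=float), _EPS_CLAMP, 1.0 - _EPS_CLAMP)
        if eps.ndim != 1 or eps.size == 0:
            raise ValueError("efficiencies must be a nonempty 1-D array")
        self.efficiencies = eps
        if self.total_rate <= 0:
            raise ValueError("total_rate must be positive")
        if self.window <= 0:
            raise ValueError("window width must be positive")
        if self.lam < 1.0:
            raise ValueError("Λ must be >= 1")

    @property
    def n_states(self) -> int:
        return self.efficiencies.size

    @property
    def n_tau(self) -> float:
        """Expected total photon count per window, nτ."""
        return self.total_rate * self.window

    @property
    def mean_donor_counts(self) -> np.ndarray:
        """Per-state expected donor counts n(1−ε_s)τ."""
        return self.n_tau * (1.0 - self.efficiencies)

    @property
    def mean_acceptor_counts(self) -> np.ndarray:
        """Per-state expected acceptor counts n·ε_s·τ."""
        return self.n_tau * self.efficiencies

    @classmethod
    def from_state_distances(
        cls,
        mean_r: Sequence[float],
        total_rate: float,
        window: float,
        r0: float = DEFAULT_R0,
        lam: float = DEFAULT_LAMBDA,
        kappa2: float = KAPPA2_ISOTROPIC,
    ) -> "EmissionModel":
        """Build the model from per-state mean donor–acceptor distances."""
        eps = generalized_efficiency(np.asarray(mean_r, dtype=float), r0=r0, lam=lam)
        return cls(efficiencies=np.atleast_1d(eps), total_rate=total_rate,
                   window=window, r0=r0, lam=lam, kappa2=kappa2)

    def log_emission_matrix(self, windows: np.ndarray) -> np.ndarray:
        """Log observation probabilities ln h(o_i | s) for every window/state.

        Parameters
        ----------
        windows : int array of shape (I, 2)
            Columns are donor and acceptor counts per window.

        Returns
        -------
        (I, M) array of log-probabilities.
        """
        w = np.asarray(windows)
        if w.ndim != 2 or w.shape[1] != 2:
            raise ValueError("windows must have shape (I, 2)")
        nd = w[:, 0:1].astype(float)
        na = w[:, 1:2].astype(float)
        mu_d = self.mean_donor_counts[None, :]
        mu_a = self.mean_acceptor_counts[None, :]
        return (
            nd * np.log(mu_d) - mu_d - gammaln(nd + 1.0)
            + na * np.log(mu_a) - mu_a - gammaln(na + 1.0)
        )


def window_emission_logprob(n_d: int, n_a: int, state: int, model: EmissionModel) -> float:
    """Log probability of observing (N_D, N_A) photons in one window of a
    given state, as the product of two independent Poisson distributions."""
    if n_d < 0 or n_a < 0:
        raise ValueError("photon counts must be non-negative")
    out = model.log_emission_matrix(np.array([[n_d, n_a]]))
    return float(out[0, state])


def window_emission_logprob_factored(n_d: int, n_a: int, state: int, model: EmissionModel) -> float:
    """Same observation probability in the factored form: a Poisson law for
    the total count N = N_D + N_A with mean nτ, times a binomial split of N
    into acceptor photons with success probability ε_s.  Used as an
    independent cross-check of :func:`window_emission_logprob`."""
    if n_d < 0 or n_a < 0:
        raise ValueError("photon counts must be non-negative")
    eps = float(model.efficiencies[state])
    n_tau = model.n_tau
    n_tot = n_d + n_a
    log_poisson = n_tot * np.log(n_tau) - n_tau - gammaln(n_tot + 1.0)
    log_binom = (
        gammaln(n_tot + 1.0) - gammaln(n_d + 1.0) - gammaln(n_a + 1.0)
        + n_a * np.log(eps) + n_d * np.log1p(-eps)
    )
    return float(log_poisson + log_binom)


def estimate_total_rate(sequences: Iterable) -> float:
    """Estimate the shared total count rate n (photons/ns) from binned data
    as total photons divided by total observation time."""
    photons = 0.0
    time = 0.0
    for seq in sequences:
        w = np.asarray(seq.windows)
        photons += float(w.sum())
        time += w.shape[0] * float(seq.window_width)
    if time <= 0:
        raise ValueError("no observation time in sequences")
    if photons <= 0:
        raise ValueError("no photons in sequences")
    return photons / time
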
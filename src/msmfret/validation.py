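"""Model-versus-data diagnostics.

Measured FRET efficiency histograms (E = N_A / (N_A + N_D) per time window),
mean-squared error between normalized histograms, model-side emulation of
photon datasets, and k-fold cross-validation of the Baum-Welch refinement.
Short windows (the native 200 ns) probe photon shot noise; long windows
(e.g. 50 μs, the folding timescale) reveal the folded/unfolded bimodality
when the model's basin exchange is slow enough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .fret_physics import EmissionModel
from .hmm_refine import PhotonWindowSequence, baum_welch, forward_loglik
from .msm_build import MarkovStateModel
from .photon_sim import generate_photon_dataset

__all__ = [
    "EfficiencyHistogram",
    "measured_efficiency_histogram",
    "histogram_mse",
    "emulate_dataset",
    "FoldResult",
    "kfold_cross_validate",
    "count_modes",
]

logger = logging.getLogger(__name__)

#: Default number of histogram bins on [0, 1].
DEFAULT_BINS = 50


@dataclass
class EfficiencyHistogram:
    """Normalized histogram of measured efficiencies over [0, 1]."""

    bin_edges: np.ndarray
    density: np.ndarray
    window_width: float
    n_windows_used: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.bin_edges.size - 1:
            raise ValueError("density must have one entry per bin")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        area = float(np.sum(self.density * np.diff(self.bin_edges)))
        if abs(area - 1.0) > 1e-12:
            raise ValueError(f"histogram area must be 1, got {area}")

    @property
    def n_bins(self) -> int:
        return self.density.size


def _aggregate(seq: PhotonWindowSequence, factor: int) -> np.ndarray:
    """Sum counts over consecutive groups of ``factor`` native windows;
    a trailing incomplete group is dropped."""
    n = (len(seq) // factor) * factor
    if n == 0:
        return np.zeros((0, 2), dtype=np.int64)
    return seq.windows[:n].reshape(-1, factor, 2).sum(axis=1)


def measured_efficiency_histogram(
    seqs: Sequence[PhotonWindowSequence],
    window_width: float,
    bins: int = DEFAULT_BINS,
) -> EfficiencyHistogram:
    """Histogram of E = N_A / (N_A + N_D) at a given window width.

    ``window_width`` must be an integer multiple of the sequences' native
    width; counts are re-aggregated by summation before E is computed.
    Zero-photon windows carry no efficiency information (0/0) and are
    excluded; the number excluded is logged.  Bin edges are uniform on
    [0, 1], left-inclusive with the last bin closed.
    """
    if not seqs:
        raise ValueError("no sequences given")
    native = seqs[0].window_width
    for s in seqs:
        if not np.isclose(s.window_width, native, rtol=1e-9):
            raise ValueError("all sequences must share the native window width")
    ratio = window_width / native
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"window width {window_width} is not an integer multiple of the "
            f"native width {native}"
        )
    agg = np.concatenate([_aggregate(s, factor) for s in seqs], axis=0)
    total = agg.sum(axis=1)
    nonempty = total > 0
    n_excluded = int(np.sum(~nonempty))
    if n_excluded:
        logger.info("excluded %d zero-photon windows from the E histogram", n_excluded)
    if not np.any(nonempty):
        raise ValueError("no windows with photons; cannot form an E histogram")
    e_values = agg[nonempty, 1] / total[nonempty]
    edges = np.linspace(0.0, 1.0, bins + 1)
    density, _ = np.histogram(e_values, bins=edges, density=True)
    return EfficiencyHistogram(
        bin_edges=edges,
        density=density,
        window_width=window_width,
        n_windows_used=int(nonempty.sum()),
    )


def histogram_mse(a: EfficiencyHistogram, b: EfficiencyHistogram) -> float:
    """Mean over bins of squared normalized-height differences."""
    if a.n_bins != b.n_bins or not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.mean((a.density - b.density) ** 2))


def emulate_dataset(
    model: MarkovStateModel,
    emission: EmissionModel,
    template: Sequence[int],
    n_realizations: int = 1,
    seed: int | None = None,
) -> list[list[PhotonWindowSequence]]:
    """Model-side photon datasets matching the lengths of the real data.

    For each realization, a state path is simulated for every template
    length and photons are emitted from it — the emulation used to put
    error bars on model histograms.  Returns one list of sequences per
    realization.
    """
    if not template:
        raise ValueError("template must be nonempty")
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_realizations):
        rng_seed = int(child.generate_state(1)[0] % (2**31))
        realization = []
        for j, length in enumerate(template):
            seqs = generate_photon_dataset(
                model, emission, n_seqs=1, n_windows=int(length),
                seed=rng_seed + j,
            )
            realization.append(seqs[0])
        out.append(realization)
    return out


@dataclass
class FoldResult:
    fold: int
    train_loglik: float
    test_loglik: float
    train_hist_mse: float
    test_hist_mse: float
    n_train: int
    n_test: int


def kfold_cross_validate(
    sequences: Sequence[PhotonWindowSequence],
    T_init: MarkovStateModel,
    emission: EmissionModel,
    k: int = 4,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
    hist_window: float | None = None,
    bins: int = DEFAULT_BINS,
    n_realizations: int = 3,
) -> list[FoldResult]:
    """k-fold cross-validation of the refinement.

    Sequences (the independent units of the likelihood) are shuffled and
    split into k folds.  For each fold, Baum-Welch refines ``T_init`` on the
    other k−1 folds; the held-out log-likelihood and the MSE between the
    refined model's emulated E histogram and the held-out histogram are
    reported.  ``hist_window`` defaults to the native window width.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(sequences) < k:
        raise ValueError("need at least k sequences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    folds = np.array_split(order, k)
    if hist_window is None:
        hist_window = sequences[0].window_width
    results = []
    for f, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train = [s for i, s in enumerate(sequences) if i not in test_set]
        test = [sequences[i] for i in sorted(test_set)]
        fit = baum_welch(T_init, train, emission, max_iter=max_iter, tol=tol)
        model = fit.refined_model
        train_ll = float(fit.loglik_trace[-1])
        test_ll = float(sum(forward_loglik(model, emission, s) for s in test))
        test_hist = measured_efficiency_histogram(test, hist_window, bins=bins)
        train_hist = measured_efficiency_histogram(train, hist_window, bins=bins)
        # Emulate at the full dataset size for both comparisons, so the
        # emulation-side sampling noise is identical for train and test and
        # the MSE contrast reflects the data side only.
        template = [len(s) for s in sequences]
        emulated = emulate_dataset(
            model, emission, template, n_realizations=n_realizations,
            seed=None if seed is None else seed + 7919 * (f + 1),
        )
        test_mses, train_mses = [], []
        for realization in emulated:
            h = measured_efficiency_histogram(realization, hist_window, bins=bins)
            test_mses.append(histogram_mse(h, test_hist))
            train_mses.append(histogram_mse(h, train_hist))
        results.append(
            FoldResult(
                fold=f,
                train_loglik=train_ll,
                test_loglik=test_ll,
                train_hist_mse=float(np.mean(train_mses)),
                test_hist_mse=float(np.mean(test_mses)),
                n_train=len(train),
                n_test=len(test),
            )
        )
    return results


def count_modes(
    hist: EfficiencyHistogram, smooth: int = 3, rel_prominence: float = 0.05
) -> int:
    """Number of modes of the histogram.

    The density is smoothed with a fixed ``smooth``-bin moving average and
    peaks are counted with :func:`scipy.signal.find_peaks`, requiring a
    topographic prominence of at least ``rel_prominence`` times the smoothed
    maximum — finite-sample wiggles on flat stretches are not modes.  The
    density is zero-padded so boundary peaks are countable.
    """
    kernel = np.ones(smooth) / smooth
    d = np.convolve(hist.density, kernel, mode="same")
    padded = np.concatenate([[0.0], d, [0.0]])
    peaks, _ = find_peaks(padded, prominence=rel_prominence * d.max())
    return int(peaks.size)
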
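"""Functional measures: phase synchrony of fast signals, surrogate-thresholded
functional connectivity, graph summaries, and sliding-window FC dynamics."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import signal, stats

from neurogain.connectome import _inverse_distances
from neurogain.hemodynamics import BoldTrace

__all__ = [
    "PhaseSeries",
    "FCMatrix",
    "FCDMatrix",
    "FunctionalSummary",
    "phase_synchrony",
    "ft_surrogate",
    "fc_threshold",
    "global_efficiency",
    "modularity_consensus",
    "clarkson_distance",
    "fcd",
    "summarize",
]


@dataclass
class PhaseSeries:
    theta: np.ndarray  # nodes x time (radians)
    band: np.ndarray  # nodes x 2 (low, high) Hz


@dataclass
class FCMatrix:
    values: np.ndarray
    thresholded: np.ndarray
    mask: np.ndarray


@dataclass
class FCDMatrix:
    values: np.ndarray
    window_length: float
    step: float


@dataclass
class FunctionalSummary:
    R_bar: float
    E_w: float
    Q_w: float
    module_assignment: np.ndarray


# ---------------------------------------------------------------------------
# Phase synchrony
# ---------------------------------------------------------------------------

def phase_synchrony(
    nu: np.ndarray,
    rate: float,
    half_band: float = 3.0,
    peak_range: tuple[float, float] = (2.0, 20.0),
    order: int = 3,
    trim: float = 1.0,
) -> tuple[float, PhaseSeries]:
    """Mean Kuramoto order parameter of narrow-band analytic phases.

    Each channel is band-passed (zero-phase Bessel) around its own spectral
    peak +- ``half_band`` Hz, phases come from the Hilbert transform, and the
    first/last ``trim`` seconds are dropped before time-averaging
    ``|mean_nodes exp(i theta)|``.
    """
    nu = np.asarray(nu, dtype=np.float64)
    n, T = nu.shape
    if T < 2 * rate:
        raise ValueError("need at least 2 s of signal")
    nperseg = min(T, int(4 * rate))
    freqs, psd = signal.welch(nu, fs=rate, nperseg=nperseg, axis=1)
    sel = (freqs >= peak_range[0]) & (freqs <= peak_range[1])
    if not sel.any():
        raise ValueError("peak search range is empty at this sampling rate")
    fsel = freqs[sel]
    psd_sel = psd[:, sel]
    bands = np.empty((n, 2))
    filtered = np.empty_like(nu)
    for i in range(n):
        if psd_sel[i].max() <= 0 or np.ptp(nu[i]) == 0:
            raise ValueError(f"flat signal (no spectral peak) at node {i}")
        f0 = fsel[np.argmax(psd_sel[i])]
        lo = max(f0 - half_band, 0.1)
        hi = min(f0 + half_band, 0.99 * rate / 2)
        bands[i] = (lo, hi)
        sos = signal.bessel(order, [lo, hi], btype="bandpass", fs=rate,
                            output="sos", norm="mag")
        filtered[i] = signal.sosfiltfilt(sos, nu[i])
    theta = np.angle(signal.hilbert(filtered, axis=1))
    k = int(trim * rate)
    core = theta[:, k: T - k] if T > 2 * k + 1 else theta
    R_t = np.abs(np.exp(1j * core).mean(axis=0))
    return float(R_t.mean()), PhaseSeries(theta, bands)


# ---------------------------------------------------------------------------
# FC with Fourier-surrogate thresholding
# ---------------------------------------------------------------------------

def ft_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized copy of each row; amplitude spectra are preserved
    exactly, pairwise correlations are destroyed."""
    x = np.asarray(x, dtype=np.float64)
    n, T = x.shape
    spec = np.fft.rfft(x, axis=1)
    nf = spec.shape[1]
    phases = rng.uniform(0, 2 * np.pi, size=(n, nf))
    phases[:, 0] = 0.0
    if T % 2 == 0:
        phases[:, -1] = 0.0
    return np.fft.irfft(spec * np.exp(1j * phases), n=T, axis=1)


def fc_threshold(
    bold: BoldTrace | np.ndarray,
    n_surrogates: int = 500,
    q: float = 0.05,
    seed: int = 0,
) -> FCMatrix:
    """Pearson FC thresholded against Fourier-surrogate null correlations.

    Per pair, a Gaussian is fitted to the surrogate correlations and the
    right-tail p-value of the observed correlation is tested at FDR level
    ``q`` (Benjamini-Hochberg over all pairs); surviving (positive) entries
    keep their Pearson weight, everything else is zeroed.
    """
    x = bold.bold if isinstance(bold, BoldTrace) else np.asarray(bold, dtype=np.float64)
    n, T = x.shape
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if (x.std(axis=1) == 0).any():
        raise ValueError("constant signal: correlation undefined")
    fc = np.corrcoef(x)
    rng = np.random.default_rng(seed)
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(n_surrogates):
        sc = np.corrcoef(ft_surrogate(x, rng))
        acc += sc
        acc2 += sc * sc
    mu = acc / n_surrogates
    var = np.maximum(acc2 / n_surrogates - mu**2, 1e-24)
    sd = np.sqrt(var)
    iu = np.triu_indices(n, k=1)
    zvals = (fc[iu] - mu[iu]) / sd[iu]
    pvals = stats.norm.sf(zvals)
    padj = stats.false_discovery_control(pvals, method="bh")
    sig = padj <= q
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = sig
    mask |= mask.T
    thresholded = np.where(mask & (fc > 0), fc, 0.0)
    np.fill_diagonal(thresholded, 0.0)
    return FCMatrix(fc, thresholded, mask)


# ---------------------------------------------------------------------------
# Graph summaries of the thresholded FC
# ---------------------------------------------------------------------------

def global_efficiency(fc: FCMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path length on 1/w edge lengths; disconnected
    pairs contribute zero."""
    w = fc.thresholded if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = w.shape[0]
    inv = _inverse_distances(w)
    return float(inv.sum() / (n * (n - 1)))


def _partition_to_labels(partition, n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for m, nodes in enumerate(partition):
        for v in nodes:
            labels[v] = m
    return labels


def modularity_consensus(
    fc: FCMatrix | np.ndarray,
    gamma: float = 1.0,
    runs: int = 200,
    agreement_threshold: float = 0.5,
    seed: int = 0,
    max_rounds: int = 20,
) -> tuple[float, np.ndarray]:
    """Consensus community detection: repeated Louvain runs, thresholded
    co-assignment matrix, iterated until a unique partition; returns the
    weighted modularity of that partition on the original matrix."""
    w = fc.thresholded if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = w.shape[0]
    if (w > 0).sum() == 0:
        raise ValueError("empty graph: no retained edges")
    rng = np.random.default_rng(seed)

    def _graph(mat: np.ndarray) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        ii, jj = np.nonzero(np.triu(mat, k=1))
        g.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(), mat[ii, jj].tolist()))
        return g

    g_orig = _graph(w)
    current = w
    final = None
    for _ in range(max_rounds):
        g = _graph(current)
        labels_all = np.empty((runs, n), dtype=int)
        for r in range(runs):
            part = nx.community.louvain_communities(
                g, weight="weight", resolution=gamma, seed=int(rng.integers(2**31 - 1))
            )
            labels_all[r] = _partition_to_labels(part, n)
        # canonical relabeling so identical partitions compare equal
        canon = np.empty_like(labels_all)
        for r in range(runs):
            _, canon[r] = np.unique(labels_all[r], return_inverse=True)
        if (canon == canon[0]).all():
            final = canon[0]
            break
        agree = np.zeros((n, n))
        for r in range(runs):
            agree += canon[r][:, None] == canon[r][None, :]
        agree /= runs
        agree[agree < agreement_threshold] = 0.0
        np.fill_diagonal(agree, 0.0)
        current = agree
    if final is None:  # cap reached; majority partition of the last round
        final = canon[0]
    communities = [set(np.flatnonzero(final == m).tolist()) for m in np.unique(final)]
    Q = nx.community.modularity(g_orig, communities, weight="weight")
    return float(Q), final


# ---------------------------------------------------------------------------
# FCD
# ---------------------------------------------------------------------------

def clarkson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Half the Euclidean distance between the unit-normalized vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * float(np.linalg.norm(x / np.linalg.norm(x) - y / np.linalg.norm(y)))


def fcd(bold: BoldTrace | np.ndarray, window: float = 100.0, step: float = 2.0,
        rate: float | None = None) -> FCDMatrix:
    """Sliding-window FC dynamics: half the Euclidean distance between unit-
    normalized upper-triangle FC vectors, for every window pair."""
    if isinstance(bold, BoldTrace):
        x, fs = bold.bold, bold.rate
    else:
        if rate is None:
            raise ValueError("rate required for a bare array")
        x, fs = np.asarray(bold, dtype=np.float64), rate
    n, T = x.shape
    wlen = int(round(window * fs))
    slen = max(1, int(round(step * fs)))
    if wlen > T:
        raise ValueError("signal shorter than one window")
    n_win = (T - wlen) // slen + 1
    iu = np.triu_indices(n, k=1)
    vecs = np.empty((n_win, iu[0].size))
    for w_idx in range(n_win):
        seg = x[:, w_idx * slen: w_idx * slen + wlen]
        vecs[w_idx] = np.corrcoef(seg)[iu]
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vecs / norms
    gram = unit @ unit.T
    d2 = np.maximum(2.0 - 2.0 * gram, 0.0)
    values = 0.5 * np.sqrt(d2)
    np.fill_diagonal(values, 0.0)
    return FCDMatrix(values, window, step)


def summarize(
    R_bar: float,
    fc: FCMatrix,
    gamma: float = 1.0,
    runs: int = 200,
    seed: int = 0,
) -> FunctionalSummary:
    """Bundle synchrony plus integration/segregation summaries of an FC."""
    E_w = global_efficiency(fc)
    Q_w, modules = modularity_consensus(fc, gamma=gamma, runs=runs, seed=seed)
    return FunctionalSummary(R_bar, E_w, Q_w, modules)
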
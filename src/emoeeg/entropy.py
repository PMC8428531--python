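"""Signal complexity measures: embedding entropies, permutation and spectral
entropy, and the Higuchi fractal dimension.

All embedding entropies use Chebyshev distance with tolerance r expressed in
signal units; binding r to 0.2 x sd (the package default at call sites)
makes them amplitude-scale invariant. Implementations are vectorised
O(N^2) template comparisons, adequate for the 1-s epochs (N <= ~1000) this
package classifies.
"""

from __future__ import annotations

import math
import warnings

import numpy as np


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """Time-delay embedding: rows are length-m templates."""
    n = len(x) - (m - 1) * delay
    if n <= 0:
        raise ValueError(f"signal too short for embedding dimension {m}")
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * delay + 1)[:, ::delay]


def _template_distances(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all length-m templates.

    Built as a running elementwise maximum over shifted views of the scalar
    difference matrix |x_i - x_j|, avoiding any (N, N, m) allocation.
    """
    n = len(x) - m + 1
    if n <= 0:
        raise ValueError(f"signal too short for embedding dimension {m}")
    d0 = np.abs(x[:, None] - x[None, :])
    d = d0[:n, :n].copy()
    for k in range(1, m):
        np.maximum(d, d0[k : k + n, k : k + n], out=d)
    return d


def _chebyshev_counts(templates: np.ndarray, r: float, exclude_self: bool) -> np.ndarray:
    """Per-template count of other templates within Chebyshev distance r."""
    d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    within = d <= r
    counts = within.sum(axis=1).astype(float)
    if exclude_self:
        counts -= 1.0
    return counts


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -log of the conditional template-match probability.

    Self-matches are excluded. If no matches exist at length m+1 the value
    is capped at the largest resolvable entropy -log(2 / ((N-m-1)(N-m)))
    and a warning is issued.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    n = len(x)
    # truncate to equal template counts at m and m+1 (standard convention)
    k = n - m
    dm = _template_distances(x, m)[:k, :k]
    dm1 = _template_distances(x, m + 1)
    b = float((dm <= r).sum() - k)  # minus the self-matches on the diagonal
    a = float((dm1 <= r).sum() - k)
    if a == 0 or b == 0:
        cap = -math.log(2.0 / ((n - m - 1) * (n - m)))
        warnings.warn(
            "SampEn: no template matches; returning capped value", stacklevel=2
        )
        return cap
    return float(-math.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = Phi(m) - Phi(m+1), self-matches included."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        d = _template_distances(x, mm)
        c = (d <= r).sum(axis=1) / d.shape[0]  # self-matches included
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None, n_fuzzy: float = 2.0
) -> float:
    """FuzzyEn(m, r, n): exponential membership exp(-(d/r)^n) on mean-centred
    templates, -log of the length-(m+1) to length-m similarity ratio."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        t = t - t.mean(axis=1, keepdims=True)
        # running max over columns avoids an (N, N, m) intermediate
        d = np.abs(t[:, 0, None] - t[None, :, 0])
        for col in range(1, mm):
            np.maximum(d, np.abs(t[:, col, None] - t[None, :, col]), out=d)
        sim = np.exp(-((d / r) ** n_fuzzy))
        np.fill_diagonal(sim, 0.0)
        k = len(t)
        return float(sim.sum() / (k * (k - 1)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        raise ValueError("degenerate fuzzy similarity (constant signal?)")
    return float(math.log(p_m) - math.log(p_m1))


def permutation_entropy(
    x: np.ndarray, order: int = 3, delay: int = 1, normalize: bool = True
) -> float:
    """Shannon entropy of the ordinal-pattern distribution.

    Normalised by log(order!) so the value lies in [0, 1]; a strictly
    monotone signal has a single pattern and entropy 0.
    """
    x = np.asarray(x, dtype=float)
    t = _embed(x, order, delay)
    ranks = np.argsort(np.argsort(t, axis=1, kind="stable"), axis=1)
    # encode each ordinal pattern as an integer
    codes = (ranks * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def spectral_entropy(
    x: np.ndarray, fs: float, f_lo: float = 0.5, f_hi: float = 45.0,
    normalize: bool = True,
) -> float:
    """Normalised Shannon entropy of the periodogram over [f_lo, f_hi).

    1 for a flat spectrum (white noise), near 0 for a single tone.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    sel = (freqs >= f_lo) & (freqs < f_hi)
    p = p[sel]
    total = p.sum()
    if total <= 0:
        raise ValueError("no spectral power in the analysis band")
    p = p / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    if normalize:
        h /= math.log(int(sel.sum()))
    return h


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension: slope of log mean curve length vs log 1/k.

    ~1 for smooth curves, ~2 for white noise. Amplitude-scale invariant.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < k_max * 3:
        raise ValueError("signal too short for the requested k_max")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no defined fractal dimension")
    lengths = []
    ks = np.arange(1, k_max + 1)
    for k in ks:
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lk += dist * norm / k
        lengths.append(lk / k)
    coeffs = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)
    return float(coeffs[0])
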
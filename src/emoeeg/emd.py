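"""Empirical mode decomposition and its ensemble variant.

EMD iteratively sifts a signal into intrinsic mode functions (IMFs): at each
sift the mean of the cubic-spline envelopes through the local maxima and
minima is subtracted until the result is approximately symmetric around
zero. The decomposition is complete by construction: the IMFs plus the final
residue sum exactly to the input.

EEMD adds independent white noise to the signal in each of ``n_ensembles``
trials, decomposes each trial, and averages the IMFs index-wise. The noise
cancels at rate 1/sqrt(n_ensembles), which suppresses the mode-mixing that
plain EMD suffers on intermittent signals, at the cost of an O(noise_sd /
sqrt(n_ensembles)) reconstruction error.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

_SD_STOP = 0.2  # classic Cauchy-like sifting stop criterion
_MAX_SIFTS = 50


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau-tolerant)."""
    dx = np.diff(x)
    # treat flat steps by propagating the previous slope sign
    sign = np.sign(dx)
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``.

    Boundary extrema are mirrored about the signal ends so the spline does
    not swing wildly at the edges.
    """
    n = len(x)
    # mirror up to two extrema about each end
    left = idx[:2]
    right = idx[-2:]
    xs = np.concatenate([-left[::-1], idx, 2 * (n - 1) - right[::-1]])
    ys = np.concatenate([x[left[::-1]], x[idx], x[right[::-1]]])
    # mirrored points can coincide with originals when an extremum sits at 0
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    return CubicSpline(xs, ys)(np.arange(n))


def _sift_once(h: np.ndarray) -> np.ndarray | None:
    maxima, minima = _local_extrema(h)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    upper = _envelope(h, maxima)
    lower = _envelope(h, minima)
    return h - 0.5 * (upper + lower)


def emd(
    x: np.ndarray, max_imfs: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose ``x`` into IMFs and a residue.

    Returns (imfs, residue) with imfs of shape (n_imfs, len(x));
    ``imfs.sum(axis=0) + residue == x`` to float precision.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if max_imfs is None:
        max_imfs = max(int(np.log2(len(x))) - 1, 1)

    imfs: list[np.ndarray] = []
    residue = x.copy()
    for _ in range(max_imfs):
        h = residue.copy()
        prev = h
        for _ in range(_MAX_SIFTS):
            nxt = _sift_once(prev)
            if nxt is None:
                h = None
                break
            denom = float(np.sum(prev**2))
            sd = float(np.sum((prev - nxt) ** 2)) / denom if denom > 0 else 0.0
            prev = nxt
            if sd < _SD_STOP:
                break
        if prev is None or h is None:
            break
        imf = prev
        imfs.append(imf)
        residue = residue - imf
        maxima, minima = _local_extrema(residue)
        if len(maxima) + len(minima) < 3:
            break

    if not imfs:
        return np.empty((0, len(x))), residue
    return np.vstack(imfs), residue


def eemd(
    x: np.ndarray,
    n_ensembles: int = 100,
    noise_sd: float | None = None,
    rng: np.random.Generator | int | None = None,
    max_imfs: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble EMD: average of EMDs of noise-perturbed copies of ``x``.

    noise_sd defaults to 0.2 x std(x) (standard EEMD practice). All trials
    are forced to the same IMF count (``max_imfs``, default log2(N)-1);
    trials producing fewer IMFs fold the shortfall into the residue so the
    per-trial completeness identity is preserved before averaging.
    """
    x = np.asarray(x, dtype=float)
    if n_ensembles < 1:
        raise ValueError("n_ensembles must be >= 1")
    if noise_sd is None:
        noise_sd = 0.2 * float(x.std())
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if max_imfs is None:
        max_imfs = max(int(np.log2(len(x))) - 1, 1)

    imf_sum = np.zeros((max_imfs, len(x)))
    residue_sum = np.zeros(len(x))
    for _ in range(n_ensembles):
        noisy = x + noise_sd * rng.standard_normal(len(x))
        imfs, residue = emd(noisy, max_imfs=max_imfs)
        k = imfs.shape[0]
        if k:
            imf_sum[:k] += imfs
        residue_sum += residue
    return imf_sum / n_ensembles, residue_sum / n_ensembles


def dominant_frequency(imf: np.ndarray, fs: float) -> float:
    """Frequency of the periodogram peak of one IMF, in Hz."""
    freqs = np.fft.rfftfreq(len(imf), d=1.0 / fs)
    p = np.abs(np.fft.rfft(imf - imf.mean())) ** 2
    p[0] = 0.0
    return float(freqs[int(np.argmax(p))])
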
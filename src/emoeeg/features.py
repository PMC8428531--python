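"""The per-channel EEG descriptor set and feature-matrix construction.

The baseline set is 59 features per channel: 14 time-domain statistics, the
two Hjorth parameters, Higuchi fractal dimension, an instability index,
14 band/sub-band spectral energies, the five main-band energy ratios, the
five band differential entropies, centroid frequency and frequency
variability for the total band and each main band, and five signal
entropies. The focused sets used by the experiments (energy ratios,
differential entropies, single-band DE, and the dual-channel 20-feature
configuration) are subsets built from the same primitives.

Spectral energies are plain (unwindowed) DFT periodogram sums so the
full-spectrum energy satisfies Parseval's identity with the time-domain sum
of squares exactly; the band differential entropy is then
h_i = 0.5 * log(P_i), the Gaussian closed form up to an additive constant
that is fixed for fixed epoch length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import entropy as ent
from .bands import (
    BandDefinition,
    MAIN_BANDS,
    MAIN_BAND_NAMES,
    SUB_BANDS,
    TOTAL_BAND,
    get_band,
)
from .montage import check_channels
from .types import LabeledEpoch


class DegenerateBandError(ValueError):
    """A band containing no DFT bins (or carrying no energy) was requested."""


# ---------------------------------------------------------------------------
# spectral primitives


def _periodogram(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided-equivalent power per rfft bin: weights fold the conjugate
    half in, so summing all bins reproduces sum(x^2) exactly (Parseval)."""
    n = len(signal)
    spec = np.abs(np.fft.rfft(signal)) ** 2 / n
    weights = np.full(len(spec), 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    return spec * weights, np.fft.rfftfreq(n, d=1.0)  # freq in cycles/sample


def _band_mask(freqs_hz: np.ndarray, band: BandDefinition | None) -> np.ndarray:
    if band is None:
        return np.ones_like(freqs_hz, dtype=bool)
    return (freqs_hz >= band.f_lo) & (freqs_hz < band.f_hi)


def band_energy(
    signal: np.ndarray, band: BandDefinition | None, fs: float
) -> float:
    """Spectral energy P_i = sum |X_k|^2 / N over DFT bins in [f_lo, f_hi).

    With band=None the sum runs over the whole spectrum and equals the
    time-domain sum of squares (Parseval's identity) to float precision.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2:
        raise ValueError("need at least 2 samples")
    power, cyc = _periodogram(signal)
    freqs = cyc * fs
    mask = _band_mask(freqs, band)
    if not mask.any():
        raise DegenerateBandError(
            f"band {band.name if band else 'full'} contains no DFT bins at "
            f"N={len(signal)}, fs={fs}"
        )
    return float(power[mask].sum())


def band_energy_ratio(
    signal: np.ndarray, band: BandDefinition, fs: float,
    total_band: BandDefinition = TOTAL_BAND,
) -> float:
    """Fraction of analysis-band energy in ``band``."""
    total = band_energy(signal, total_band, fs)
    if total <= 0:
        raise DegenerateBandError("zero total energy: ratio undefined")
    return band_energy(signal, band, fs) / total


def differential_entropy(
    signal: np.ndarray, band: BandDefinition | None, fs: float
) -> float:
    """Band differential entropy h_i = 0.5 * log(P_i) (natural log).

    Equals the band-limited-Gaussian closed form 0.5*log(2*pi*e*sigma_i^2)
    minus the epoch-length constant 0.5*log(2*pi*e/N); scaling the signal by
    a > 0 shifts the value by exactly log(a).
    """
    p = band_energy(signal, band, fs)
    if p <= 0:
        raise DegenerateBandError(
            f"band {band.name if band else 'full'} has zero energy; "
            "differential entropy undefined"
        )
    return float(0.5 * np.log(p))


def spectral_descriptors(
    signal: np.ndarray, band: BandDefinition, fs: float
) -> tuple[float, float]:
    """(centroid frequency, frequency variability) of the band periodogram.

    Centroid is the power-weighted mean frequency; variability is the
    power-weighted standard deviation around it, both in Hz.
    """
    power, cyc = _periodogram(np.asarray(signal, dtype=float))
    freqs = cyc * fs
    mask = _band_mask(freqs, band)
    p = power[mask]
    f = freqs[mask]
    total = p.sum()
    if not mask.any() or total <= 0:
        raise DegenerateBandError(f"band {band.name}: no spectral power")
    centroid = float((f * p).sum() / total)
    variability = float(np.sqrt(((f - centroid) ** 2 * p).sum() / total))
    return centroid, variability


# ---------------------------------------------------------------------------
# time-domain primitives


def hjorth_parameters(signal: np.ndarray) -> tuple[float, float]:
    """(mobility, complexity) from first-difference variances."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    v0 = x.var()
    if v0 == 0:
        raise ValueError("constant signal: Hjorth parameters undefined")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    mobility = float(np.sqrt(d1.var() / v0))
    mob_d1 = np.sqrt(d2.var() / d1.var())
    return mobility, float(mob_d1 / mobility)


TIME_STAT_NAMES = (
    "mean", "squared_difference", "std", "max", "min", "median",
    "skewness", "kurtosis", "zero_crossings", "amplitude",
    "first_diff", "first_diff_norm", "second_diff", "second_diff_norm",
)


def time_domain_stats(signal: np.ndarray) -> dict[str, float]:
    """The 14 basic time-domain statistics, in canonical order.

    "second difference" is x[n+2] - x[n]; the normalised variants divide by
    the signal standard deviation (0 for a constant signal).
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    d1 = np.diff(x)
    d2 = x[2:] - x[:-2]
    sd = float(x.std())
    s = np.sign(x)
    nz = s != 0
    crossings = int(np.count_nonzero(np.diff(s[nz]) != 0))
    if sd > 0:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))  # excess kurtosis
    else:
        skew = kurt = 0.0
    return {
        "mean": float(x.mean()),
        "squared_difference": float(np.mean(d1**2)),
        "std": sd,
        "max": float(x.max()),
        "min": float(x.min()),
        "median": float(np.median(x)),
        "skewness": skew,
        "kurtosis": kurt,
        "zero_crossings": float(crossings),
        "amplitude": float(np.ptp(x)),
        "first_diff": float(np.mean(np.abs(d1))),
        "first_diff_norm": float(np.mean(np.abs(d1)) / sd) if sd > 0 else 0.0,
        "second_diff": float(np.mean(np.abs(d2))),
        "second_diff_norm": float(np.mean(np.abs(d2)) / sd) if sd > 0 else 0.0,
    }


def fractal_dimension(signal: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension (see :func:`emoeeg.entropy.higuchi_fd`)."""
    return ent.higuchi_fd(np.asarray(signal, dtype=float), k_max=k_max)


def instability_index(signal: np.ndarray, n_segments: int = 4) -> float:
    """Nonstationarity score: variance of per-segment variances over the
    squared overall variance. Near 0 for stationary signals; amplitude-scale
    invariant."""
    x = np.asarray(signal, dtype=float)
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    if n_segments > len(x):
        raise ValueError("more segments than samples")
    v0 = x.var()
    if v0 == 0:
        raise ValueError("constant signal: instability index undefined")
    segs = np.array_split(x, n_segments)
    seg_vars = np.array([s.var() for s in segs])
    return float(seg_vars.var() / v0**2)


@dataclass(frozen=True)
class EntropyParams:
    m: int = 2
    r_factor: float = 0.2  # r = r_factor * sd -> scale invariance
    fuzzy_n: float = 2.0
    perm_order: int = 3
    perm_delay: int = 1


ENTROPY_NAMES = (
    "sample_entropy", "approximate_entropy", "fuzzy_entropy",
    "permutation_entropy", "spectral_entropy",
)


def signal_entropies(
    signal: np.ndarray, fs: float, params: EntropyParams = EntropyParams()
) -> dict[str, float]:
    """The five entropy descriptors with r bound to 0.2 x sd."""
    x = np.asarray(signal, dtype=float)
    r = params.r_factor * float(x.std())
    if r <= 0:
        raise ValueError("zero-variance signal: embedding entropies undefined")
    return {
        "sample_entropy": ent.sample_entropy(x, m=params.m, r=r),
        "approximate_entropy": ent.approximate_entropy(x, m=params.m, r=r),
        "fuzzy_entropy": ent.fuzzy_entropy(x, m=params.m, r=r, n_fuzzy=params.fuzzy_n),
        "permutation_entropy": ent.permutation_entropy(
            x, order=params.perm_order, delay=params.perm_delay
        ),
        "spectral_entropy": ent.spectral_entropy(
            x, fs, TOTAL_BAND.f_lo, TOTAL_BAND.f_hi
        ),
    }


# ---------------------------------------------------------------------------
# the 59-feature baseline vector

_ENERGY_ORDER = (
    "low_delta", "high_delta", "delta", "theta",
    "low_alpha", "high_alpha", "alpha",
    "low_beta", "high_beta", "beta",
    "low_gamma", "high_gamma", "gamma",
)


def extract_baseline_features(
    signal: np.ndarray,
    fs: float,
    entropy_params: EntropyParams = EntropyParams(),
) -> dict[str, float]:
    """The full 59-feature vector for one channel of one epoch.

    Raises on any non-finite value, naming the offending feature.
    """
    x = np.asarray(signal, dtype=float)
    out: dict[str, float] = {}
    out.update(time_domain_stats(x))
    mob, comp = hjorth_parameters(x)
    out["hjorth_mobility"] = mob
    out["hjorth_complexity"] = comp
    out["fractal_dimension"] = fractal_dimension(x)
    out["instability_index"] = instability_index(x)

    power, cyc = _periodogram(x)
    freqs = cyc * fs

    def _p(band: BandDefinition) -> float:
        mask = _band_mask(freqs, band)
        if not mask.any():
            raise DegenerateBandError(f"band {band.name}: no DFT bins")
        return float(power[mask].sum())

    total = _p(TOTAL_BAND)
    out["total_energy"] = total
    band_p = {b.name: _p(b) for b in (*MAIN_BANDS, *SUB_BANDS)}
    for name in _ENERGY_ORDER:
        out[f"{name}_energy"] = band_p[name]
    for name in MAIN_BAND_NAMES:
        out[f"{name}_ratio"] = band_p[name] / total
    for name in MAIN_BAND_NAMES:
        p = band_p[name]
        if p <= 0:
            raise DegenerateBandError(f"band {name}: zero energy, DE undefined")
        out[f"{name}_de"] = float(0.5 * np.log(p))
    descriptors = {
        band.name: spectral_descriptors(x, band, fs)
        for band in (TOTAL_BAND, *MAIN_BANDS)
    }
    for name, (c, _) in descriptors.items():
        out[f"{name}_centroid"] = c
    for name, (_, v) in descriptors.items():
        out[f"{name}_freq_variability"] = v
    out.update(signal_entropies(x, fs, entropy_params))

    for name, value in out.items():
        if not np.isfinite(value):
            raise ValueError(f"feature {name!r} is non-finite ({value})")
    return out


BASELINE_FEATURE_COUNT = 59

FEATURE_SETS = ("baseline", "ratio_de", "de", "ratio", "dual20") + tuple(
    f"de_{b}" for b in MAIN_BAND_NAMES
)


def _focused_features(signal: np.ndarray, fs: float, feature_set: str) -> dict[str, float]:
    if feature_set == "ratio":
        return {
            f"{b.name}_ratio": band_energy_ratio(signal, b, fs) for b in MAIN_BANDS
        }
    if feature_set == "de":
        return {
            f"{b.name}_de": differential_entropy(signal, b, fs) for b in MAIN_BANDS
        }
    if feature_set in ("ratio_de", "dual20"):
        out = {
            f"{b.name}_ratio": band_energy_ratio(signal, b, fs) for b in MAIN_BANDS
        }
        out.update(
            {f"{b.name}_de": differential_entropy(signal, b, fs) for b in MAIN_BANDS}
        )
        return out
    if feature_set.startswith("de_"):
        band = get_band(feature_set[3:])
        return {f"{band.name}_de": differential_entropy(signal, band, fs)}
    raise KeyError(f"unknown feature set {feature_set!r}; known: {FEATURE_SETS}")


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Epochs x features table with channel-qualified column names."""

    values: pd.DataFrame
    labels: np.ndarray
    subjects: np.ndarray
    feature_set: str

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(self.values) != len(self.labels) or len(self.labels) != len(self.subjects):
            raise ValueError("row count mismatch between values, labels, subjects")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "__label", self.labels)
        df.insert(1, "__subject", self.subjects)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, feature_set: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("__label").to_numpy()
        subjects = df.pop("__subject").to_numpy()
        return cls(values=df, labels=labels, subjects=subjects, feature_set=feature_set)


def build_feature_matrix(
    epochs: list[LabeledEpoch],
    feature_set: str = "baseline",
    channels: list[str] | None = None,
    entropy_params: EntropyParams = EntropyParams(),
) -> FeatureMatrix:
    """Stack per-channel features over epochs.

    Per-channel width: baseline 59, ratio_de 10, de 5, ratio 5, de_<band> 1.
    ``dual20`` forces channels to (Fp1, Fp2) for the 2 x 10 = 20-column
    dual-frontal configuration.
    """
    if not epochs:
        raise ValueError("no epochs given")
    if feature_set not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {feature_set!r}; known: {FEATURE_SETS}")
    if feature_set == "dual20":
        channels = ["Fp1", "Fp2"]
    if channels is None:
        channels = list(epochs[0].channel_names)
    channels = check_channels(channels)

    rows = []
    for ep in epochs:
        row: dict[str, float] = {}
        for ch in channels:
            ci = ep.channel_names.index(ch)
            sig = ep.data[ci]
            if feature_set == "baseline":
                feats = extract_baseline_features(sig, ep.fs, entropy_params)
            else:
                feats = _focused_features(sig, ep.fs, feature_set)
            row.update({f"{ch}:{k}": v for k, v in feats.items()})
        rows.append(row)

    df = pd.DataFrame(rows)
    return FeatureMatrix(
        values=df,
        labels=np.array([ep.label for ep in epochs]),
        subjects=np.array([ep.subject_id for ep in epochs]),
        feature_set=feature_set,
    )


# ---------------------------------------------------------------------------
# normalisation


class FeatureNormalizer:
    """Column-wise normalisation with fit/transform split so statistics can
    be computed on training folds only."""

    def __init__(self, mode: str = "none"):
        if mode not in ("none", "zscore", "minmax01"):
            raise ValueError(f"unknown normalisation mode {mode!r}")
        self.mode = mode

    def fit(self, X: np.ndarray) -> "FeatureNormalizer":
        X = np.asarray(X, dtype=float)
        if self.mode == "zscore":
            self.center_ = X.mean(axis=0)
            scale = X.std(axis=0)
            if np.any(scale == 0):
                warnings.warn(
                    "zero-variance column(s) under z-score; left at 0",
                    stacklevel=2,
                )
            self.scale_ = np.where(scale == 0, 1.0, scale)
        elif self.mode == "minmax01":
            self.center_ = X.min(axis=0)
            rng = X.max(axis=0) - X.min(axis=0)
            self.scale_ = np.where(rng == 0, 1.0, rng)
        else:
            self.center_ = 0.0
            self.scale_ = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mode == "none":
            return X.copy()
        return (X - self.center_) / self.scale_


def normalize_features(matrix: FeatureMatrix, mode: str = "none") -> FeatureMatrix:
    """Normalise with statistics from the matrix itself (fit set = apply set)."""
    norm = FeatureNormalizer(mode).fit(matrix.values.to_numpy())
    values = pd.DataFrame(
        norm.transform(matrix.values.to_numpy()),
        columns=matrix.values.columns,
        index=matrix.values.index,
    )
    return FeatureMatrix(
        values=values,
        labels=matrix.labels.copy(),
        subjects=matrix.subjects.copy(),
        feature_set=matrix.feature_set,
    )
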
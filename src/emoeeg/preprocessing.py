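"""Cleaning and segmentation of multi-channel emotional EEG.

The multi-channel path is: zero-phase band-pass (0.5-45 Hz) + notch
(48-52 Hz) -> average re-reference -> ICA-based ocular removal -> 1-s
segmentation -> +/-80 uV amplitude rejection. The dual-frontal-channel path
cannot run plain ICA (two channels are too few), so each channel is first
decomposed by ensemble empirical mode decomposition and ICA runs on the
pooled intrinsic mode functions instead (see :func:`eemd_clean_dual_channel`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .emd import eemd
from .montage import frontal_weight
from .types import LabeledEpoch, Recording


class PreprocessConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass: tuple[float, float] = (0.5, 45.0)
    notch: tuple[float, float] = (48.0, 52.0)
    reference: str = "average"  # "average" | "none"
    epoch_length_s: float = 1.0
    reject_uV: float = 80.0
    ica: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.bandpass[0] < self.bandpass[1]:
            raise PreprocessConfigError("bandpass low must be < high and > 0")
        if self.reject_uV <= 0:
            raise PreprocessConfigError("reject_uV must be positive")
        if self.reference not in ("average", "none"):
            raise PreprocessConfigError(f"unknown reference {self.reference!r}")


def bandpass_notch_filter(
    recording: Recording, config: PreprocessConfig = PreprocessConfig()
) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass plus band-stop notch.

    Applied forward-backward (sosfiltfilt) so the phase response is zero;
    the 0.5 Hz high-pass edge removes any DC offset.
    """
    lo, hi = config.bandpass
    nyq = recording.fs / 2.0
    if hi >= nyq:
        raise PreprocessConfigError(
            f"bandpass high {hi} Hz needs fs > {2 * hi} Hz (fs={recording.fs})"
        )
    sos_bp = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    out = sps.sosfiltfilt(sos_bp, recording.data, axis=1)
    n_lo, n_hi = config.notch
    if n_lo < nyq:  # notch only applies when the band exists below Nyquist
        if n_hi >= nyq:
            raise PreprocessConfigError(
                f"notch band ({n_lo}, {n_hi}) does not fit below Nyquist {nyq}"
            )
        sos_notch = sps.butter(
            4, [n_lo / nyq, n_hi / nyq], btype="bandstop", output="sos"
        )
        out = sps.sosfiltfilt(sos_notch, out, axis=1)
    return recording.copy_with(out)


def rereference_average(recording: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean (common average reference)."""
    if recording.n_channels < 2:
        warnings.warn(
            "average re-reference skipped: fewer than 2 channels", stacklevel=2
        )
        return recording.copy_with(recording.data.copy())
    return recording.copy_with(recording.data - recording.data.mean(axis=0))


def segment_epochs(recording: Recording, epoch_length_s: float) -> list[LabeledEpoch]:
    """Cut non-overlapping contiguous windows from t=0; drop the partial tail."""
    n_per = int(round(epoch_length_s * recording.fs))
    if n_per <= 0:
        raise ValueError("epoch_length_s too short for this sampling rate")
    n_epochs = recording.n_samples // n_per
    return [
        LabeledEpoch(
            data=recording.data[:, i * n_per : (i + 1) * n_per].copy(),
            fs=recording.fs,
            channel_names=list(recording.channel_names),
            label=recording.clip_label,
            subject_id=recording.subject_id,
            clip_id=recording.clip_id,
        )
        for i in range(n_epochs)
    ]


def reject_amplitude(
    epochs: list[LabeledEpoch], reject_uV: float = 80.0
) -> list[LabeledEpoch]:
    """Drop epochs with any sample beyond +/-reject_uV on any channel."""
    if reject_uV <= 0:
        raise ValueError("reject_uV must be positive")
    return [ep for ep in epochs if np.abs(ep.data).max() <= reject_uV]


def _ocular_template(recording: Recording) -> np.ndarray:
    """Frontal-weighted channel average, low-passed at 4 Hz.

    Blinks project mostly onto frontal electrodes and live below ~4 Hz, so
    this reference trace is dominated by ocular activity whenever any is
    present.
    """
    w = np.array([frontal_weight(c) for c in recording.channel_names])
    ref = w @ recording.data / w.sum()
    nyq = recording.fs / 2.0
    sos = sps.butter(4, 4.0 / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, ref)


def _strip_low_freq(
    sources: np.ndarray, flagged: list[int], fs: float, f_cut: float = 8.0
) -> np.ndarray:
    """Remove the sub-f_cut content of flagged ICA sources (in a copy).

    Ocular activity lives below ~8 Hz; high-passing the flagged component
    rather than zeroing it keeps whatever faster activity the imperfect
    unmixing swept into it, so beta/gamma band power is not distorted.
    """
    cleaned = sources.copy()
    nyq = fs / 2.0
    sos = sps.butter(4, f_cut / nyq, btype="high", output="sos")
    for k in flagged:
        cleaned[:, k] = sps.sosfiltfilt(sos, sources[:, k])
    return cleaned


def _low_freq_fraction(x: np.ndarray, fs: float, f_cut: float = 4.0) -> float:
    """Fraction of spectral power below f_cut."""
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    p = np.abs(np.fft.rfft(x - x.mean())) ** 2
    total = p.sum()
    if total == 0:
        return 0.0
    return float(p[freqs < f_cut].sum() / total)


def remove_ocular_ica(
    recording: Recording,
    corr_threshold: float = 0.8,
    seed: int = 0,
) -> Recording:
    """Remove ocular components found by ICA on the multi-channel path.

    Decomposes the recording with FastICA (as many components as channels),
    flags components whose time course correlates with the frontal-weighted
    low-frequency ocular template above ``corr_threshold`` in magnitude and
    is itself low-frequency dominated, and reconstructs without them. With
    nothing flagged the reconstruction is the identity up to numerical
    round-off.
    """
    if recording.n_channels < 8:
        raise ValueError(
            "ICA ocular removal needs >= 8 channels; "
            "use the EEMD dual-channel path for 2-channel data"
        )
    X = recording.data.T  # samples x channels
    ica = FastICA(
        n_components=recording.n_channels,
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on clean data
        sources = ica.fit_transform(X)  # samples x components

    template = _ocular_template(recording)
    flagged = []
    for k in range(sources.shape[1]):
        s = sources[:, k]
        r = np.corrcoef(s, template)[0, 1]
        if abs(r) > corr_threshold and _low_freq_fraction(s, recording.fs) > 0.5:
            flagged.append(k)

    if not flagged:
        return recording.copy_with(recording.data.copy())
    cleaned_sources = _strip_low_freq(sources, flagged, recording.fs)
    cleaned = ica.inverse_transform(cleaned_sources).T
    return recording.copy_with(cleaned)


def eemd_clean_dual_channel(
    recording: Recording,
    n_ensembles: int = 100,
    noise_sd: float = 0.2,
    corr_threshold: float = 0.8,
    seed: int = 0,
    max_imfs: int | None = None,
) -> Recording:
    """Ocular cleaning for the two-frontal-channel path.

    Two channels are too few for ICA directly, so each channel is expanded
    by EEMD into intrinsic mode functions (IMFs); ICA then runs on the
    pooled IMF set, ocular-flagged components are zeroed, and each channel
    is rebuilt by summing its retained IMF parts plus its residue.

    noise_sd is relative to each channel's standard deviation.
    """
    if recording.n_channels != 2:
        raise ValueError(
            f"dual-channel cleaning needs exactly 2 channels, got {recording.n_channels}"
        )
    rng = np.random.default_rng(seed)
    imfs_per_ch = []
    residues = []
    for ci in range(2):
        x = recording.data[ci]
        imfs, residue = eemd(
            x,
            n_ensembles=n_ensembles,
            noise_sd=noise_sd * x.std(),
            rng=rng,
            max_imfs=max_imfs,
        )
        imfs_per_ch.append(imfs)
        residues.append(residue)

    pooled_all = np.vstack(imfs_per_ch)  # (n_imfs_total) x samples
    # unfilled IMF slots (trials produced fewer modes) are ~zero rows that
    # would break ICA whitening; keep only carrying modes
    scale = pooled_all.std(axis=1)
    carrying = scale > 1e-9 * max(scale.max(), 1e-30)
    pooled = pooled_all[carrying]
    n_comp = pooled.shape[0]
    ica = FastICA(
        n_components=n_comp,
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(pooled.T)  # samples x components

    # ocular reference: low-passed mean of the two frontal channels
    nyq = recording.fs / 2.0
    sos = sps.butter(4, 4.0 / nyq, btype="low", output="sos")
    template = sps.sosfiltfilt(sos, recording.data.mean(axis=0))

    flagged = []
    for k in range(sources.shape[1]):
        s = sources[:, k]
        r = np.corrcoef(s, template)[0, 1]
        if abs(r) > corr_threshold and _low_freq_fraction(s, recording.fs) > 0.5:
            flagged.append(k)

    pooled_clean = pooled_all.copy()
    if flagged:
        cleaned_sources = _strip_low_freq(sources, flagged, recording.fs)
        pooled_clean[carrying] = ica.inverse_transform(cleaned_sources).T

    out = np.empty_like(recording.data)
    n0 = imfs_per_ch[0].shape[0]
    out[0] = pooled_clean[:n0].sum(axis=0) + residues[0]
    out[1] = pooled_clean[n0:].sum(axis=0) + residues[1]
    return recording.copy_with(out)


def preprocess_recording(
    recording: Recording,
    config: PreprocessConfig = PreprocessConfig(),
    seed: int = 0,
) -> list[LabeledEpoch]:
    """Full multi-channel pipeline: filter -> re-reference -> ICA -> segment -> reject."""
    rec = bandpass_notch_filter(recording, config)
    if config.reference == "average":
        rec = rereference_average(rec)
    if config.ica and rec.n_channels >= 8:
        rec = remove_ocular_ica(rec, seed=seed)
    epochs = segment_epochs(rec, config.epoch_length_s)
    return reject_amplitude(epochs, config.reject_uV)


def preprocess_dual_channel(
    recording: Recording,
    config: PreprocessConfig = PreprocessConfig(reference="none"),
    n_ensembles: int = 100,
    seed: int = 0,
) -> list[LabeledEpoch]:
    """Dual-frontal pipeline: filter -> EEMD+ICA cleaning -> segment -> reject.

    Re-referencing is skipped: with two channels a common average would just
    subtract the channels' mean and destroy half the signal.
    """
    rec = recording if recording.n_channels == 2 else recording.pick(["Fp1", "Fp2"])
    rec = bandpass_notch_filter(rec, config)
    if config.ica:
        rec = eemd_clean_dual_channel(rec, n_ensembles=n_ensembles, seed=seed)
    epochs = segment_epochs(rec, config.epoch_length_s)
    return reject_amplitude(epochs, config.reject_uV)
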
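"""Generator behaviour: class effect, ratings, label filtering, determinism."""

import numpy as np
import pytest
from scipy import stats as sstats
from scipy.signal import welch

from emoeeg.montage import MontageError
from emoeeg.preprocessing import segment_epochs
from emoeeg.synthetic import (
    DatasetConfig,
    SubjectProfile,
    apply_label_filter,
    generate_dataset,
    generate_ratings,
    synthesize_subject_recording,
)
from emoeeg.types import LabeledEpoch, RatingRecord

FS = 250.0
SMALL_CHANNELS = ("Fp1", "Fp2", "Cz", "Pz")


def _welch_band_power(x, fs, f_lo, f_hi):
    f, p = welch(x, fs=fs, nperseg=min(len(x), 256))
    return p[(f >= f_lo) & (f < f_hi)].sum()


def _epoch_band_powers(profile, label, n_epochs, seed, channel, f_lo, f_hi):
    rec = synthesize_subject_recording(
        profile, label, float(n_epochs), FS, seed, channels=[channel, "Cz"]
    )
    return np.array(
        [
            _welch_band_power(ep.data[0], FS, f_lo, f_hi)
            for ep in segment_epochs(rec, 1.0)
        ]
    )


class TestSynthesizeRecording:
    def test_same_seed_is_bit_identical(self, clean_profile):
        a = synthesize_subject_recording(clean_profile, "positive", 2.0, FS, 3)
        b = synthesize_subject_recording(clean_profile, "positive", 2.0, FS, 3)
        assert np.array_equal(a.data, b.data)

    def test_unknown_channel_rejected(self, clean_profile):
        with pytest.raises(MontageError):
            synthesize_subject_recording(
                clean_profile, "positive", 1.0, FS, 0, channels=["Fp1", "XX9"]
            )

    def test_no_effect_null_indistinguishable(self):
        """With effect_size 1 the class variances match (two-sample test)."""
        prof = SubjectProfile(effect_size=1.0)
        pos = _epoch_band_powers(prof, "positive", 100, 11, "Fp1", 30, 45)
        neg = _epoch_band_powers(prof, "negative", 100, 12, "Fp1", 30, 45)
        _, p = sstats.ttest_ind(pos, neg)
        assert p > 0.01

    def test_gamma_effect_ratio_recovered_on_target_channel_only(self):
        """effect_size 4 in gamma on Fp1: empirical variance ratio ~4 there,
        ~1 on the untouched Cz."""
        prof = SubjectProfile(
            effect_channels=frozenset({"Fp1"}),
            effect_bands=frozenset({"gamma"}),
            effect_size=4.0,
        )
        rec_p = synthesize_subject_recording(
            prof, "positive", 200.0, FS, 21, channels=["Fp1", "Cz"]
        )
        rec_n = synthesize_subject_recording(
            prof, "negative", 200.0, FS, 22, channels=["Fp1", "Cz"]
        )

        def mean_gamma(rec, ch_idx):
            return np.mean(
                [
                    _welch_band_power(ep.data[ch_idx], FS, 30, 45)
                    for ep in segment_epochs(rec, 1.0)
                ]
            )

        ratio_fp1 = mean_gamma(rec_p, 0) / mean_gamma(rec_n, 0)
        ratio_cz = mean_gamma(rec_p, 1) / mean_gamma(rec_n, 1)
        assert 3.0 <= ratio_fp1 <= 5.0
        assert 0.85 <= ratio_cz <= 1.18

    def test_band_variances_match_request(self):
        """Requested band powers are realised within 10% (200-epoch mean),
        judged by an independent Welch periodogram."""
        prof = SubjectProfile(pink_power=0.0, effect_size=1.0)
        rec = synthesize_subject_recording(
            prof, "negative", 200.0, FS, 31, channels=["Cz", "Pz"]
        )
        epochs = segment_epochs(rec, 1.0)
        for f_lo, f_hi, name in ((4, 8, "theta"), (8, 13, "alpha"), (30, 45, "gamma")):
            est = np.mean(
                [_welch_band_power(ep.data[0], FS, f_lo, f_hi) for ep in epochs]
            )
            want = prof.baseline_band_power[name]
            assert abs(est - want) / want < 0.10, name


class TestRatings:
    def test_noise_free_ratings_hit_the_threshold_rule(self, clean_profile):
        prof = SubjectProfile(rating_noise_sd=0.0)
        pos = generate_ratings(prof, "positive", 0)
        neg = generate_ratings(prof, "negative", 0)
        assert pos.valence == 7.0 and pos.high_valence
        assert neg.valence == 3.0 and neg.low_valence

    def test_mismatch_fraction_matches_normal_tail(self):
        """P(positive clip rated <= 4.5) equals the normal-tail probability
        of the clip distribution (mean 7, sd 3) within 3 points."""
        prof = SubjectProfile(rating_noise_sd=3.0)
        n = 1000
        frac = (
            sum(
                not generate_ratings(prof, "positive", s).high_valence
                for s in range(n)
            )
            / n
        )
        expected = sstats.norm.cdf((4.5 - 7.0) / 3.0)
        assert abs(frac - expected) < 0.03

    def test_rating_bounds_enforced(self):
        with pytest.raises(ValueError):
            RatingRecord(valence=0.5, arousal=5, dominance=5, liking=5)


def _dummy_epoch(label, clip_id):
    return LabeledEpoch(
        data=np.zeros((1, 10)),
        fs=10.0,
        channel_names=["Cz"],
        label=label,
        subject_id="S01",
        clip_id=clip_id,
    )


class TestLabelFilter:
    def test_concordant_clips_all_retained(self):
        epochs = [
            _dummy_epoch("positive" if c < 4 else "negative", f"c{c}")
            for c in range(8)
            for _ in range(60)
        ]
        ratings = {
            f"c{c}": RatingRecord(
                valence=7 if c < 4 else 3, arousal=6, dominance=5, liking=5
            )
            for c in range(8)
        }
        assert len(apply_label_filter(epochs, ratings)) == 480

    def test_discordant_clip_fully_deleted(self):
        epochs = [_dummy_epoch("positive", "c0") for _ in range(60)]
        ratings = {"c0": RatingRecord(valence=4.0, arousal=6, dominance=5, liking=5)}
        assert apply_label_filter(epochs, ratings) == []

    def test_exact_midpoint_counts_as_mismatch(self):
        epochs = [_dummy_epoch("positive", "c0"), _dummy_epoch("negative", "c1")]
        ratings = {
            "c0": RatingRecord(valence=4.5, arousal=6, dominance=5, liking=5),
            "c1": RatingRecord(valence=4.5, arousal=6, dominance=5, liking=5),
        }
        assert apply_label_filter(epochs, ratings) == []

    def test_empty_input_and_missing_rating(self):
        assert apply_label_filter([], {}) == []
        with pytest.raises(KeyError):
            apply_label_filter([_dummy_epoch("positive", "c9")], {})

    def test_noisier_ratings_never_retain_more_epochs(self):
        """Retained-epoch count is non-increasing in rating noise (20-seed mean)."""
        epochs = [
            _dummy_epoch("positive" if c < 4 else "negative", f"c{c}")
            for c in range(8)
            for _ in range(10)
        ]

        def mean_retained(sd):
            total = 0
            for seed in range(20):
                prof = SubjectProfile(rating_noise_sd=sd)
                ratings = {
                    f"c{c}": generate_ratings(
                        prof, "positive" if c < 4 else "negative", (seed, c)
                    )
                    for c in range(8)
                }
                total += len(apply_label_filter(epochs, ratings))
            return total / 20

        assert mean_retained(0.5) >= mean_retained(2.0) >= mean_retained(4.0)


class TestGenerateDataset:
    def test_recording_and_epoch_counts(self):
        cfg = DatasetConfig(
            n_subjects=2,
            clips_per_class=4,
            clip_duration_s=4.0,
            fs=100.0,
            channels=SMALL_CHANNELS,
            profile=SubjectProfile(rating_noise_sd=0.0),
        )
        ds = generate_dataset(cfg, seed=0)
        assert len(ds.recordings) == 2 * 8
        assert len(ds.ratings) == 2 * 8
        # noise-free ratings are always concordant: 2 subjects x 8 clips x 4 epochs
        assert len(ds.epochs) == 2 * 8 * 4

    def test_single_subject_balanced_epochs(self):
        cfg = DatasetConfig(
            n_subjects=1,
            clips_per_class=4,
            clip_duration_s=60.0,
            fs=100.0,
            channels=SMALL_CHANNELS,
            apply_rating_filter=False,
        )
        ds = generate_dataset(cfg, seed=1)
        labels = [ep.label for ep in ds.epochs]
        assert len(labels) == 480
        assert labels.count("positive") == 240
        assert labels.count("negative") == 240

    def test_dataset_determinism(self):
        cfg = DatasetConfig(
            n_subjects=1,
            clips_per_class=2,
            clip_duration_s=2.0,
            fs=100.0,
            channels=SMALL_CHANNELS,
        )
        a = generate_dataset(cfg, seed=5)
        b = generate_dataset(cfg, seed=5)
        assert len(a.epochs) == len(b.epochs)
        for ea, eb in zip(a.epochs, b.epochs):
            assert np.array_equal(ea.data, eb.data)
            assert ea.label == eb.label

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(n_subjects=0)
        with pytest.raises(ValueError):
            DatasetConfig(clips_per_class=-1)
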
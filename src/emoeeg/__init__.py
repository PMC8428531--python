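"""emoeeg: positive/negative emotion classification from EEG band features.

A reusable pipeline around the band differential-entropy approach to
binary emotion recognition: synthetic emotional-EEG generation with a known
class effect, preprocessing (zero-phase filtering, average reference, ICA
or EEMD+ICA ocular removal, 1-s segmentation, amplitude rejection), a
59-feature per-channel descriptor set, gradient-boosting electrode
selection, and four classifiers compared under stratified 10-fold
cross-validation in pooled and per-subject schemes.
"""

from .bands import BandDefinition, MAIN_BANDS, TOTAL_BAND, get_band
from .classify import (
    ClassifierSpec,
    CVResult,
    evaluate_single,
    evaluate_whole,
    kfold_split,
    train_and_score,
)
from .features import (
    FeatureMatrix,
    band_energy,
    band_energy_ratio,
    build_feature_matrix,
    differential_entropy,
    extract_baseline_features,
    normalize_features,
)
from .montage import MONTAGE_32
from .pipeline import SuiteConfig, paper_mimic_suite, report_tables, run_suite
from .preprocessing import (
    PreprocessConfig,
    bandpass_notch_filter,
    eemd_clean_dual_channel,
    preprocess_recording,
    reject_amplitude,
    remove_ocular_ica,
    rereference_average,
    segment_epochs,
)
from .selection import (
    ContributionTable,
    ElectrodeScheme,
    FIXED_SCHEMES,
    build_scheme,
    fit_gbdt_contributions,
    reference_table,
)
from .synthetic import (
    DatasetConfig,
    SubjectProfile,
    apply_label_filter,
    full_study_config,
    generate_dataset,
    generate_ratings,
    synthesize_subject_recording,
)
from .types import LabeledEpoch, RatingRecord, Recording

__version__ = "0.1.0"
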
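"""Compare the 59-feature baseline against the focused band feature sets.

Runs the baseline (1888-dimensional over 32 channels) and the energy-ratio /
differential-entropy ablations — combined, each alone, and the combined set
under z-score and [0,1] normalisation — through all four classifiers in both
evaluation schemes. Writes results/03_feature_sets/.
"""

from emoeeg.pipeline import ExperimentConfig, SuiteConfig, run_suite, summarize

SEED = 1


def main() -> None:
    config = SuiteConfig(
        experiments=[
            ExperimentConfig("1_baseline59", "baseline"),
            ExperimentConfig("2-1_ratio_de", "ratio_de"),
            ExperimentConfig("2-2_ratio_de_zscore", "ratio_de", normalize="zscore"),
            ExperimentConfig("2-3_ratio_de_minmax", "ratio_de", normalize="minmax01"),
            ExperimentConfig("2-4_de", "de"),
            ExperimentConfig("2-5_ratio", "ratio"),
        ],
        seed=SEED,
        fit_contributions=False,
        out_dir="results/03_feature_sets",
    )
    out = run_suite(config)
    print(out["table"].to_string(index=False))
    print(summarize(out["table"]))


if __name__ == "__main__":
    main()
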
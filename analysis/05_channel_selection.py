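"""Select electrodes by GBDT contribution on gamma-band DE and compare the
five electrode-combination schemes.

Fits the gradient-boosting selector on one gamma-DE feature per electrode,
writes the contribution table, then evaluates the forehead pair, the two
published threshold groups, the head-loop ring and the half loop under all
four classifiers. Writes results/05_channel_selection/.
"""

from emoeeg.pipeline import ExperimentConfig, SuiteConfig, run_suite, summarize

SEED = 1


def main() -> None:
    config = SuiteConfig(
        experiments=[
            ExperimentConfig("5-1_forehead", "de_gamma", electrode_scheme="forehead"),
            ExperimentConfig("5-2_gt_05", "de_gamma", electrode_scheme="forehead_gt_05"),
            ExperimentConfig("5-3_gt_03", "de_gamma", electrode_scheme="contribution_gt_03"),
            ExperimentConfig("5-4_head_loop", "de_gamma", electrode_scheme="head_loop"),
            ExperimentConfig("5-5_half_loop", "de_gamma", electrode_scheme="half_loop"),
        ],
        seed=SEED,
        fit_contributions=True,
        out_dir="results/05_channel_selection",
    )
    out = run_suite(config)
    print("electrode contributions (gamma-band DE):")
    for electrode, rate in out["contributions"].entries[:10]:
        print(f"  {electrode:>5s}  {rate:.4f}")
    print(out["table"].to_string(index=False))
    print(summarize(out["table"]))


if __name__ == "__main__":
    main()
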
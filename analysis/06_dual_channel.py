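"""The dual-frontal-channel configuration: Fp1/Fp2 only, 20 features.

Two channels are too few for plain ICA, so each channel is decomposed by
EEMD and ICA runs on the pooled intrinsic mode functions before the band
energy ratios and differential entropies (2 channels x 10 features) are
classified. Writes results/06_dual_channel/.
"""

from emoeeg.pipeline import ExperimentConfig, SuiteConfig, run_suite, summarize

SEED = 1


def main() -> None:
    config = SuiteConfig(
        experiments=[
            ExperimentConfig("6_dual20", "dual20", dual_channel=True),
        ],
        seed=SEED,
        fit_contributions=False,
        out_dir="results/06_dual_channel",
    )
    out = run_suite(config)
    print(out["table"].to_string(index=False))
    print(summarize(out["table"]))


if __name__ == "__main__":
    main()
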
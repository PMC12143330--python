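"""Regenerate the committed worked fixture and its golden result tables.

Run from the repository root after any intentional change to the fixture or
to result-table formats:

    python scripts/regen_fixture.py
"""

from pathlib import Path

from hapase import io
from hapase.pipeline import PipelineConfig, run_pipeline
from hapase.simulate import make_worked_fixture

ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = ROOT / "tests" / "data" / "fixture"
GOLDEN_DIR = ROOT / "tests" / "data" / "golden"


def main() -> None:
    cohort = make_worked_fixture()
    FIXTURE_DIR.mkdir(parents=True, exist_ok=True)
    cohort.write(FIXTURE_DIR)
    results = run_pipeline(cohort.records, cohort.tpm, PipelineConfig())
    GOLDEN_DIR.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        io.write_table(df, GOLDEN_DIR / f"{name}.tsv")
    print(f"fixture -> {FIXTURE_DIR}\ngolden  -> {GOLDEN_DIR}")


if __name__ == "__main__":
    main()
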
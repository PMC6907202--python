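"""Simulate the study panel: 15 clones of one heterozygous mother.

Writes two fixtures under results/: a clean panel (all caller metrics
passing, no artifact genotypes) used by the downstream analyses, and a
noisy variant of the same panel (8% of records carry a failing hard-filter
metric, 0.4% of genotypes spiked to erroneous hom-alt) used to demonstrate
the sanitation stages.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import FIXTURE, FIXTURE_NOISY, ensure_fixture

import pandas as pd


def main() -> None:
    ensure_fixture()
    truth = pd.read_csv(FIXTURE / "truth.tsv", sep="\t")
    print(f"fixture:       {FIXTURE}")
    print(f"noisy variant: {FIXTURE_NOISY}")
    print("\ntruth records by type and origin:")
    print(truth.groupby(["vartype", "origin"]).size().to_string())
    small = truth[truth["vartype"].isin(["SNV", "INDEL"])]
    shared = (small["carriers"].str.split(",").map(len) == 15).mean()
    print(f"\nheterozygous small variants shared by all 15 clones: "
          f"{100 * shared:.1f}%")


if __name__ == "__main__":
    main()
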
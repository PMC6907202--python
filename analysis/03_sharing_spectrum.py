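"""The clone-sharing spectrum: variants shared by only N of 15 clones.

Heterozygous sites split into ancestral heterozygosity (N = 15, inherited
from the mother) and somatic mutations (N = 1 private events in a star
pedigree).  Writes the per-type, per-feature spectrum and prints the
headline fractions.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from _common import CLONES, FIXTURE, TABLES, ensure_fixture, \
    load_index_and_genes, load_sanitized

from clonediv.simulate import read_te_table
from clonediv.spectrum import build_spectrum, headline_fractions
from clonediv.variants import read_sv_table


def main() -> None:
    ensure_fixture()
    table = load_sanitized()
    _, _, index = load_index_and_genes()
    te = read_te_table(FIXTURE / "tei.tsv")
    sv = read_sv_table(FIXTURE / "svs.vcf")
    spec = build_spectrum(table, CLONES, index, te_table=te, sv_table=sv)
    spec.to_csv(TABLES / "sharing_spectrum.tsv", sep="\t", index=False)
    head = headline_fractions(spec, len(CLONES))
    head.to_csv(TABLES / "sharing_headline.tsv", sep="\t", index=False)
    print(head.round(3).to_string(index=False))
    print("\nSNV spectrum (all features):")
    snv = spec[(spec["vartype"] == "SNV") & (spec["feature"] == "all")]
    print(snv[["N", "count", "proportion"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
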
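"""Transition/transversion ratios and cytosine-context signatures.

Clone-unique heterozygous SNVs (N = 1) are stratified by feature class:
methylated-cytosine deamination predicts an elevated Ti/Tv in repeats and
the highest percentage of CpG/CHG/CHH sites carrying C-to-T transitions in
repeat-rich intergenic space.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import CLONES, TABLES, ensure_fixture, load_index_and_genes, \
    load_sanitized

from clonediv.pipeline import _per_variant_frame, _unique_het_snvs
from clonediv.signature import context_transition_percentages, titv_ratio


def main() -> None:
    ensure_fixture()
    table = load_sanitized()
    reference, _, index = load_index_and_genes()
    pv = _per_variant_frame(table, CLONES, index)
    uniq = _unique_het_snvs(pv, CLONES)
    titv = titv_ratio(uniq, by=["feature"])
    titv.to_csv(TABLES / "titv_by_feature.tsv", sep="\t", index=False)
    print("Ti/Tv of clone-unique heterozygous SNVs by feature:")
    print(titv.round(3).to_string(index=False))

    per_clone, summary = context_transition_percentages(
        uniq, reference, index, CLONES)
    per_clone.to_csv(TABLES / "context_percent_per_clone.tsv", sep="\t",
                     index=False)
    summary.to_csv(TABLES / "context_percent_summary.tsv", sep="\t",
                   index=False)
    print("\nmean % of context cytosine sites with a unique C>T transition:")
    print(summary.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
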
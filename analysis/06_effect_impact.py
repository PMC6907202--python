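"""Variant effects and the deleterious fraction by sharing level.

Classifies every exonic small variant against the gene models (codon
translation for SNVs, frame arithmetic for INDELs, canonical splice sites)
and reports the fraction of exonic variants that are putatively
deleterious (high impact) at each sharing level N — private mutations are
expected to carry a larger deleterious fraction than ancestral ones.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from _common import CLONES, TABLES, ensure_fixture, load_index_and_genes, \
    load_sanitized

from clonediv.effects import classify_effect, deleterious_fraction_by_sharing
from clonediv.features import EXON
from clonediv.pipeline import _per_variant_frame


def main() -> None:
    ensure_fixture()
    table = load_sanitized()
    reference, genes, index = load_index_and_genes()
    pv = _per_variant_frame(table, CLONES, index)
    exonic = pv[pv["feature"] == EXON]
    rows = []
    for rec in exonic.itertuples(index=False):
        call = classify_effect(rec.contig, rec.pos, rec.ref, rec.alt,
                               genes, reference)
        rows.append({"contig": rec.contig, "pos": rec.pos, "N": rec.N,
                     "category": call.category, "impact": call.impact,
                     "gene_id": call.gene_id})
    effects = pd.DataFrame(rows)
    effects.to_csv(TABLES / "exonic_effects.tsv", sep="\t", index=False)
    print("exonic effect categories:")
    print(effects["category"].value_counts().to_string())
    frac = deleterious_fraction_by_sharing(effects, None)
    frac.to_csv(TABLES / "impact_by_sharing.tsv", sep="\t", index=False)
    print("\ndeleterious fraction by sharing level:")
    print(frac.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
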
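"""TE-insertion sharing and gene proximity; structural-variant summary.

TE insertions are mostly shared by the whole panel with a minority of
private events, mirroring the small-variant spectrum; intergenic
insertions are summarized by their distance to the nearest gene.  SVs are
summarized per type (count, median and total size, percent of assembly,
genes intersected).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import CLONES, FIXTURE, TABLES, ensure_fixture, \
    load_index_and_genes

from clonediv.features import nearest_gene_distances, summarize_svs
from clonediv.simulate import read_te_table
from clonediv.spectrum import build_spectrum, merge_svs
from clonediv.variants import VariantTable, read_sv_table


def main() -> None:
    ensure_fixture()
    _, genes, index = load_index_and_genes()
    te = read_te_table(FIXTURE / "tei.tsv")
    spec = build_spectrum(VariantTable(CLONES, []), CLONES, te_table=te)
    spec.to_csv(TABLES / "te_sharing_spectrum.tsv", sep="\t", index=False)
    n_all = spec.loc[spec["N"] == len(CLONES), "count"].sum()
    n_one = spec.loc[spec["N"] == 1, "count"].sum()
    total = spec["count"].sum()
    print(f"TE insertions: {total} total, {100 * n_all / total:.1f}% shared "
          f"by all clones, {100 * n_one / total:.1f}% private")

    dist, dist_summary = nearest_gene_distances(te, genes)
    dist.to_csv(TABLES / "te_gene_distances.tsv", sep="\t", index=False)
    print("\nintergenic TE distance to nearest gene:")
    print(dist_summary.round(1).to_string(index=False))

    sv = merge_svs(read_sv_table(FIXTURE / "svs.vcf"))
    assembly_length = sum(len(a) for a in index.codes.values())
    summary = summarize_svs(sv, genes, assembly_length)
    summary.to_csv(TABLES / "sv_summary.tsv", sep="\t", index=False)
    print("\nstructural variants by type:")
    cols = ["svtype", "count", "median_size", "total_size", "pct_assembly",
            "genes_intersected"]
    print(summary[cols].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
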
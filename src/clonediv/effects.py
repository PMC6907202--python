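"""Minimal variant-effect classification over gene models.

Classifies SNVs and INDELs against transcript CDS geometry and flags the
putatively deleterious ("high impact") categories: exon loss, start/stop
gain or loss, frameshift, gene fusion, and canonical splice acceptor/donor
disruption.  Severity selection across transcripts is deterministic (fixed
category order, ties broken by transcript id).

Coordinates are 1-based; variants are assumed left-aligned with the usual
VCF anchor-base convention for INDELs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genes import GeneModel

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")

HIGH_IMPACT = frozenset({
    "gene_fusion", "exon_loss", "frameshift", "stop_gained", "stop_lost",
    "start_lost", "start_gained", "splice_acceptor", "splice_donor",
})

# most severe first; aggregation across transcripts picks the lowest rank
SEVERITY_ORDER = (
    "gene_fusion", "exon_loss", "frameshift", "stop_gained", "stop_lost",
    "start_lost", "splice_acceptor", "splice_donor", "start_gained",
    "missense", "inframe_indel", "synonymous", "noncoding_exonic",
    "intronic", "intergenic",
)
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

IMPACT_BY_CATEGORY = {
    **{c: "HIGH" for c in HIGH_IMPACT},
    "missense": "MODERATE", "inframe_indel": "MODERATE",
    "synonymous": "LOW",
    "noncoding_exonic": "MODIFIER", "intronic": "MODIFIER",
    "intergenic": "MODIFIER",
}


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class EffectCall:
    category: str
    impact: str
    gene_id: str | None = None
    transcript_id: str | None = None


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return "".join(GENETIC_CODE.get(seq[i:i + 3], "X") for i in range(0, n, 3))


def _fetch(reference, contig: str, start0: int, end0: int) -> str:
    return str(reference[contig][max(start0, 0):end0]).upper()


def cds_sequence(model: GeneModel, reference) -> str:
    """Coding-strand CDS sequence, 5'→3'."""
    parts = [
        _fetch(reference, model.contig, s - 1, e) for s, e in model.cds
    ]
    seq = "".join(parts)
    return seq if model.strand == "+" else revcomp(seq)


def _splice_category(model: GeneModel, affected: set[int]) -> str | None:
    """splice_donor / splice_acceptor if the canonical 2 bp are touched.

    Donor = first 2 intronic bases 5' of the intron on the coding strand,
    acceptor = last 2 (3' side); genomic orientation flips with strand.
    """
    for s, e in model.introns():
        left = {s, min(s + 1, e)}       # intron start, genomic
        right = {max(e - 1, s), e}      # intron end, genomic
        donor, acceptor = (left, right) if model.strand == "+" else (right, left)
        if affected & donor:
            return "splice_donor"
        if affected & acceptor:
            return "splice_acceptor"
    return None


def _classify_cds_snv(model: GeneModel, reference, pos: int,
                      ref: str, alt: str) -> str:
    offset = model.cds_offset(pos)
    assert offset is not None
    cds = cds_sequence(model, reference)
    ref_c, alt_c = (ref, alt) if model.strand == "+" else (
        revcomp(ref), revcomp(alt))
    if cds[offset] != ref_c:
        raise ReferenceMismatchError(
            f"{model.transcript_id}: CDS base at offset {offset} is "
            f"{cds[offset]}, variant says {ref_c}"
        )
    codon_i = offset // 3
    within = offset % 3
    codon = cds[codon_i * 3:codon_i * 3 + 3]
    mutated = codon[:within] + alt_c + codon[within + 1:]
    if len(codon) < 3:  # trailing partial codon in a malformed model
        return "noncoding_exonic"
    ref_aa = GENETIC_CODE.get(codon, "X")
    alt_aa = GENETIC_CODE.get(mutated, "X")
    if codon_i == 0 and mutated != "ATG":
        return "start_lost"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained"
    return "synonymous" if ref_aa == alt_aa else "missense"


def _classify_cds_indel(model: GeneModel, reference, pos: int,
                        ref: str, alt: str) -> str:
    """INDEL with its edited bases inside CDS of this transcript."""
    net = len(alt) - len(ref)
    cds = cds_sequence(model, reference)
    mutated = _mutated_cds(model, reference, pos, ref, alt)
    # a deletion removing start-codon bases, or an insertion splitting the
    # start codon, destroys the annotated start regardless of frame
    if mutated[:3] != "ATG" and cds[:3] == "ATG":
        return "start_lost"
    if net % 3 != 0:
        return "frameshift"
    ref_prot = translate(cds)
    alt_prot = translate(mutated)
    ref_stop = ref_prot.find("*")
    alt_stop = alt_prot.find("*")
    ref_premature = 0 <= ref_stop < len(ref_prot) - 1
    alt_premature = 0 <= alt_stop < len(alt_prot) - 1
    if alt_premature and not ref_premature:
        return "stop_gained"
    return "inframe_indel"


def _mutated_cds(model: GeneModel, reference, pos: int,
                 ref: str, alt: str) -> str:
    """CDS sequence after applying an indel that lies within one interval."""
    parts = []
    for s, e in model.cds:
        seg = _fetch(reference, model.contig, s - 1, e)
        if s <= pos <= e:
            off = pos - s
            if pos + len(ref) - 1 <= e and seg[off:off + len(ref)] != ref:
                raise ReferenceMismatchError(
                    f"{model.transcript_id}: reference mismatch at "
                    f"{model.contig}:{pos}"
                )
            seg = seg[:off] + alt + seg[off + len(ref):]
        parts.append(seg)
    seq = "".join(parts)
    return seq if model.strand == "+" else revcomp(seq)


def classify_effect_transcript(
    contig: str, pos: int, ref: str, alt: str,
    model: GeneModel, reference,
) -> str:
    """Effect category of one variant against one transcript."""
    if model.contig != contig:
        return "intergenic"
    affected = set(range(pos, pos + max(len(ref), 1)))
    if len(ref) > 1 and len(alt) <= len(ref):
        deleted = range(pos + 1, pos + len(ref))
        # deletion swallowing at least one complete exon
        for s, e in model.exons:
            if deleted and min(deleted) <= s and e <= max(deleted):
                return "exon_loss"
    aff_lo, aff_hi = min(affected), max(affected)
    if aff_hi < model.start or aff_lo > model.end:
        return "intergenic"
    splice = _splice_category(model, affected if len(ref) == 1 and len(alt) == 1
                              else set(range(pos + 1, pos + len(ref))) or affected)
    if splice:
        return splice
    in_exon = any(s <= pos <= e for s, e in model.exons)
    cds_hit = model.cds_offset(pos) is not None
    if len(ref) == 1 and len(alt) == 1:
        if cds_hit:
            return _classify_cds_snv(model, reference, pos, ref, alt)
        if in_exon:
            if _creates_upstream_atg(model, reference, pos, alt):
                return "start_gained"
            return "noncoding_exonic"
        return "intronic"
    # indel: edited bases start after the anchor
    edit_start = pos + 1 if len(ref) > 1 else pos
    edit_in_cds = model.cds_offset(edit_start) is not None or (
        len(ref) == 1 and cds_hit)
    if edit_in_cds:
        return _classify_cds_indel(model, reference, pos, ref, alt)
    if any(s <= edit_start <= e for s, e in model.exons):
        return "noncoding_exonic"
    return "intronic"


def _creates_upstream_atg(model: GeneModel, reference, pos: int,
                          alt: str) -> bool:
    """SNV in a 5' noncoding exon region creating an ATG (coding strand).

    Only evaluable when the gene model annotates exon sequence upstream of
    the CDS start; models whose exons equal their CDS never reach here.
    """
    if not model.cds:
        return False
    for shift in range(3):
        if model.strand == "+":
            s0 = pos - 1 - shift
            window = _fetch(reference, model.contig, s0, s0 + 3)
            idx = shift
            if len(window) == 3:
                mutated = window[:idx] + alt + window[idx + 1:]
                if mutated == "ATG" and s0 + 1 < model.cds[0][0]:
                    return True
        else:
            s0 = pos - 1 - (2 - shift)
            window = _fetch(reference, model.contig, s0, s0 + 3)
            idx = 2 - shift
            if len(window) == 3:
                mutated = window[:idx] + alt + window[idx + 1:]
                if revcomp(mutated) == "ATG" and s0 + 3 > model.cds[-1][1]:
                    return True
    return False


def classify_effect(
    contig: str, pos: int, ref: str, alt: str,
    gene_models: Sequence[GeneModel], reference,
) -> EffectCall:
    """Most severe effect of a variant across all transcripts.

    A deletion whose removed bases intersect the CDS of two distinct genes
    is a gene_fusion (only reachable from deletion records).
    """
    ref_obs = _fetch(reference, contig, pos - 1, pos - 1 + len(ref))
    if ref_obs != ref.upper():
        raise ReferenceMismatchError(
            f"REF {ref!r} at {contig}:{pos} disagrees with reference "
            f"{ref_obs!r}"
        )
    if len(ref) > len(alt):
        deleted = set(range(pos + 1, pos + len(ref)))
        cds_genes = set()
        for m in gene_models:
            if m.contig != contig:
                continue
            cds_bases = set()
            for s, e in m.cds:
                cds_bases.update(range(s, e + 1))
            if deleted & cds_bases:
                cds_genes.add(m.gene_id)
        if len(cds_genes) >= 2:
            return EffectCall("gene_fusion", "HIGH",
                              gene_id=";".join(sorted(cds_genes)))
    best: tuple[int, str, GeneModel] | None = None
    for m in sorted(gene_models, key=lambda g: g.transcript_id):
        cat = classify_effect_transcript(contig, pos, ref, alt, m, reference)
        if cat == "intergenic":
            continue
        rank = _RANK[cat]
        if best is None or rank < best[0]:
            best = (rank, cat, m)
    if best is None:
        return EffectCall("intergenic", "MODIFIER")
    _, cat, m = best
    return EffectCall(cat, IMPACT_BY_CATEGORY[cat],
                      gene_id=m.gene_id, transcript_id=m.transcript_id)


def deleterious_fraction_by_sharing(effects, spectrum_n):
    """Fraction of exonic variants that are high impact, per sharing level N.

    ``effects``: DataFrame with columns N (sharing level) and impact for
    exonic variants.  Bins with zero denominator are omitted.
    """
    import pandas as pd

    df = effects.copy()
    grouped = df.groupby("N").agg(
        n_exonic=("impact", "size"),
        n_high=("impact", lambda s: int((s == "HIGH").sum())),
    ).reset_index()
    grouped["fraction"] = grouped["n_high"] / grouped["n_exonic"]
    if spectrum_n is not None:
        grouped = grouped[grouped["N"].isin(spectrum_n)]
    return grouped
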
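"""Variant-effect classification against constructed genes and a
translate-and-diff oracle."""

import numpy as np
import pandas as pd
import pytest

from clonediv.effects import (EffectCall, ReferenceMismatchError,
                              classify_effect, deleterious_fraction_by_sharing)
from clonediv.genes import GeneModel

from _oracles import revcomp, translate_and_diff

# plus-strand gene: CDS = ATG GAT TAC TGG TTC TAA split over two exons
_CDS = "ATGGATTACTGGTTCTAA"
_EXON1, _EXON2 = _CDS[:9], _CDS[9:]
_INTRON = "GTAAAAAAAG"  # canonical GT...AG
_SEQ = "A" * 20 + _EXON1 + _INTRON + _EXON2 + "A" * 20
# coordinates: exon1 21-29, intron 30-39, exon2 40-48

PLUS = GeneModel(gene_id="gp", transcript_id="gp.t1", contig="cp",
                 strand="+", exons=[(21, 29), (40, 48)],
                 cds=[(21, 29), (40, 48)])
REF_PLUS = {"cp": _SEQ}

# the same gene mirrored to the minus strand
_SEQ_M = revcomp(_SEQ)
_L = len(_SEQ)


def _mirror(pos):
    return _L - pos + 1


MINUS = GeneModel(gene_id="gm", transcript_id="gm.t1", contig="cm",
                  strand="-",
                  exons=[(_mirror(48), _mirror(40)), (_mirror(29), _mirror(21))],
                  cds=[(_mirror(48), _mirror(40)), (_mirror(29), _mirror(21))])
REF_MINUS = {"cm": _SEQ_M}


def _classify(pos, ref, alt, models=(PLUS,), reference=REF_PLUS, contig="cp"):
    return classify_effect(contig, pos, ref, alt, list(models), reference)


class TestConstructedCases:
    @pytest.mark.parametrize("pos,ref,alt,category,impact", [
        (29, "C", "A", "stop_gained", "HIGH"),      # TAC -> TAA
        (29, "C", "T", "synonymous", "LOW"),        # TAC -> TAT (Tyr)
        (25, "A", "C", "missense", "MODERATE"),     # GAT -> GCT
        (21, "A", "G", "start_lost", "HIGH"),       # ATG -> GTG
        (46, "T", "C", "stop_lost", "HIGH"),        # TAA -> CAA
        (30, "G", "A", "splice_donor", "HIGH"),
        (31, "T", "C", "splice_donor", "HIGH"),
        (38, "A", "C", "splice_acceptor", "HIGH"),
        (39, "G", "T", "splice_acceptor", "HIGH"),
        (34, "A", "T", "intronic", "MODIFIER"),
        (5, "A", "T", "intergenic", "MODIFIER"),
    ])
    def test_plus_strand_snv_categories(self, pos, ref, alt, category, impact):
        call = _classify(pos, ref, alt)
        assert (call.category, call.impact) == (category, impact)

    def test_frameshift_and_inframe_deletions(self):
        # 1 bp deletion mid-CDS
        call = _classify(24, _SEQ[23:25], _SEQ[23])
        assert (call.category, call.impact) == ("frameshift", "HIGH")
        # 3 bp deletion removing codon GAT
        call = _classify(23, _SEQ[22:26], _SEQ[22])
        assert (call.category, call.impact) == ("inframe_indel", "MODERATE")

    def test_inframe_insertion_creating_stop(self):
        # insert TAA after codon 2 (after genomic base 26)
        call = _classify(26, _SEQ[25], _SEQ[25] + "TAA")
        assert call.category == "stop_gained"

    def test_deletion_of_whole_exon_is_exon_loss(self):
        ref = _SEQ[38:50]  # anchor 39, deletes 40-50 which covers exon2
        call = _classify(39, ref, ref[0])
        assert (call.category, call.impact) == ("exon_loss", "HIGH")

    def test_minus_strand_mirrored_categories(self):
        # TAC -> TAA on the coding strand = mirrored position, complement alt
        call = _classify(_mirror(29), "G", "T", models=(MINUS,),
                         reference=REF_MINUS, contig="cm")
        assert call.category == "stop_gained"
        call = _classify(_mirror(21), "T", "C", models=(MINUS,),
                         reference=REF_MINUS, contig="cm")
        assert call.category == "start_lost"
        # donor lies on the 5' side of the intron in coding orientation
        call = _classify(_mirror(30), "C", "T", models=(MINUS,),
                         reference=REF_MINUS, contig="cm")
        assert call.category == "splice_donor"

    def test_deletion_spanning_two_genes_is_fusion(self):
        second = GeneModel(gene_id="g2", transcript_id="g2.t1", contig="cp",
                           strand="+", exons=[(60, 68)], cds=[(60, 68)])
        seq = _SEQ[:59] + "ATGTTTTAA" + _SEQ[68:]
        ref = seq[44:62]  # anchor 45: deletes 46-62, hits CDS of both genes
        call = classify_effect("cp", 45, ref, ref[0], [PLUS, second],
                               {"cp": seq})
        assert (call.category, call.impact) == ("gene_fusion", "HIGH")
        assert call.gene_id == "g2;gp"

    def test_reference_mismatch_is_integrity_error(self):
        with pytest.raises(ReferenceMismatchError):
            _classify(29, "G", "A")

    def test_severity_selection_is_order_independent(self):
        other = GeneModel(gene_id="gp", transcript_id="gp.t2", contig="cp",
                          strand="+", exons=[(21, 29)], cds=[(21, 29)])
        a = classify_effect("cp", 25, "A", "C", [PLUS, other], REF_PLUS)
        b = classify_effect("cp", 25, "A", "C", [other, PLUS], REF_PLUS)
        assert a == b


class TestOracleAgreement:
    def test_random_cds_variants_match_translate_and_diff(self, default_dataset):
        """500+ random CDS SNVs and INDELs on simulated genes, both strands,
        must agree with full-CDS reconstruction and translation."""
        rng = np.random.default_rng(12)
        genome = default_dataset.genome
        genes = default_dataset.annotation.genes
        assert {g.strand for g in genes} == {"+", "-"}
        n_checked = 0
        mismatches = []
        while n_checked < 550:
            model = genes[int(rng.integers(0, len(genes)))]
            s, e = model.cds[int(rng.integers(0, len(model.cds)))]
            margin = 4
            if e - s + 1 <= 2 * margin + 8:
                continue
            pos = int(rng.integers(s + margin, e - margin))
            off = model.cds_offset(pos)
            if off is None or off < 3 or off >= model.cds_length - 3:
                continue
            seq = genome[model.contig]
            kind = rng.random()
            if kind < 0.5:  # SNV
                ref = seq[pos - 1]
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            elif kind < 0.75:  # deletion within the exon
                length = int(rng.integers(1, 7))
                if pos + length > e - margin:
                    continue
                end_off = model.cds_offset(pos + length)
                if end_off is None or end_off < 3 or \
                        end_off >= model.cds_length - 3:
                    continue
                ref = seq[pos - 1:pos + length]
                alt = ref[0]
            else:  # insertion
                length = int(rng.integers(1, 7))
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice(list("ACGT"), size=length))
            call = classify_effect(model.contig, pos, ref, alt, genes, genome)
            expected = translate_and_diff(model, genome, pos, ref, alt)
            if call.category != expected:
                mismatches.append((model.transcript_id, pos, ref, alt,
                                   call.category, expected))
            n_checked += 1
        assert not mismatches, mismatches[:5]


class TestImpactBySharing:
    def test_all_high_at_one(self):
        df = pd.DataFrame({"N": [1, 1, 15], "impact":
                           ["HIGH", "HIGH", "LOW"]})
        out = deleterious_fraction_by_sharing(df, None).set_index("N")
        assert out.loc[1, "fraction"] == 1.0
        assert out.loc[15, "fraction"] == 0.0

    def test_zero_high_everywhere(self):
        df = pd.DataFrame({"N": [1, 2, 15], "impact": ["LOW"] * 3})
        out = deleterious_fraction_by_sharing(df, None)
        assert (out["fraction"] == 0).all()

    def test_high_iff_disruptive_category(self):
        assert EffectCall("frameshift", "HIGH").impact == "HIGH"
        from clonediv.effects import HIGH_IMPACT, IMPACT_BY_CATEGORY
        for cat, imp in IMPACT_BY_CATEGORY.items():
            assert (imp == "HIGH") == (cat in HIGH_IMPACT)
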
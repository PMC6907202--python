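"""Forward simulator of an annotated diploid genome and a star pedigree of
clones accumulating somatic mutations.

The generator emulates the statistical structure that a clone-panel
resequencing analysis assumes:

* one heterozygous ancestral mother; every clone inherits her heterozygous
  sites, so ancestral variants are shared by the whole panel;
* somatic heterozygous mutations private to single clones (or, optionally,
  to configured subclades), placed uniformly within a feature class at
  class-specific per-bp per-clone rates — repeat-rich intergenic space
  fastest, exons slowest;
* transition probability conditioned on feature class and cytosine context,
  plus an explicit deamination process that converts methylation-context
  cytosines (C→T, strand-mirrored G→A) at a configurable per-site per-clone
  rate — the fingerprint of methylated-cytosine deamination in repeats;
* rare artifactual homozygous-alt genotypes, labelled in the truth table so
  sanitation filters can be scored;
* TE insertions and structural variants that are mostly ancestral (shared by
  all clones) with a minority of private events.

Every emitted variant has a ground-truth record; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Faidx

from . import signature
from .features import (EXON, INTRON, NONREP, REPEAT, FEATURE_CLASSES,
                       FeatureIndex, build_feature_index)
from .genes import GeneModel, write_gff3, write_repeats_bed
from .variants import (VariantRecord, VariantTable, write_variant_table)

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
BASES = ("A", "C", "G", "T")
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOPS and a + b + c != "ATG"
)

TRUTH_COLUMNS = [
    "variant_id", "contig", "position", "ref_allele", "alt_allele",
    "vartype", "carriers", "origin", "feature_class", "cytosine_context",
    "is_transition", "effect_label", "artifact_samples",
]

_TE_CATALOG = [
    ("Retrotransposon", "LTR", "Gypsy"),
    ("Retrotransposon", "LTR", "Copia"),
    ("Retrotransposon", "LINE", "L1"),
    ("DNA-transposon", "TIR", "hAT"),
    ("DNA-transposon", "TIR", "Mutator"),
    ("DNA-transposon", "Helitron", "Helitron"),
]
_SV_TYPES = ("deletion", "duplication", "insertion", "inversion")


class SimulationLayoutError(ValueError):
    """Requested gene/repeat content does not fit on the contigs."""


@dataclass
class SimulationConfig:
    """Study conditions for the clone-panel simulation.

    Defaults describe a 50 kb two-contig genome carrying 12 three-exon genes
    and a 15-clone star pedigree: ancestral heterozygosity 8/kb (so roughly
    a third of heterozygous sites end up shared by the whole panel once
    somatic mutations accumulate), somatic per-clone rates 2.0/kb in
    intergenic repeats > 1.0/kb in introns and non-repetitive intergenic
    space > 0.2/kb in exons, transition probability 2/3 in repeats and 1/3
    elsewhere, and mostly-shared TE insertions and SVs.
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 25_000
    gc_content: float = 0.35
    n_genes: int = 12
    exons_per_gene: int = 3
    exon_length_mean: int = 150
    intron_length_mean: int = 120
    intergenic_repeat_fraction: float = 0.35
    n_clones: int = 15
    ancestral_het_rate: float = 0.008
    somatic_rate_by_feature: dict[str, float] = dc_field(default_factory=lambda: {
        EXON: 0.0002, INTRON: 0.001, REPEAT: 0.002, NONREP: 0.001,
    })
    transition_prob_by_stratum: dict[tuple[str, str], float] = dc_field(
        default_factory=lambda: {
            **{(REPEAT, g): 2 / 3 for g in ("cytosine", "other")},
            **{(c, g): 1 / 3 for c in (EXON, INTRON, NONREP)
               for g in ("cytosine", "other")},
        })
    ancestral_transition_prob: float = 0.7
    deamination_rate_by_context: dict[tuple[str, str], float] = dc_field(
        default_factory=dict)  # (feature class, context) -> per-site per-clone
    indel_fraction: float = 0.15
    indel_max_len: int = 10
    artifact_homalt_rate: float = 0.0
    artifact_samples: tuple[str, ...] | None = None  # None = all samples
    high_impact_prob_private: float = 0.3
    high_impact_prob_ancestral: float = 0.05
    n_te_ancestral: int = 45
    n_te_private: int = 5
    n_sv_ancestral: int = 10
    n_sv_private: int = 2
    subclade_spec: tuple[tuple[str, ...], ...] | None = None
    subclade_event_fraction: float = 0.0
    metric_fail_fraction: float = 0.0
    include_reference_sample: bool = True
    reference_sample: str = "mother"

    def __post_init__(self) -> None:
        probs = [self.gc_content, self.intergenic_repeat_fraction,
                 self.ancestral_transition_prob, self.indel_fraction,
                 self.artifact_homalt_rate, self.metric_fail_fraction,
                 self.high_impact_prob_private, self.high_impact_prob_ancestral,
                 self.subclade_event_fraction,
                 *self.transition_prob_by_stratum.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        rates = [self.ancestral_het_rate,
                 *self.somatic_rate_by_feature.values(),
                 *self.deamination_rate_by_context.values()]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.n_clones < 2:
            raise ValueError("need at least 2 clones")

    @property
    def clone_labels(self) -> list[str]:
        return [f"clone{i:02d}" for i in range(1, self.n_clones + 1)]

    @property
    def sample_labels(self) -> list[str]:
        base = [self.reference_sample] if self.include_reference_sample else []
        return base + self.clone_labels

    def transition_prob(self, feature: str, context: str) -> float:
        group = "cytosine" if context in ("CpG", "CHG", "CHH") else "other"
        return self.transition_prob_by_stratum.get((feature, group), 0.5)


@dataclass
class Annotation:
    genes: list[GeneModel]
    repeats: list[tuple[str, int, int]]  # BED convention, 0-based half-open
    contig_lengths: dict[str, int]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    annotation: Annotation
    variants: VariantTable
    te_table: pd.DataFrame
    sv_table: pd.DataFrame
    truth: pd.DataFrame

    @property
    def index(self) -> FeatureIndex:
        return build_feature_index(
            self.annotation.genes, self.annotation.repeats,
            self.annotation.contig_lengths)


# --------------------------------------------------------------------------
# reference + annotation
# --------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + stop; no internal stop codons."""
    middle = rng.choice(SENSE_CODONS, size=max(n_codons - 2, 0))
    stop = rng.choice(sorted(STOPS))
    return "ATG" + "".join(middle) + stop


def simulate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], Annotation]:
    """Simulate contig sequences with genes and intergenic repeats.

    Every base belongs to exactly one feature class; gene CDS are
    well-formed ORFs (start codon, sense codons, stop codon, length % 3 == 0)
    written into the sequence on the annotated strand.
    """
    rng = np.random.default_rng([config.seed, 0])
    contigs = [f"ctg{i + 1}" for i in range(config.n_contigs)]
    lengths = {c: config.contig_length for c in contigs}
    genes: list[GeneModel] = []
    repeats: list[tuple[str, int, int]] = []
    genome: dict[str, str] = {}

    genes_per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        genes_per_contig[i] += 1

    gene_no = 0
    for ci, contig in enumerate(contigs):
        n_here = genes_per_contig[ci]
        # draw exon/intron lengths per gene
        structures = []
        for _ in range(n_here):
            exl = rng.integers(
                max(30, int(0.7 * config.exon_length_mean)),
                int(1.3 * config.exon_length_mean) + 1,
                size=config.exons_per_gene)
            total = int(exl.sum())
            exl[-1] += (3 - total % 3) % 3  # CDS length divisible by 3
            inl = rng.integers(
                max(20, int(0.7 * config.intron_length_mean)),
                int(1.3 * config.intron_length_mean) + 1,
                size=max(config.exons_per_gene - 1, 0))
            structures.append((exl.tolist(), inl.tolist()))
        spans = [sum(e) + sum(i) for e, i in structures]
        min_gap = 100
        intergenic = config.contig_length - sum(spans)
        if intergenic < min_gap * (n_here + 1):
            raise SimulationLayoutError(
                f"{contig}: {n_here} genes of total span {sum(spans)} bp do "
                f"not fit in {config.contig_length} bp with {min_gap} bp gaps"
            )
        extra = intergenic - min_gap * (n_here + 1)
        gaps = rng.multinomial(extra, np.full(n_here + 1, 1 / (n_here + 1)))
        gaps = gaps + min_gap

        # sequence backbone
        p = [(1 - config.gc_content) / 2, config.gc_content / 2,
             config.gc_content / 2, (1 - config.gc_content) / 2]
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                         size=config.contig_length, p=p)

        cursor = 0
        for gi in range(n_here):
            cursor += int(gaps[gi])
            exl, inl = structures[gi]
            strand = "+" if rng.random() < 0.5 else "-"
            exons: list[tuple[int, int]] = []
            pos = cursor
            for k, el in enumerate(exl):
                exons.append((pos + 1, pos + el))  # 1-based closed
                pos += el
                if k < len(inl):
                    pos += inl[k]
            gene_no += 1
            model = GeneModel(
                gene_id=f"gene{gene_no:03d}",
                transcript_id=f"gene{gene_no:03d}.t1",
                contig=contig, strand=strand,
                exons=exons, cds=list(exons),
            )
            genes.append(model)
            cds_len = sum(e - s + 1 for s, e in exons)
            cds_seq = _random_cds(rng, cds_len // 3)
            genomic = cds_seq if strand == "+" else _revcomp(cds_seq)
            off = 0
            for s, e in exons:
                seg = genomic[off:off + (e - s + 1)]
                seq[s - 1:e] = np.frombuffer(seg.encode(), dtype="S1")
                off += e - s + 1
            cursor = pos
        genome[contig] = seq.tobytes().decode()

        # repeats: cover a fixed fraction of every intergenic gap
        if config.intergenic_repeat_fraction > 0:
            gap_bounds = []
            last_end = 0
            for g in sorted((g for g in genes if g.contig == contig),
                            key=lambda g: g.start):
                gap_bounds.append((last_end, g.start - 1))  # 0-based half-open
                last_end = g.end
            gap_bounds.append((last_end, config.contig_length))
            for g0, g1 in gap_bounds:
                glen = g1 - g0
                rlen = int(round(config.intergenic_repeat_fraction * glen))
                if rlen < 1 or glen < 3:
                    continue
                offset = int(rng.integers(0, glen - rlen + 1))
                repeats.append((contig, g0 + offset, g0 + offset + rlen))

    annotation = Annotation(genes=genes, repeats=repeats,
                            contig_lengths=lengths)
    return genome, annotation


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# --------------------------------------------------------------------------
# small variants
# --------------------------------------------------------------------------

class _Placer:
    """Tracks occupied reference bases so variants never overlap."""

    def __init__(self) -> None:
        self.occupied: dict[str, set[int]] = {}

    def free(self, contig: str, start: int, end: int) -> bool:
        occ = self.occupied.setdefault(contig, set())
        return not any(p in occ for p in range(start, end + 1))

    def reserve(self, contig: str, start: int, end: int) -> None:
        self.occupied.setdefault(contig, set()).update(range(start, end + 1))


def _draw_snv(rng, seq: str, pos: int, p_transition: float):
    ref = seq[pos - 1]
    if rng.random() < p_transition:
        return ref, TRANSITION_PARTNER[ref], True
    tv = [b for b in BASES if b != ref and b != TRANSITION_PARTNER[ref]]
    return ref, tv[int(rng.integers(0, 2))], False


def _draw_indel(rng, seq: str, pos: int, max_len: int):
    length = min(int(rng.geometric(0.5)), max_len)
    if rng.random() < 0.5 or pos + length > len(seq):  # insertion
        ins = "".join(rng.choice(list(BASES), size=length))
        ref = seq[pos - 1]
        return ref, ref + ins, length, "ins"
    ref = seq[pos - 1:pos + length]
    return ref, ref[0], length, "del"


def simulate_clone_variants(
    config: SimulationConfig,
    genome: Mapping[str, str],
    annotation: Annotation,
) -> tuple[VariantTable, pd.DataFrame]:
    """Place ancestral and somatic small variants; emit table plus truth.

    Ancestral sites are heterozygous in every clone; somatic events carry in
    a single clone (or a configured subclade).  Exonic events follow the
    impact scheme: with the configured high-impact probability the event is
    a frameshift indel, otherwise a codon-safe SNV (no stop or start change).
    """
    rng = np.random.default_rng([config.seed, 1])
    index = build_feature_index(annotation.genes, annotation.repeats,
                                annotation.contig_lengths)
    contigs = sorted(genome)
    placer = _Placer()
    events: list[dict] = []

    exon_pool = _exon_pool(annotation)
    class_positions = _class_positions(index)

    # ancestral heterozygosity, uniform over the genome
    total_bp = sum(annotation.contig_lengths.values())
    n_anc = rng.binomial(total_bp, config.ancestral_het_rate)
    all_clones = tuple(config.clone_labels)
    for _ in range(n_anc):
        ev = _place_small_variant(
            rng, config, genome, index, exon_pool, class_positions, placer,
            origin="ancestral", carriers=all_clones,
            p_high=config.high_impact_prob_ancestral,
            feature=None,
        )
        if ev:
            events.append(ev)

    # somatic events per clone x feature class
    warned: set[str] = set()
    for clone in config.clone_labels:
        for feat in FEATURE_CLASSES:
            rate = config.somatic_rate_by_feature.get(feat, 0.0)
            bp = index.class_lengths[feat]
            if rate <= 0:
                continue
            if bp == 0:
                if feat not in warned:
                    import logging
                    logging.getLogger(__name__).warning(
                        "feature class %s has zero mutable bases; skipped", feat)
                    warned.add(feat)
                continue
            for _ in range(rng.poisson(bp * rate)):
                carriers: tuple[str, ...] = (clone,)
                if (config.subclade_spec and
                        rng.random() < config.subclade_event_fraction):
                    sub = config.subclade_spec[
                        int(rng.integers(0, len(config.subclade_spec)))]
                    carriers = tuple(sub)
                ev = _place_small_variant(
                    rng, config, genome, index, exon_pool, class_positions,
                    placer, origin="somatic", carriers=carriers,
                    p_high=config.high_impact_prob_private, feature=feat,
                )
                if ev:
                    events.append(ev)

    # deamination at methylation-context cytosines
    if any(r > 0 for r in config.deamination_rate_by_context.values()):
        sites = signature.context_site_table(genome, index)
        merged: dict[tuple[str, int], dict] = {}
        for (feat, ctx), rate in sorted(config.deamination_rate_by_context.items()):
            if rate <= 0:
                continue
            sub = sites[(sites["feature"] == feat) & (sites["context"] == ctx)]
            for clone in config.clone_labels:
                hit = rng.random(len(sub)) < rate
                for rec in sub.loc[hit].itertuples(index=False):
                    pos = int(rec.position)
                    key = (rec.contig, pos)
                    if key in merged:
                        merged[key]["carriers"].add(clone)
                        continue
                    if not placer.free(rec.contig, pos, pos):
                        continue
                    ref = genome[rec.contig][pos - 1]
                    alt = "T" if rec.strand == "+" else "A"
                    merged[key] = {
                        "contig": rec.contig, "position": pos,
                        "ref": ref, "alt": alt, "vartype": "SNV",
                        "carriers": {clone}, "origin": "somatic",
                        "feature_class": feat, "cytosine_context": ctx,
                        "is_transition": True, "effect_label": "NA",
                    }
        for key, ev in sorted(merged.items()):
            placer.reserve(ev["contig"], ev["position"], ev["position"])
            ev["carriers"] = tuple(sorted(ev["carriers"]))
            events.append(ev)

    events.sort(key=lambda e: (e["contig"], e["position"], e["alt"]))

    # genotypes + artifact spiking
    samples = config.sample_labels
    artifact_scope = (list(config.artifact_samples)
                      if config.artifact_samples is not None else samples)
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    fail_cycle = 0
    for i, ev in enumerate(events, 1):
        gts: dict[str, tuple[int, int] | None] = {}
        for s in samples:
            if s in ev["carriers"]:
                gts[s] = (0, 1)
            else:
                gts[s] = (0, 0)
        artifacts = []
        if config.artifact_homalt_rate > 0:
            for s in artifact_scope:
                if rng.random() < config.artifact_homalt_rate:
                    gts[s] = (1, 1)
                    artifacts.append(s)
        metrics, qual = _caller_metrics(rng, config, fail_cycle)
        if metrics.get("_failed"):
            fail_cycle += 1
            metrics.pop("_failed")
        vid = f"var{i:06d}"
        records.append(VariantRecord(
            contig=ev["contig"], pos=ev["position"], ref=ev["ref"],
            alts=(ev["alt"],), qual=qual, metrics=metrics, genotypes=gts,
            filters=None, variant_id=vid,
        ))
        truth_rows.append({
            "variant_id": vid, "contig": ev["contig"],
            "position": ev["position"], "ref_allele": ev["ref"],
            "alt_allele": ev["alt"], "vartype": ev["vartype"],
            "carriers": ",".join(ev["carriers"]), "origin": ev["origin"],
            "feature_class": ev["feature_class"],
            "cytosine_context": ev["cytosine_context"],
            "is_transition": ev["is_transition"],
            "effect_label": ev["effect_label"],
            "artifact_samples": ",".join(artifacts) if artifacts else "",
        })
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return VariantTable(samples=samples, records=records), truth


def _caller_metrics(rng, config: SimulationConfig, cycle: int):
    passing = {"DP": 12.0, "QD": 25.0, "FS": 3.0, "MQ": 60.0,
               "MQRankSum": 0.5, "ReadPosRankSum": 0.3}
    qual = 500.0
    metrics = dict(passing)
    if config.metric_fail_fraction > 0 and rng.random() < config.metric_fail_fraction:
        failing = [("DP", 30.0), ("DP", 2.0), ("QUAL", 10.0), ("QD", 1.0),
                   ("FS", 70.0), ("MQ", 20.0), ("MQRankSum", -13.0),
                   ("ReadPosRankSum", -9.0)]
        name, value = failing[cycle % len(failing)]
        if name == "QUAL":
            qual = value
        else:
            metrics[name] = value
        metrics["_failed"] = True
    return metrics, qual


def _exon_pool(annotation: Annotation):
    """(model, start, end, cumulative-length) list for weighted placement."""
    pool = []
    for m in annotation.genes:
        for s, e in m.cds:
            pool.append((m, s, e))
    lengths = np.array([e - s + 1 for _, s, e in pool], dtype=float)
    weights = lengths / lengths.sum() if len(pool) else lengths
    return pool, weights


def _class_positions(index: FeatureIndex):
    """0-based position arrays per (contig, class)."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for contig, arr in index.codes.items():
        for ci, cname in enumerate(FEATURE_CLASSES):
            out[(contig, cname)] = np.flatnonzero(arr == ci)
    return out


def _place_small_variant(rng, config, genome, index, exon_pool, class_positions,
                         placer, *, origin, carriers, p_high, feature):
    """Construct one small-variant event dict, or None after many misses."""
    for _ in range(60):
        if feature is None:
            contig_names = sorted(genome)
            lens = np.array([len(genome[c]) for c in contig_names], dtype=float)
            contig = contig_names[int(rng.choice(len(contig_names),
                                                 p=lens / lens.sum()))]
            pos = int(rng.integers(1, len(genome[contig]) + 1))
            feat = index.class_of(contig, pos)
        else:
            feat = feature
            if feat == EXON:
                contig = pos = None  # chosen inside the exon branch
            else:
                pool = class_positions
                cands = [(c, pool[(c, feat)]) for c in sorted(genome)
                         if len(pool[(c, feat)])]
                if not cands:
                    return None
                weights = np.array([len(a) for _, a in cands], dtype=float)
                contig, arr = cands[int(rng.choice(len(cands),
                                                   p=weights / weights.sum()))]
                pos = int(arr[int(rng.integers(0, len(arr)))]) + 1

        if feat == EXON:
            ev = _place_exonic(rng, config, genome, exon_pool, placer,
                               origin, carriers, p_high)
            if ev:
                return ev
            continue

        seq = genome[contig]
        is_indel = rng.random() < config.indel_fraction
        if is_indel:
            ref, alt, length, kind = _draw_indel(rng, seq, pos,
                                                 config.indel_max_len)
            span_end = pos + (length if kind == "del" else 0)
            if span_end > len(seq) or not placer.free(contig, pos, span_end):
                continue
            # keep deletions within a single feature run
            if kind == "del" and len({index.class_of(contig, p)
                                      for p in range(pos, span_end + 1)}) > 1:
                continue
            placer.reserve(contig, pos, span_end)
            return {
                "contig": contig, "position": pos, "ref": ref, "alt": alt,
                "vartype": "INDEL", "carriers": carriers, "origin": origin,
                "feature_class": feat, "cytosine_context": "NA",
                "is_transition": "NA", "effect_label": "NA",
            }
        if not placer.free(contig, pos, pos):
            continue
        ctx = signature.cytosine_context(genome, contig, pos)
        p_tr = (config.ancestral_transition_prob if origin == "ancestral"
                else config.transition_prob(feat, ctx))
        ref, alt, is_tr = _draw_snv(rng, seq, pos, p_tr)
        placer.reserve(contig, pos, pos)
        return {
            "contig": contig, "position": pos, "ref": ref, "alt": alt,
            "vartype": "SNV", "carriers": carriers, "origin": origin,
            "feature_class": feat, "cytosine_context": ctx,
            "is_transition": is_tr, "effect_label": "NA",
        }
    return None


def _place_exonic(rng, config, genome, exon_pool, placer,
                  origin, carriers, p_high):
    pool, weights = exon_pool
    if not pool:
        return None
    model, s, e = pool[int(rng.choice(len(pool), p=weights))]
    contig = model.contig
    seq = genome[contig]
    margin = 4
    if e - s + 1 <= 2 * margin + 6:
        return None
    high = rng.random() < p_high
    if high:
        # frameshift deletion of 1-2 bp, interior to the exon
        length = int(rng.integers(1, 3))
        pos = int(rng.integers(s + margin, e - margin - length))
        if not placer.free(contig, pos, pos + length):
            return None
        # avoid clipping the start codon region
        if _in_terminal_codons(model, pos, pos + length):
            return None
        ref = seq[pos - 1:pos + length]
        placer.reserve(contig, pos, pos + length)
        return {
            "contig": contig, "position": pos, "ref": ref, "alt": ref[0],
            "vartype": "INDEL", "carriers": carriers, "origin": origin,
            "feature_class": EXON, "cytosine_context": "NA",
            "is_transition": "NA", "effect_label": "frameshift",
        }
    # codon-safe SNV: never start_lost / stop_gained / stop_lost
    from .effects import GENETIC_CODE
    for _ in range(20):
        pos = int(rng.integers(s + margin, e - margin + 1))
        if not placer.free(contig, pos, pos):
            continue
        if _in_terminal_codons(model, pos, pos):
            continue
        off = model.cds_offset(pos)
        if off is None:
            continue
        from .effects import cds_sequence
        cds = cds_sequence(model, genome)
        codon_i, within = divmod(off, 3)
        codon = cds[codon_i * 3:codon_i * 3 + 3]
        if len(codon) < 3 or codon in STOPS:
            continue
        ref = seq[pos - 1]
        alts = [b for b in BASES if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            alt_c = alt if model.strand == "+" else _revcomp(alt)
            mutated = codon[:within] + alt_c + codon[within + 1:]
            if mutated in STOPS:
                continue
            label = ("synonymous" if GENETIC_CODE[mutated] == GENETIC_CODE[codon]
                     else "missense")
            placer.reserve(contig, pos, pos)
            ctx = signature.cytosine_context(genome, contig, pos)
            return {
                "contig": contig, "position": pos, "ref": ref, "alt": alt,
                "vartype": "SNV", "carriers": carriers, "origin": origin,
                "feature_class": EXON, "cytosine_context": ctx,
                "is_transition": is_tr_pair(ref, alt),
                "effect_label": label,
            }
    return None


def _in_terminal_codons(model: GeneModel, start: int, end: int) -> bool:
    """True if [start, end] touches the first or last codon of the CDS."""
    for pos in (start, end):
        off = model.cds_offset(pos)
        if off is not None and (off < 3 or off >= model.cds_length - 3):
            return True
    return False


def is_tr_pair(a: str, b: str) -> bool:
    return TRANSITION_PARTNER[a] == b


# --------------------------------------------------------------------------
# TE insertions and structural variants
# --------------------------------------------------------------------------

def simulate_structural(
    config: SimulationConfig,
    genome: Mapping[str, str],
    annotation: Annotation,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TE-insertion table, SV table, and their truth rows."""
    rng = np.random.default_rng([config.seed, 2])
    contigs = sorted(genome)
    lens = np.array([len(genome[c]) for c in contigs], dtype=float)
    pcontig = lens / lens.sum()
    clones = config.clone_labels

    te_rows, truth_rows = [], []
    for i in range(config.n_te_ancestral + config.n_te_private):
        contig = contigs[int(rng.choice(len(contigs), p=pcontig))]
        pos = int(rng.integers(1, len(genome[contig]) + 1))
        cls, order, family = _TE_CATALOG[int(rng.integers(0, len(_TE_CATALOG)))]
        if i < config.n_te_ancestral:
            carriers = tuple(clones)
            origin = "ancestral"
        else:
            carriers = (clones[int(rng.integers(0, len(clones)))],)
            origin = "somatic"
        tid = f"tei{i + 1:04d}"
        te_rows.append({
            "tei_id": tid, "contig": contig, "position": pos,
            "te_class": cls, "te_order": order, "te_superfamily": family,
            "carriers": ",".join(carriers),
        })
        truth_rows.append({
            "variant_id": tid, "contig": contig, "position": pos,
            "ref_allele": "N", "alt_allele": f"<INS:{family}>",
            "vartype": "TEI", "carriers": ",".join(carriers),
            "origin": origin, "feature_class": "NA",
            "cytosine_context": "NA", "is_transition": "NA",
            "effect_label": "NA", "artifact_samples": "",
        })

    sv_rows = []
    for i in range(config.n_sv_ancestral + config.n_sv_private):
        contig = contigs[int(rng.choice(len(contigs), p=pcontig))]
        svtype = _SV_TYPES[int(rng.integers(0, len(_SV_TYPES)))]
        length = int(rng.integers(100, 2001))
        start = int(rng.integers(1, len(genome[contig]) - length))
        end = start if svtype == "insertion" else start + length - 1
        if i < config.n_sv_ancestral:
            carriers = tuple(clones)
            origin = "ancestral"
        else:
            carriers = (clones[int(rng.integers(0, len(clones)))],)
            origin = "somatic"
        sid = f"sv{i + 1:04d}"
        sv_rows.append({
            "sv_id": sid, "contig": contig, "start": start, "end": end,
            "svtype": svtype, "length": length,
            "carriers": ",".join(carriers),
        })
        truth_rows.append({
            "variant_id": sid, "contig": contig, "position": start,
            "ref_allele": "N", "alt_allele": f"<{svtype.upper()[:3]}>",
            "vartype": "SV", "carriers": ",".join(carriers),
            "origin": origin, "feature_class": "NA",
            "cytosine_context": "NA", "is_transition": "NA",
            "effect_label": "NA", "artifact_samples": "",
        })
    te = pd.DataFrame(te_rows).sort_values(
        ["contig", "position"]).reset_index(drop=True)
    sv = pd.DataFrame(sv_rows).sort_values(
        ["contig", "start"]).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return te, sv, truth


# --------------------------------------------------------------------------
# top level + fixture writing
# --------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulatedDataset:
    genome, annotation = simulate_reference(config)
    table, truth_small = simulate_clone_variants(config, genome, annotation)
    te, sv, truth_struct = simulate_structural(config, genome, annotation)
    truth = pd.concat([truth_small, truth_struct], ignore_index=True)
    return SimulatedDataset(config=config, genome=genome,
                            annotation=annotation, variants=table,
                            te_table=te, sv_table=sv, truth=truth)


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in sorted(genome):
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fixture(dataset: SimulatedDataset,
                  outdir: str | os.PathLike) -> dict[str, Path]:
    """Write the complete file set: FASTA(+fai), GFF3, BED, VCFs, TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    paths = {
        "fasta": out / "reference.fa",
        "gff3": out / "genes.gff3",
        "bed": out / "repeats.bed",
        "vcf": out / "variants.vcf",
        "tei": out / "tei.tsv",
        "sv": out / "svs.vcf",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.tsv",
    }
    write_fasta(dataset.genome, paths["fasta"])
    Faidx(str(paths["fasta"]))  # writes reference.fa.fai
    write_gff3(dataset.annotation.genes, paths["gff3"])
    write_repeats_bed(dataset.annotation.repeats, paths["bed"])
    write_variant_table(dataset.variants, paths["vcf"],
                        contig_lengths=dataset.annotation.contig_lengths)
    dataset.te_table.to_csv(paths["tei"], sep="\t", index=False)
    _write_sv_vcf(dataset, paths["sv"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    flat = {k: v for k, v in asdict(cfg).items()
            if isinstance(v, (int, float, str, bool))}
    pd.Series(flat).rename("value").rename_axis("key").to_csv(
        paths["config"], sep="\t")
    return paths


_SV_ALT = {"deletion": "<DEL>", "duplication": "<DUP>",
           "insertion": "<INS>", "inversion": "<INV>"}


def _write_sv_vcf(dataset: SimulatedDataset, path: Path) -> None:
    samples = dataset.config.clone_labels
    records = []
    for rec in dataset.sv_table.itertuples(index=False):
        carriers = set(rec.carriers.split(","))
        gts = {s: ((0, 1) if s in carriers else (0, 0)) for s in samples}
        records.append(VariantRecord(
            contig=rec.contig, pos=int(rec.start),
            ref=dataset.genome[rec.contig][int(rec.start) - 1],
            alts=(_SV_ALT[rec.svtype],), qual=100.0,
            metrics={"SVTYPE": rec.svtype.upper()[:3],
                     "SVLEN": int(rec.length), "END": int(rec.end)},
            genotypes=gts, filters=(), variant_id=rec.sv_id,
        ))
    write_variant_table(VariantTable(samples=samples, records=records), path,
                        contig_lengths=dataset.annotation.contig_lengths)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"carriers": str,
                                              "artifact_samples": str},
                       keep_default_na=False, na_values=[])


def read_te_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"carriers": str})
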
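"""End-to-end orchestration: sanitize -> classify -> analyze -> tables.

``run_pipeline`` executes the full downstream analysis on one input set
(reference FASTA, GFF3 genes, BED repeats, multi-sample VCF, TE-insertion
TSV, SV VCF) and writes figure-ready TSV tables plus a machine-readable run
summary.  Every output is deterministic for a fixed input and config; the
summary records a config hash and per-stage record counts entering and
leaving each step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import effects as fx
from . import signature
from .features import (EXON, FeatureIndex, affected_position,
                       build_feature_index, filter_svs_in_repeats,
                       nearest_gene_distances, normalized_rates, summarize_svs)
from .genes import load_gene_models, read_repeats_bed
from .relatedness import (genotype_matrix, genotype_pca, kinship_dendrogram,
                          kinship_matrix)
from .spectrum import build_spectrum, headline_fractions, merge_svs, sharing_level
from .variants import (FilterConfig, VariantTable, apply_hard_filters,
                       classify_variant_type, complete_call_sites,
                       drop_reference_nonref, limit_alts, read_sv_table,
                       read_variant_table)

logger = logging.getLogger(__name__)

OUTPUT_TABLES = [
    "fig4_rates.tsv", "fig5a_spectrum.tsv", "fig5c_titv.tsv",
    "fig5d_context.tsv", "fig5e_impact.tsv", "fig6_te.tsv", "fig6c_te_distance.tsv",
    "table3_sv.tsv", "fig3_kinship.tsv", "fig3_pca.tsv", "tree.nwk",
]


@dataclass
class RunConfig:
    reference: str
    gff3: str
    repeats_bed: str
    vcf: str
    tei_tsv: str
    sv_vcf: str
    outdir: str
    clone_samples: list[str]
    reference_sample: str | None = None
    outgroup_samples: list[str] = field(default_factory=list)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    exclude_uniform_het: bool = False
    drop_homalt_sites: bool = False
    sv_repeat_filter: bool = False
    sv_reciprocal_overlap: float = 0.8
    pca_exclude_reference: bool = True
    assembly_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        roles = [set(self.clone_samples), set(self.outgroup_samples)]
        if self.reference_sample:
            roles.append({self.reference_sample})
        total = sum(len(r) for r in roles)
        if len(set().union(*roles)) != total:
            raise ValueError("sample roles must be disjoint")

    def hash(self) -> str:
        """Digest of the analysis inputs and parameters (not the outdir)."""
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        payload = asdict(self)
        payload.pop("outdir", None)
        payload = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages; return the run summary (also written as JSON)."""
    out = Path(config.outdir)
    summary_path = out / "run_summary.json"
    if summary_path.exists() and not force:
        raise FileExistsError(
            f"{out} already holds a run; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, int]] = {}

    def stage(name: str, n_in: int, n_out: int) -> None:
        stages[name] = {"in": n_in, "out": n_out, "removed": n_in - n_out}
        logger.info("stage %-24s in=%d out=%d", name, n_in, n_out)

    reference = Fasta(config.reference)
    genes = load_gene_models(config.gff3)
    repeats = read_repeats_bed(config.repeats_bed)
    contig_lengths = {name: len(reference[name]) for name in reference.keys()}
    index = build_feature_index(genes, repeats, contig_lengths)

    table = read_variant_table(config.vcf)
    n0 = len(table)
    table = limit_alts(table, max_alts=2)
    table = apply_hard_filters(table, config.filter_config)
    passing = table.passing()
    stage("hard_filters", n0, len(passing))

    if config.reference_sample:
        sanitized, removed_frac = drop_reference_nonref(
            passing, config.reference_sample)
    else:
        sanitized, removed_frac = passing, 0.0
    stage("drop_reference_nonref", len(passing), len(sanitized))

    complete = complete_call_sites(sanitized)
    stage("complete_call_sites", len(sanitized), len(complete))

    if config.drop_homalt_sites:
        kept = [r for r in complete.records
                if not any((g is not None and g[0] > 0 and g[0] == g[1])
                           for s, g in r.genotypes.items()
                           if s in config.clone_samples)]
        complete = VariantTable(complete.samples, kept)
        stage("drop_homalt_sites", stages["complete_call_sites"]["out"],
              len(complete))

    clones = config.clone_samples
    te_table = pd.read_csv(config.tei_tsv, sep="\t", dtype={"carriers": str})
    sv_raw = read_sv_table(config.sv_vcf)
    if config.sv_repeat_filter:
        sv_raw = filter_svs_in_repeats(sv_raw, index)
    sv_merged = merge_svs(sv_raw, config.sv_reciprocal_overlap)

    spectrum = build_spectrum(
        complete, clones, index, te_table=te_table, sv_table=sv_merged,
        exclude_uniform_het=config.exclude_uniform_het)
    spectrum.to_csv(out / "fig5a_spectrum.tsv", sep="\t", index=False)
    headline = headline_fractions(spectrum, len(clones))

    # per-clone variant rates by feature / type / zygosity
    per_variant = _per_variant_frame(complete, clones, index)
    rate_rows = []
    for clone in clones:
        het = per_variant[per_variant[f"het_{clone}"]]
        hom = per_variant[per_variant[f"hom_{clone}"]]
        for zyg, sub in (("het", het), ("hom", hom)):
            counts = (sub.groupby(["feature", "vartype"]).size()
                      .rename("count").reset_index())
            counts["clone"] = clone
            counts["zygosity"] = zyg
            rate_rows.append(counts)
    rates = pd.concat(rate_rows, ignore_index=True) if rate_rows else \
        pd.DataFrame(columns=["feature", "vartype", "count", "clone", "zygosity"])
    rates = normalized_rates(rates, index)
    rates.to_csv(out / "fig4_rates.tsv", sep="\t", index=False)

    # clone-unique heterozygous SNVs: Ti/Tv and context signatures
    unique_snvs = _unique_het_snvs(per_variant, clones)
    titv = signature.titv_ratio(unique_snvs, by=["feature"]) \
        if len(unique_snvs) else pd.DataFrame()
    titv_clone = signature.titv_ratio(unique_snvs, by=["clone", "feature"]) \
        if len(unique_snvs) else pd.DataFrame()
    titv.to_csv(out / "fig5c_titv.tsv", sep="\t", index=False)
    titv_clone.to_csv(out / "fig5c_titv_per_clone.tsv", sep="\t", index=False)

    per_clone_ctx, ctx_summary = signature.context_transition_percentages(
        unique_snvs, reference, index, clones)
    ctx_summary.to_csv(out / "fig5d_context.tsv", sep="\t", index=False)
    per_clone_ctx.to_csv(out / "fig5d_context_per_clone.tsv", sep="\t",
                         index=False)

    # effect classification of exonic small variants
    exonic = per_variant[per_variant["feature"] == EXON]
    effect_rows = []
    for rec in exonic.itertuples(index=False):
        call = fx.classify_effect(rec.contig, rec.pos, rec.ref, rec.alt,
                                  genes, reference)
        effect_rows.append({
            "contig": rec.contig, "pos": rec.pos, "ref": rec.ref,
            "alt": rec.alt, "N": rec.N, "category": call.category,
            "impact": call.impact, "gene_id": call.gene_id,
        })
    effect_table = pd.DataFrame(effect_rows)
    impact = fx.deleterious_fraction_by_sharing(effect_table, None) \
        if len(effect_table) else pd.DataFrame(
            columns=["N", "n_exonic", "n_high", "fraction"])
    impact.to_csv(out / "fig5e_impact.tsv", sep="\t", index=False)
    effect_table.to_csv(out / "effects.tsv", sep="\t", index=False)

    # relatedness over clones (+ outgroups); the reference-derived sample is
    # homozygous-reference by construction, so its kinship is undefined
    related_samples = clones + config.outgroup_samples
    gmat = genotype_matrix(complete, samples=related_samples)
    kin = kinship_matrix(gmat)
    kin.to_csv(out / "fig3_kinship.tsv", sep="\t")
    exclude = ([config.reference_sample]
               if (config.pca_exclude_reference and config.reference_sample)
               else [])
    try:
        coords, evr = genotype_pca(gmat, n_components=2, exclude=exclude)
        coords["explained_variance_PC1"] = evr[0]
        coords.to_csv(out / "fig3_pca.tsv", sep="\t")
    except ValueError as exc:
        logger.warning("PCA skipped: %s", exc)
        coords = None
    _, newick = kinship_dendrogram(kin)
    (out / "tree.nwk").write_text(newick + "\n")

    # TE insertions: spectrum + gene proximity
    te_spec = build_spectrum(VariantTable(clones, []), clones,
                             te_table=te_table)
    te_spec.to_csv(out / "fig6_te.tsv", sep="\t", index=False)
    te_dist, te_dist_summary = nearest_gene_distances(te_table, genes)
    te_dist.to_csv(out / "fig6c_te_distance.tsv", sep="\t", index=False)

    # SV summary
    assembly_length = config.assembly_length or sum(contig_lengths.values())
    sv_summary = summarize_svs(sv_merged, genes, assembly_length)
    sv_summary.to_csv(out / "table3_sv.tsv", sep="\t", index=False)

    summary = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_samples": len(table.samples),
        "n_clones": len(clones),
        "stages": stages,
        "removed_reference_nonref_fraction": removed_frac,
        "headline": headline.to_dict(orient="records"),
        "te_distance_summary": te_dist_summary.to_dict(orient="records"),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                       default=str) + "\n")
    return summary


def _per_variant_frame(table: VariantTable, clones: list[str],
                       index: FeatureIndex) -> pd.DataFrame:
    """One row per (record, first alt): type, feature, N, per-clone zygosity."""
    rows = []
    for rec in table.records:
        alt = rec.alts[0]
        vtype = classify_variant_type(rec.ref, alt)
        if vtype == "SV":
            continue
        feature = index.class_of(rec.contig,
                                 affected_position(rec.pos, rec.ref, alt))
        row = {
            "contig": rec.contig, "pos": rec.pos, "ref": rec.ref, "alt": alt,
            "vartype": vtype, "feature": feature,
            "N": sharing_level(rec, clones),
        }
        for c in clones:
            g = rec.genotypes[c]
            row[f"het_{c}"] = g[0] != g[1] and 1 in g
            row[f"hom_{c}"] = g[0] == g[1] == 1
        rows.append(row)
    return pd.DataFrame(rows)


def _unique_het_snvs(per_variant: pd.DataFrame,
                     clones: list[str]) -> pd.DataFrame:
    """Long frame (clone, contig, position, ref, alt, feature) for N=1 SNVs."""
    if not len(per_variant):
        return pd.DataFrame(
            columns=["clone", "contig", "position", "ref", "alt", "feature"])
    uniq = per_variant[(per_variant["N"] == 1)
                       & (per_variant["vartype"] == "SNV")]
    rows = []
    for rec in uniq.itertuples(index=False):
        carrier = next(c for c in clones if getattr(rec, f"het_{c}"))
        rows.append({"clone": carrier, "contig": rec.contig,
                     "position": rec.pos, "ref": rec.ref, "alt": rec.alt,
                     "feature": rec.feature})
    return pd.DataFrame(
        rows, columns=["clone", "contig", "position", "ref", "alt", "feature"])
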
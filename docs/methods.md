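# Methods

## Model

A panel of `n` clones descends from one heterozygous mother by vegetative
propagation (a star pedigree: every clone is an independent branch unless
subclades are configured). Each clone's diploid genotype at a biallelic
site is one of hom-ref (0), het (1), hom-alt (2). Heterozygous sites
decompose into:

* **ancestral** sites, heterozygous in the mother and hence in every clone
  (sharing level N = n);
* **somatic** sites, heterozygous mutations acquired on one branch
  (N = 1), or on a configured subclade (N = |subclade|, shared by descent).

Somatic mutations arrive independently per clone and per feature class at
a per-bp rate; within a class, placement is uniform. A simulated SNV is a
transition with a probability conditioned on (feature class, whether the
site is a CpG/CHG/CHH cytosine context), which encodes the
methylated-cytosine-deamination mechanism without modelling methylation
itself. An optional explicit deamination process additionally converts
context cytosines C→T (strand-mirrored G→A) at a per-site per-clone rate.

The analysis half of the package never sees the truth table: it works
from the emitted VCF/FASTA/GFF3/BED/TSV files alone, exactly as it would
on real data.

## Simulator parameters (defaults = study conditions)

| parameter | default | meaning |
|---|---|---|
| `n_contigs` × `contig_length` | 2 × 25,000 bp | genome size (desk-scale) |
| `gc_content` | 0.35 | plant-like backbone composition |
| `n_genes`, `exons_per_gene` | 12, 3 | gene space; CDS = exons, no UTRs |
| `exon_length_mean`, `intron_length_mean` | 150, 120 bp | drawn ±30% |
| `intergenic_repeat_fraction` | 0.35 | fraction of each intergenic gap covered by a repeat block |
| `n_clones` | 15 | panel size |
| `ancestral_het_rate` | 0.008 /bp | chosen so the ancestral fraction of het SNVs lands near one third once somatic load accumulates, matching the empirical sharing spectra of clone panels |
| `somatic_rate_by_feature` | repeat 0.002, intron 0.001, non-rep. intergenic 0.001, exon 0.0002 /bp/clone | i.e. 2.0 > 1.0 = 1.0 > 0.2 per kb |
| `transition_prob_by_stratum` | 2/3 in repeats, 1/3 elsewhere | Ti/Tv 2.0 vs 0.5 |
| `ancestral_transition_prob` | 0.7 | typical germline Ti excess |
| `indel_fraction` | 0.15 | somatic small variants that are INDELs (non-exonic) |
| `deamination_rate_by_context` | {} (off) | per-site per-clone C→T rate at context cytosines |
| `artifact_homalt_rate` | 0 | per-genotype probability of an erroneous hom-alt spike |
| `metric_fail_fraction` | 0 | records given one failing caller metric (cycled over the eight rules) |
| `high_impact_prob_private` / `..._ancestral` | 0.3 / 0.05 | probability an exonic event is disruptive (frameshift) rather than a codon-safe SNV |
| `n_te_ancestral` / `n_te_private` | 45 / 5 | TE insertions, mostly shared |
| `n_sv_ancestral` / `n_sv_private` | 10 / 2 | SVs, mostly shared |

INDEL lengths are geometric (p = 0.5) capped at 10 bp, insertion and
deletion equiprobable; deletions are constrained to a single feature run
so the leftmost-affected-base feature assignment is unambiguous. Exonic
events follow the impact scheme: with the configured high-impact
probability the event is a 1–2 bp frameshift deletion interior to an exon
(never touching the first/last codon), otherwise an SNV whose codon change
is verified not to create or destroy a stop or the start codon — so the
exonic SNV alt is uniform over the three non-stop choices, giving an
exonic transition fraction near 1/3 rather than following
`transition_prob_by_stratum`. Ancestral and somatic events never share a
reference base (occupied positions are reserved), so cross-clone
recurrence does not occur except through the deamination process, where
two clones hitting the same site merge into one record with two carriers.

The passing caller metrics written to INFO are DP = 12, QD = 25, FS = 3,
MQ = 60, MQRankSum = 0.5, ReadPosRankSum = 0.3, QUAL = 500 — chosen to
clear every default rule, including the DP ∈ (5, 20) window left by
applying both printed depth flags literally.

## What the simulator does *not* emulate

No reads, base errors, mapping bias, coverage variation or genotype
likelihoods — caller behaviour enters only through the configured
pass/fail INFO metrics and the artifact hom-alt spikes. No cell-layer
chimerism (bulk genotypes only), no linkage structure, no fine-scale rate
heterogeneity within a feature class, no recurrent mutation at a site,
and ancestral sites are independent (no LD). Consequently, passing tests
demonstrate that the estimators recover the generative parameters under
the stated statistical structure; they do not validate robustness to
alignment or calling pathologies in real data.

## Analysis conventions and numerical choices

* **Coordinates.** VCF and GFF3 are 1-based closed; BED is 0-based
  half-open. INDEL/SV feature assignment uses the leftmost
  reference-affected base (anchor + 1 for deletions).
* **Hard filters** annotate; nothing is deleted. A rule whose metric is
  absent on a record is not evaluated there (logged once); a record with
  no evaluable rules passes vacuously. Both printed depth flags are
  applied literally by default; each rule can be disabled independently.
* **Carrier definition.** Heterozygous for the considered ALT; hom-alt
  clones are non-carriers (treated as technical artifacts in clone
  panels), and a clone het for a different ALT at a multi-allelic site is
  a non-carrier. ALTs beyond the first two are dropped (logged). An
  `exclude_uniform_het` switch removes sites where all clones are
  identically het from the N = n bin; both behaviours are first-class.
* **Cytosine contexts** are strand-specific sites: a CpG dinucleotide
  contributes two sites. Context is read from the reference neighborhood,
  not the mutated sequence. Only C→T on the site's strand counts as the
  site "experiencing a transition" (the deamination mechanism is
  directional); percentages are means over clones with the standard error
  across clones (a pooled mode exists behind a flag). A clone with zero
  unique SNVs contributes 0%, not a missing value.
* **Ti/Tv** is undefined (NaN, reported absent) when a stratum has zero
  transversions — never infinity.
* **Effect severity order** (most severe first): gene_fusion, exon_loss,
  frameshift, stop_gained, stop_lost, start_lost, splice_acceptor,
  splice_donor, start_gained, missense, inframe_indel, synonymous,
  noncoding_exonic, intronic, intergenic. Most-severe-across-transcripts
  aggregation iterates transcripts in sorted id order, so ties are
  deterministic. Splice sites are the canonical 2 intronic bases; an
  inframe indel that introduces a premature stop is stop_gained; an indel
  destroying the annotated start codon (checked on the rebuilt CDS prefix)
  is start_lost regardless of frame. `start_gained` requires annotated 5'
  noncoding exon sequence and so cannot fire on models whose exons equal
  their CDS; `gene_fusion` is only reachable from deletions spanning the
  CDS of two genes.
* **Kinship.** Pairwise-complete sites per pair; multi-allelic sites are
  excluded from the dosage matrix (logged). A pair with no heterozygote in
  either sample is undefined: an error for a single pair, NaN with a
  warning inside the matrix. The reference-derived sample is hom-ref by
  construction and is excluded from the kinship/PCA stage of the pipeline.
* **PCA** uses centered, unscaled dosages (allele-frequency scaling exists
  but is off); missing entries are mean-imputed per site.
* **Dendrogram**: average linkage on d = 0.5 − PHI, negative distances
  clipped to zero with a warning; Newick branch lengths are merge-height
  differences; no bootstrap.
* **SV handling**: records of the same type merge at ≥80% reciprocal
  overlap (insertions: position within 10 bp and length ratio ≥ threshold);
  an optional flag drops SVs intersecting repeat annotation. Percent of
  assembly uses a configured assembly length, falling back to the sum of
  observed contigs.
* **Tests of group differences** delegate to statsmodels (Tukey HSD,
  compact-letter display via insert-and-absorb) and scipy (KS,
  Mann–Whitney); no additional FDR layer is applied on top of Tukey's
  family-wise control.

## Problem sizes

All shipped analyses and tests run on 50 kb genomes with 15 clones
(~1,300 small variants, ~50 TE insertions, 12 SVs), 50,000-site dosage
matrices for the kinship nulls, and ≥500 random CDS variants for the
effect-classifier oracle. These sizes make every recovery check
well-powered (3-SE binomial bands are a small fraction of the configured
rates) while keeping a full suite run in seconds; all stages scale
linearly in genome size and panel size, with the per-base feature index
costing one byte per reference base.

## Open design points resolved here

* Subclade sharing is modelled as descent only (one event, many
  carriers); recurrent mutation producing convergent sharing is not
  simulated.
* The pipeline's Fig-style rate table reports all four feature classes;
  the three-class grouping (merging the two intergenic classes) is a
  trivial aggregation of the emitted table rather than a separate output.
* Sharing-spectrum denominators count variant *sites*, not
  variant–transcript pairs.
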
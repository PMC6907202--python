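"""Shared plumbing for the numbered analysis scripts.

All scripts run from the repository root and share one simulated study
panel under results/fixture (15 clones, 50 kb genome, default conditions,
seed 11).  The fixture is created on demand so every script is runnable in
isolation.
"""

from __future__ import annotations

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
FIXTURE = RESULTS / "fixture"
FIXTURE_NOISY = RESULTS / "fixture_noisy"
TABLES = RESULTS / "tables"
SEED = 11

CLONES = [f"clone{i:02d}" for i in range(1, 16)]


def ensure_fixture() -> Path:
    from clonediv.simulate import SimulationConfig, simulate, write_fixture

    TABLES.mkdir(parents=True, exist_ok=True)
    if not (FIXTURE / "truth.tsv").exists():
        write_fixture(simulate(SimulationConfig(seed=SEED)), FIXTURE)
    if not (FIXTURE_NOISY / "truth.tsv").exists():
        noisy = SimulationConfig(seed=SEED, metric_fail_fraction=0.08,
                                 artifact_homalt_rate=0.004)
        write_fixture(simulate(noisy), FIXTURE_NOISY)
    return FIXTURE


def load_sanitized():
    """Clean fixture through the standard sanitation chain."""
    from clonediv.variants import (FilterConfig, apply_hard_filters,
                                   complete_call_sites, drop_reference_nonref,
                                   read_variant_table)

    ensure_fixture()
    table = read_variant_table(FIXTURE / "variants.vcf")
    table = apply_hard_filters(table, FilterConfig()).passing()
    table, _ = drop_reference_nonref(table, "mother")
    return complete_call_sites(table)


def load_index_and_genes():
    from pyfaidx import Fasta

    from clonediv.features import build_feature_index
    from clonediv.genes import load_gene_models, read_repeats_bed

    ensure_fixture()
    reference = Fasta(str(FIXTURE / "reference.fa"))
    genes = load_gene_models(FIXTURE / "genes.gff3")
    repeats = read_repeats_bed(FIXTURE / "repeats.bed")
    lengths = {n: len(reference[n]) for n in reference.keys()}
    return reference, genes, build_feature_index(genes, repeats, lengths)
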
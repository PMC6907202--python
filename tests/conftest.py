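import pytest

from clonediv.pipeline import RunConfig, run_pipeline
from clonediv.simulate import SimulationConfig, simulate, write_fixture

CLONES = [f"clone{i:02d}" for i in range(1, 16)]


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 50 kb genome, 15 clones, clean calls."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(default_dataset, outdir)
    return outdir


def make_run_config(fixture_dir, outdir, **overrides) -> RunConfig:
    kwargs = dict(
        reference=str(fixture_dir / "reference.fa"),
        gff3=str(fixture_dir / "genes.gff3"),
        repeats_bed=str(fixture_dir / "repeats.bed"),
        vcf=str(fixture_dir / "variants.vcf"),
        tei_tsv=str(fixture_dir / "tei.tsv"),
        sv_vcf=str(fixture_dir / "svs.vcf"),
        outdir=str(outdir),
        clone_samples=list(CLONES),
        reference_sample="mother",
        seed=11,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def run_summary(fixture_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    summary = run_pipeline(make_run_config(fixture_dir, outdir))
    return outdir, summary


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A fast single-contig configuration for focused tests."""
    kwargs = dict(seed=seed, n_contigs=1, contig_length=8000, n_genes=3)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
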
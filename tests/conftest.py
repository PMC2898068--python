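import pytest
from hypothesis import settings

import rnaconcord as rc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """A benchmark-scale simulated study (~13k planted sites)."""
    cfg = rc.SimulationConfig(n_genes=2000, seed=11)
    return rc.simulate_study(cfg)


@pytest.fixture(scope="session")
def fitted(study):
    """Default-pipeline concordance fit of the simulated study."""
    truth = study.truth
    model = rc.ConcordanceAnalysis(
        study.gdna_calls,
        study.cdna.calls,
        exons=truth.exons,
        expression=truth.expression,
        genes=truth.genes,
        known_sites=truth.known_sites,
    )
    return model, model.fit()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A tiny on-disk fixture bundle written through the external formats."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = rc.SimulationConfig(n_genes=40, seed=7)
    manifest = rc.generate_fixture_bundle(cfg, outdir)
    return outdir, cfg, manifest


def make_call(pos=100, *, chrom="chr1", ref="A", genotype=("A", "G"), qual=40.0,
              depth=30, alt=12, end_fraction=0.0, source="cDNA", **kwargs):
    return rc.VariantCall(
        chrom=chrom, pos=pos, ref_allele=ref, genotype=genotype,
        snp_quality=qual, read_depth=depth, alt_support=alt,
        alt_end_fraction=end_fraction, source=source, **kwargs,
    )
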
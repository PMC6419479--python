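import pytest
from hypothesis import settings

from rddscan import GeneIndex, SimulationConfig, simulate_dataset
from rddscan.io_formats import BASES, PileupSite

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


def make_site(
    chrom="chr1",
    pos=100,
    ref="A",
    sample_id="s1",
    mean_baseq=37.0,
    frac_mapq_ge=1.0,
    **base_counts,
):
    """Hand-build a pileup site. Base counts may be ints (split ~evenly across
    strands, so the Fisher strand value stays 0) or (fwd, rev) pairs."""
    counts = {}
    for b in BASES:
        v = base_counts.get(b, 0)
        if isinstance(v, int):
            counts[b] = (v - v // 2, v // 2)
        else:
            counts[b] = (int(v[0]), int(v[1]))
    depth = sum(f + r for f, r in counts.values())
    site = PileupSite(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref_base=ref,
        depth=depth,
        counts=counts,
        mean_baseq=mean_baseq,
        frac_mapq_ge=frac_mapq_ge,
    )
    site.validate()
    return site


@pytest.fixture
def pileup_factory():
    return make_site


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chroms=1,
        chrom_length=20_000,
        n_genes=8,
        n_edit_sites=40,
        n_replicates=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_index(small_dataset):
    return GeneIndex(small_dataset.models)
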
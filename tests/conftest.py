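import numpy as np
import pytest

from sweepscan.variants import GenotypeMatrix, PopulationMap


def make_gm(genotypes, pos=None, chrom=None, samples=None, chrom_lengths=None):
    """Build a small GenotypeMatrix from a nested list of (a0, a1) pairs:
    genotypes[variant][sample] = (allele0, allele1)."""
    a = np.array(genotypes, dtype=np.int8)
    V, S = a.shape[0], a.shape[1]
    if pos is None:
        pos = np.arange(V) * 1000
    if chrom is None:
        chrom = np.full(V, "chr1", dtype=object)
    if samples is None:
        samples = [f"s{i + 1}" for i in range(S)]
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.full(V, "A", dtype=object),
        alt=np.full(V, "G", dtype=object),
        alleles=a,
        samples=samples,
        phased=True,
        chrom_lengths=chrom_lengths,
    )


@pytest.fixture
def small_panel():
    """Deterministic 2-population simulated panel, small enough for fast tests."""
    from sweepscan.simulate import SimConfig, simulate_panel

    cfg = SimConfig(
        seed=11,
        n_pops=2,
        samples_per_pop=10,
        chrom_lengths=[2_000_000],
        n_snps_per_chrom=500,
    )
    return simulate_panel(cfg)


@pytest.fixture
def popmap_two():
    return PopulationMap(
        {"s1": "pop1", "s2": "pop1", "s3": "pop2", "s4": "pop2"}
    )
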
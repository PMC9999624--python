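import numpy as np
import pytest

from pseudohet import popsim
from pseudohet.io_formats import GenotypeMatrix


def make_gm(calls, chrom="chr1", positions=None, accessions=None):
    """GenotypeMatrix from a (n_snps, n_accessions) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if accessions is None:
        accessions = [f"a{i}" for i in range(n)]
    refs = ["A"] * m
    alts = ["G"] * m
    return GenotypeMatrix(accessions, [chrom] * m, positions, refs, alts, calls)


def eligible_genes(sim):
    """Gene ids containing at least one SNP, in annotation order."""
    gm = sim.genotypes
    out = []
    for g in sim.annotation:
        sl = gm.chrom_slice(g.chrom)
        if ((gm.pos[sl] >= g.start) & (gm.pos[sl] <= g.end)).any():
            out.append(g.gene_id)
    return out


def small_config(seed, **kw):
    defaults = dict(n_accessions=60, chrom_lengths=(200_000, 200_000),
                    snp_density=0.002, n_founders=8, recomb_rate=5e-6,
                    founder_weights=(0.3,) + (0.1,) * 7,
                    n_genes_per_chrom=10, gene_length=1000)
    defaults.update(kw)
    return popsim.SimConfig(seed=seed, **defaults)


@pytest.fixture
def small_sim():
    return popsim.simulate_population(small_config(7))


@pytest.fixture
def planted_sim():
    """Small population with one trans duplication planted."""
    sim = popsim.simulate_population(small_config(7))
    gene = eligible_genes(sim)[2]
    event = popsim.plant_duplication(sim, gene, mode="trans", divergence=0.05,
                                     carrier_founder=0, origin_founder=1)
    return sim, event
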
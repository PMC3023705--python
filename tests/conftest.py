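"""Shared fixtures: small seeded pooled-sequencing datasets built in memory."""

import pandas as pd
import pytest

from rrlsnp import rrl_digest as rd
from rrlsnp import synthetic_data as sd


@pytest.fixture(scope="session")
def pool_truth():
    """16-diploid pool, ~80 planted SNPs on a 20 kb genome (seeded)."""
    model = sd.PopulationModel(
        n_individuals=16, ploidy=2, snp_density=4.0,
        maf_distribution=("uniform", 0.05, 0.5), seed=7,
    )
    return sd.simulate_population(model, 20_000)


@pytest.fixture(scope="session")
def pool_fragments(pool_truth):
    chrom, ref = next(iter(pool_truth.references.items()))
    return rd.digest(ref, rd.ALU_I, source_id=chrom)


@pytest.fixture(scope="session")
def errorfree_reads(pool_truth, pool_fragments):
    return sd.simulate_reads(
        pool_truth, pool_fragments, sd.ReadModel(seed=7), target_depth=30
    )


@pytest.fixture(scope="session")
def bovine_like_chromosomes():
    """A surrogate-genome length table with named chromosomes and chrUn bins."""
    return pd.DataFrame(
        {
            "name": [f"chr{i}" for i in range(1, 11)] + ["chrUn.001", "chrUn.002"],
            "length": [50_000_000] * 10 + [5_000_000] * 2,
        }
    )


def read_support(truth, reads):
    """Independent per-variant recount of depth and alt support from reads.

    Counts covering reads and carrier haplotypes directly from the simulation
    output, bypassing the pileup machinery entirely.
    """
    depth = {v.pos: 0 for v in truth.variants}
    alt = {v.pos: 0 for v in truth.variants}
    for r in reads:
        span = sum(n for op, n in r.cigar if op in "MD")
        for v in truth.variants:
            if r.chrom == v.chrom and r.ref_start <= v.pos < r.ref_start + span:
                depth[v.pos] += 1
                if r.haplotype in v.carriers:
                    alt[v.pos] += 1
    return depth, alt
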
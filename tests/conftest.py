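import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import ebwtcall as ec
from ebwtcall import calling, lcp


@pytest.fixture(scope="session")
def figure_reads() -> list[str]:
    """Read set reconstructing the paper-style worked example.

    Two alleles of a genotype carrying the deletion ATGCGCTA -> ATGCTA;
    three reads sequence the long allele, two the short one.  Interleaved
    read order makes the variant cluster read exactly TCCTC.
    """
    long_allele = "ATGCGCTA"
    short_allele = "ATGCTA"
    return [short_allele, long_allele, long_allele, short_allele, long_allele]


@pytest.fixture(scope="session")
def figure_params() -> calling.CallerParams:
    return calling.CallerParams(k_min=3, k_left=2, k_right=2, max_indel=2,
                                min_cov=2, max_edits=2)


@pytest.fixture(scope="session")
def figure_setup(figure_reads, figure_params):
    coll = ec.SequenceCollection(figure_reads)
    index = ec.build_ebwt(coll)
    bv = ec.lcp_bitvectors_from_ebwt(index, figure_params.k_min,
                                     figure_params.k_right)
    return coll, index, bv


@pytest.fixture(scope="session")
def figure_cluster(figure_setup):
    _, index, bv = figure_setup
    for cluster in ec.find_clusters(bv, index):
        if cluster.counts.get("T") == 2 and cluster.counts.get("C") == 3:
            return cluster
    raise AssertionError("worked-example cluster {T:2, C:3} not found")


@pytest.fixture(scope="session")
def errorfree_sim():
    """Small error-free diploid simulation with isolated variants."""
    from ebwtcall import bench, pipeline

    truth = bench.generate_truth(10_000, snp_rate=1e-3, indel_rate=6e-4,
                                 max_indel_len=10, min_spacing=150, seed=5)
    reads = bench.simulate_reads(truth, read_len=100, coverage=40,
                                 sub_error_rate=0.0, seed=6)
    reads = pipeline.augment_reverse_complement(reads)
    coll = ec.SequenceCollection(reads)
    index = ec.build_ebwt(coll)
    params = calling.CallerParams()
    bv = ec.lcp_bitvectors_from_ebwt(index, params.k_min, params.k_right)
    return truth, coll, index, bv, params


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
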
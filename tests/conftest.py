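import numpy as np
import pandas as pd
import pytest

from rrbspipe import bsalign, pipeline, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully featured study configuration (fast to simulate)."""
    return simulate.SimConfig(
        chrom_lengths={"chr1": 120_000, "chr2": 100_000, "chr21": 80_000},
        n_cgis=24,
        n_genes=45,
        target_depth=25,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate.generate_truth(small_cfg)


@pytest.fixture(scope="session")
def small_fragments(small_cfg, small_truth):
    return simulate.digest_rrbs(small_truth.genome, small_cfg)


@pytest.fixture(scope="session")
def small_genomes(small_truth):
    return bsalign.build_converted_genomes(small_truth.genome)


@pytest.fixture(scope="session")
def clean_sample(small_cfg, small_truth, small_fragments, small_genomes):
    """One processed control sample with no sequencing error and perfect
    conversion, for round-trip style checks."""
    from dataclasses import replace

    cfg = replace(small_cfg, base_error_rate=0.0, conversion_efficiency=1.0)
    batch = simulate.simulate_bisulfite_reads(
        small_fragments, small_truth, "clean1", "control", cfg, seed=101
    )
    return pipeline.process_sample(batch, small_genomes)


def make_methylome(rows):
    """Helper to build a bsalign-format methylome table from tuples of
    (chrom, pos0, strand, meth, unmeth[, other, dinuc_other, dinuc_total])."""
    full = []
    for r in rows:
        chrom, pos0, strand, meth, unmeth = r[:5]
        other = r[5] if len(r) > 5 else 0
        d_oth = r[6] if len(r) > 6 else 0
        d_tot = r[7] if len(r) > 7 else meth + unmeth
        depth = meth + unmeth
        full.append(
            (chrom, pos0, strand, meth, unmeth, other, d_oth, d_tot,
             meth / depth if depth else np.nan)
        )
    return pd.DataFrame(
        full,
        columns=["chrom", "pos0", "strand", "meth_count", "unmeth_count",
                 "other_count", "dinuc_other", "dinuc_total", "level"],
    )
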
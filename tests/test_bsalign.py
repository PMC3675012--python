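"""Tests for quality filtering, in-silico conversion, three-letter
alignment, methylation calling, conversion rate and the polymorphic-CpG
filter."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rrbspipe import bsalign, pipeline, seqs, simulate
from conftest import make_methylome


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def test_quality_filter_high_quality_kept():
    q = np.full((1, 36), 40)
    mask, keep = bsalign.quality_filter(q)
    assert keep[0] and mask.all()


def test_quality_filter_low_quality_dropped():
    q = np.full((1, 36), 2)
    mask, keep = bsalign.quality_filter(q)
    assert not keep[0] and not mask.any()


def test_quality_filter_boundary_at_cutoff():
    q = np.full((1, 10), 30)
    mask, keep = bsalign.quality_filter(q, q_cutoff=30)
    assert keep[0] and mask.all()  # Q30 meets the Q>=30 rule
    q[:, :6] = 29  # 60% masked -> dropped
    mask, keep = bsalign.quality_filter(q, q_cutoff=30)
    assert not keep[0]


def test_quality_filter_pair_and_malformed():
    ok, m1, m2 = bsalign.quality_filter_pair("I" * 10, "I" * 10)
    assert ok and m1.all() and m2.all()
    with pytest.raises(bsalign.AlignmentError):
        bsalign.parse_phred33("\x01bad")


# ---------------------------------------------------------------------------
# Converted genomes and read conversion
# ---------------------------------------------------------------------------

def test_build_converted_genomes_substitutions():
    g = bsalign.build_converted_genomes({"c": "ACGT"})
    L = 4
    assert seqs.decode(g.c2t[:L]) == "ATGT"
    assert seqs.decode(g.g2a[:L]) == "ACAT"
    # linear-scan oracle: no C anywhere in C2T, no G in G2A
    assert not (g.c2t == seqs.C).any()
    assert not (g.g2a == seqs.G).any()


def test_converted_genome_idempotent(small_truth):
    seq = small_truth.genome["chr1"][:5000]
    once = seqs.c2t(seq)
    assert np.array_equal(seqs.c2t(once), once)


def test_convert_read_classes():
    conv, cls = bsalign.convert_read("TTGGAC")  # C=1 < G=2
    assert (conv, cls) == ("TTGGAT", "C2T")
    conv, cls = bsalign.convert_read("CCAAT")   # G=0 < C=2
    assert (conv, cls) == ("CCAAT", "G2A")
    conv, cls = bsalign.convert_read("ATTA")    # tie
    assert cls == "ambiguous"
    assert conv == ("ATTA", "ATTA")
    conv, cls = bsalign.convert_read("GCGC")    # tie with real substitutions
    assert cls == "ambiguous"
    assert conv == ("GTGT", "ACAC")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _random_genome(n, seed=0, p=(0.3, 0.2, 0.2, 0.3)):
    rng = np.random.default_rng(seed)
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def test_align_unique_substring_maps_exactly():
    seq = _random_genome(5000, seed=1)
    g = bsalign.build_converted_genomes({"c": seq})
    read = seqs.decode(seqs.c2t(seq[1000:1036]))  # converted top-strand read
    rec = bsalign.align_read(read, g)
    assert rec is not None
    assert (rec["chrom"], rec["pos0"], rec["mismatches"]) == ("c", 1000, 0)
    assert rec["ref"] == "C2T"


def test_align_reverse_orientation_read():
    seq = _random_genome(5000, seed=2)
    g = bsalign.build_converted_genomes({"c": seq})
    # mate-2 style read: reverse complement of a C->T converted region
    read = seqs.decode(seqs.revcomp(seqs.c2t(seq[2000:2036])))
    rec = bsalign.align_read(read, g)
    assert rec is not None
    assert rec["pos0"] == 2000
    assert rec["orient"] == -1


def test_align_duplicated_locus_ambiguous():
    """A read planted at two identical loci has two best hits and must
    come back unmapped; an exhaustive scan confirms both loci exist."""
    seq = _random_genome(6000, seed=3)
    seq[3000:3036] = seq[1000:1036]
    g = bsalign.build_converted_genomes({"c": seq})
    read_arr = seqs.c2t(seq[1000:1036])
    # exhaustive oracle in converted space
    conv = seqs.c2t(seq)
    hits = [i for i in range(len(conv) - 35)
            if np.array_equal(conv[i:i + 36], read_arr)]
    assert hits == [1000, 3000]
    assert bsalign.align_read(seqs.decode(read_arr), g) is None


def test_align_mismatch_cap():
    seq = _random_genome(5000, seed=4)
    g = bsalign.build_converted_genomes({"c": seq})
    arr = seqs.c2t(seq[1200:1236])
    for n_mm, expected_mapped in ((2, True), (3, False)):
        r = arr.copy()
        # mutate positions outside both seed windows is impossible (36bp);
        # use the second half so the first 16-mer seed stays intact
        for j in range(n_mm):
            col = 33 - j
            # swap A<->G: distinct both raw and in C2T-converted space
            r[col] = seqs.G if r[col] != seqs.G else seqs.A
        rec = bsalign.align_read(seqs.decode(r), g)
        if expected_mapped:
            assert rec is not None and rec["mismatches"] == n_mm
        else:
            assert rec is None


def test_simulated_error_free_reads_map_to_origin(small_cfg, small_truth,
                                                  small_fragments, small_genomes):
    """>=95% of error-free reads from the toy genome map back to their
    recorded origin (the rest hit repeated or ambiguous loci)."""
    cfg = replace(small_cfg, base_error_rate=0.0)
    batch = simulate.simulate_bisulfite_reads(
        small_fragments, small_truth, "s", "case", cfg, seed=12
    )
    aln = bsalign.align_batch(batch.r1, small_genomes)
    ci, local = small_genomes.global_to_chrom(aln.gpos)
    names = np.array(small_genomes.chrom_names, dtype=object)[ci]
    side = batch.sidecar
    expected_start = np.where(
        side.strand.to_numpy() == "+",
        side.frag_start.to_numpy(),
        side.frag_end.to_numpy() - cfg.read_length,
    )
    good = (
        (names == side.chrom.to_numpy()[aln.read_idx])
        & (local == expected_start[aln.read_idx])
    )
    mapped_correct = good.sum() / len(batch.names)
    assert mapped_correct >= 0.95


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------

def test_single_read_evidence_counts():
    """One read carrying a C over a CpG yields (1 meth, 0 unmeth)."""
    seq = _random_genome(4000, seed=5)
    seq[2000:2002] = seqs.encode("CG")
    g = bsalign.build_converted_genomes({"c": seq})
    read = seq[1990:2026].copy()
    conv = seqs.c2t(read)
    conv[10] = seqs.C  # retain the CpG cytosine (methylated)
    aln = bsalign.align_batch(conv[None, :], g)
    assert len(aln) == 1
    meth, tally = bsalign.call_methylation(aln, conv[None, :], None, g)
    row = meth[(meth.pos0 == 2000) & (meth.strand == "+")]
    assert len(row) == 1
    assert (int(row.meth_count.iloc[0]), int(row.unmeth_count.iloc[0])) == (1, 0)
    assert row.level.iloc[0] == 1.0


def test_round_trip_binary_truth_exact(clean_sample, small_truth):
    """Error 0, efficiency 1, truth levels in {0,1}: every covered site's
    called level equals 0/1-rounded truth at fully deterministic sites."""
    meth = clean_sample.methylome
    tm = small_truth.methylome
    binary = tm[(tm.p_control == 0.0) | (tm.p_control == 1.0)]
    merged = meth.merge(binary, on=["chrom", "pos0", "strand"])
    if len(merged):
        assert (merged.level == merged.p_control).all()
    # and across all sites the estimate is a consistent binomial draw
    merged_all = meth.merge(tm, on=["chrom", "pos0", "strand"])
    depth = merged_all.meth_count + merged_all.unmeth_count
    ok = depth >= 30
    err = np.abs(merged_all.level[ok] - merged_all.p_control[ok])
    bound = 4 * np.sqrt(merged_all.p_control[ok] * (1 - merged_all.p_control[ok])
                        / depth[ok]) + 1e-9
    assert (err <= np.maximum(bound, 0.15)).mean() > 0.99


def test_counts_partition_unmasked_bases(clean_sample):
    meth = clean_sample.methylome
    # other_count stays rare when there are no sequencing errors (SNP alleles only)
    total = (meth.meth_count + meth.unmeth_count + meth.other_count).sum()
    assert meth.other_count.sum() / total < 0.02


def test_depth_estimate_matches_binomial_oracle(small_truth, small_genomes, small_cfg):
    """Truth level 0.6 at high depth: called level within 3 binomial SE."""
    tm = small_truth.methylome.copy()
    tm["p_control"] = 0.6
    tm["p_case"] = 0.6
    truth2 = simulate.SimTruth(small_cfg, small_truth.genome, small_truth.genes,
                               small_truth.cgis, tm, small_truth.snps.iloc[0:0])
    cfg = replace(small_cfg, base_error_rate=0.0, conversion_efficiency=1.0,
                  target_depth=60, snp_rate=0.0)
    frags = simulate.digest_rrbs(truth2.genome, cfg).head(30)
    batch = simulate.simulate_bisulfite_reads(frags, truth2, "s", "control", cfg, seed=6)
    res = pipeline.process_sample(batch, small_genomes)
    m = res.methylome
    deep = m[(m.meth_count + m.unmeth_count) >= 40]
    assert len(deep) > 50
    depth = (deep.meth_count + deep.unmeth_count).to_numpy()
    se = np.sqrt(0.6 * 0.4 / depth)
    within = np.abs(deep.level.to_numpy() - 0.6) <= 3 * se
    assert within.mean() > 0.95


# ---------------------------------------------------------------------------
# Conversion rate
# ---------------------------------------------------------------------------

def test_conversion_rate_arithmetic():
    t = bsalign.EvidenceTally(
        glen=0, **{k: np.zeros(0, dtype=np.int32) for k in
                   ("meth_f", "unmeth_f", "other_f", "meth_r", "unmeth_r", "other_r",
                    "dinuc_other_f", "dinuc_total_f", "dinuc_other_r", "dinuc_total_r")},
    )
    t.conv_converted, t.conv_unconverted = 990, 10
    assert bsalign.conversion_rate(t) == pytest.approx(0.99)
    t.conv_converted, t.conv_unconverted = 500, 0
    assert bsalign.conversion_rate(t) == 1.0
    t.conv_converted = t.conv_unconverted = 0
    with pytest.raises(bsalign.AlignmentError):
        bsalign.conversion_rate(t)


def test_conversion_rate_recovered_from_simulation(clean_sample):
    assert clean_sample.conversion_rate == 1.0  # efficiency 1.0 fixture


# ---------------------------------------------------------------------------
# Polymorphic-CpG filter
# ---------------------------------------------------------------------------

def test_polymorphic_filter_thresholds():
    meth = make_methylome([
        ("chr1", 100, "+", 5, 2, 0, 3, 10),   # 30% other -> excluded
        ("chr1", 200, "+", 5, 2, 0, 2, 10),   # exactly 20% -> retained
        ("chr1", 300, "+", 5, 5, 0, 0, 10),   # clean -> retained
    ])
    kept, excluded = bsalign.filter_polymorphic_cpgs(meth)
    assert list(excluded.pos0) == [100]
    assert list(kept.pos0) == [200, 300]


def test_snp_sites_enriched_among_excluded(small_cfg, small_truth, small_fragments,
                                           small_genomes):
    """Heterozygous CpG-destroying SNP sites should be flagged as
    polymorphic far more often than clean sites."""
    cfg = replace(small_cfg, base_error_rate=0.0, conversion_efficiency=1.0)
    batch = simulate.simulate_bisulfite_reads(
        small_fragments, small_truth, "s", "control", cfg, seed=33
    )
    res = pipeline.process_sample(batch, small_genomes)
    snp_keys = set()
    for r in small_truth.snps.itertuples():
        snp_keys.add((r.chrom, r.cpg_pos, "+"))
        snp_keys.add((r.chrom, r.cpg_pos + 1, "-"))

    def snp_frac(df):
        if len(df) == 0:
            return 0.0
        keys = set(zip(df.chrom, df.pos0, df.strand))
        return len(keys & snp_keys) / len(keys)

    exc_frac = snp_frac(res.excluded_sites)
    kept_frac = snp_frac(res.methylome)
    assert len(res.excluded_sites) > 0
    assert exc_frac >= 10 * max(kept_frac, 1e-9)


def test_no_alignment_reported_beyond_mismatch_cap(small_cfg, small_truth,
                                                   small_fragments, small_genomes):
    batch = simulate.simulate_bisulfite_reads(
        small_fragments, small_truth, "s", "case", small_cfg, seed=14
    )
    aln = bsalign.align_batch(batch.r1[:2000], small_genomes, max_mismatches=2)
    assert (aln.mismatches <= 2).all()
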
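"""Tests for the synthetic-data generator: truth methylome, in-silico
digestion, bisulfite read simulation and expression counts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rrbspipe import seqs, simulate
from rrbspipe.seqs import C, G


def test_config_validation_rejects_bad_windows():
    cfg = simulate.SimConfig(fragment_windows=((150, 140),))
    with pytest.raises(simulate.SimConfigError):
        cfg.validate()
    cfg = simulate.SimConfig(fragment_windows=((150, 197), (190, 230)))
    with pytest.raises(simulate.SimConfigError):
        cfg.validate()
    cfg = simulate.SimConfig(meth_weights=(0.8, 0.5, 0.1))
    with pytest.raises(simulate.SimConfigError):
        cfg.validate()


def test_default_fragment_windows():
    cfg = simulate.SimConfig()
    assert cfg.fragment_windows == ((150, 197), (207, 230))
    assert cfg.read_length == 36
    assert (cfg.n_control_samples, cfg.n_case_samples) == (6, 11)


def test_truth_deterministic(small_cfg):
    t1 = simulate.generate_truth(small_cfg)
    t2 = simulate.generate_truth(small_cfg)
    for chrom in t1.genome:
        assert np.array_equal(t1.genome[chrom], t2.genome[chrom])
    pd.testing.assert_frame_equal(t1.methylome, t2.methylome)
    pd.testing.assert_frame_equal(t1.genes, t2.genes)
    pd.testing.assert_frame_equal(t1.snps, t2.snps)


def test_cgis_are_cg_enriched(small_truth):
    """Direct counting oracle: CG dinucleotide frequency inside planted
    CGIs exceeds the genome background."""
    total_cg = 0
    total_len = 0
    cgi_cg = 0
    cgi_len = 0
    for chrom, seq in small_truth.genome.items():
        cg = (seq[:-1] == C) & (seq[1:] == G)
        total_cg += int(cg.sum())
        total_len += len(seq) - 1
        for r in small_truth.cgis[small_truth.cgis.chrom == chrom].itertuples():
            cgi_cg += int(cg[r.start : r.end - 1].sum())
            cgi_len += r.end - r.start - 1
    assert cgi_cg / cgi_len > 2 * (total_cg / total_len)


def test_zero_spike_fraction_gives_identical_groups(small_cfg):
    cfg = replace(small_cfg, spike_fraction=0.0)
    truth = simulate.generate_truth(cfg)
    assert np.array_equal(truth.methylome.p_control, truth.methylome.p_case)
    assert not truth.methylome.spiked.any()


def test_spiked_sites_shifted_by_delta(small_truth, small_cfg):
    tm = small_truth.methylome
    spiked = tm[tm.spiked]
    assert len(spiked) > 0
    diff = spiked.p_case - spiked.p_control
    clipped = spiked.p_control + small_cfg.spike_delta > 1.0
    assert diff[~clipped].to_numpy() == pytest.approx(
        np.full((~clipped).sum(), small_cfg.spike_delta)
    )
    unspiked = tm[~tm.spiked]
    assert np.array_equal(unspiked.p_control, unspiked.p_case)


def test_methylome_is_bimodal(small_truth, small_cfg):
    """The configured near-0/near-1 mixture masses should be visible in
    the truth distribution (promoter-CGI sites push extra mass to 0)."""
    m = small_truth.methylome.p_control.to_numpy()
    near0 = (m <= 0.05).mean()
    near1 = (m >= 0.95).mean()
    w0, w1, _ = small_cfg.meth_weights
    assert near0 >= w0 * 0.7
    assert 0.3 * w1 <= near1 <= 2.5 * w1


def test_digest_manual_cut_enumeration():
    """300 bp sequence with CCGG at offsets 10 and 180 and no TCGA:
    cuts at 11 and 181, internal fragment length 170 retained."""
    rng = np.random.default_rng(8)
    seq = rng.choice([0, 3], size=300).astype(np.uint8)  # A/T only: no sites
    seq[10:14] = seqs.encode("CCGG")
    seq[180:184] = seqs.encode("CCGG")
    cfg = simulate.SimConfig()
    frags = simulate.digest_rrbs({"c": seq}, cfg)
    assert len(frags) == 1
    f = frags.iloc[0]
    assert (f.start, f.end, f.length) == (11, 181, 170)
    assert f.cutter_at_start == "MspI" and f.cutter_at_end == "MspI"


def test_digest_taqi_and_chromosome_end():
    seq = np.zeros(400, dtype=np.uint8)  # all A
    seq[200:204] = seqs.encode("TCGA")
    cfg = simulate.SimConfig(fragment_windows=((150, 250),))
    frags = simulate.digest_rrbs({"c": seq}, cfg)
    # cut at 201: fragments [0,201) (201bp, kept) and [201,400) (199bp, kept)
    assert len(frags) == 2
    assert frags.iloc[0].cutter_at_start == "chrom_end"
    assert frags.iloc[0].cutter_at_end == "TaqaI"
    assert frags.iloc[1].cutter_at_start == "TaqaI"


def test_digest_no_sites_no_fragments():
    seq = np.zeros(500, dtype=np.uint8)
    assert len(simulate.digest_rrbs({"c": seq}, simulate.SimConfig())) == 0


def test_fragment_boundaries_coincide_with_cut_offsets(small_truth, small_fragments):
    """Every retained fragment boundary is a CCGG/TCGA cut offset or a
    chromosome end."""
    for chrom, sub in small_fragments.groupby("chrom"):
        seq = small_truth.genome[chrom]
        for f in sub.itertuples():
            for pos, cutter in ((f.start, f.cutter_at_start), (f.end, f.cutter_at_end)):
                if cutter == "chrom_end":
                    assert pos in (0, len(seq))
                else:
                    motif = "CCGG" if cutter == "MspI" else "TCGA"
                    assert seqs.decode(seq[pos - 1 : pos + 3]) == motif
            lo, hi = f.start, f.end
            assert any(w[0] <= hi - lo <= w[1]
                       for w in ((150, 197), (207, 230)))


def _clean_reads(truth, frags, cfg, level, seed=3):
    tm = truth.methylome.copy()
    tm["p_control"] = level
    tm["p_case"] = level
    truth2 = simulate.SimTruth(cfg, truth.genome, truth.genes, truth.cgis, tm, truth.snps)
    cfg2 = replace(cfg, base_error_rate=0.0, conversion_efficiency=1.0, snp_rate=0.0)
    return simulate.simulate_bisulfite_reads(frags, truth2, "s", "control", cfg2, seed=seed)


def _cpg_c_positions_in_reads(batch, truth, cfg):
    """Yield (read_row, col, base) for mate-1 positions over CpG cytosines
    of the molecule's strand."""
    site = {}
    for r in truth.methylome.itertuples():
        site.setdefault((r.chrom, r.strand), set()).add(r.pos0)
    for i, r in enumerate(batch.sidecar.itertuples()):
        positions = site.get((r.chrom, r.strand), set())
        L = r.frag_end - r.frag_start
        for col in range(cfg.read_length):
            fwd = r.frag_start + col if r.strand == "+" else r.frag_end - 1 - col
            if fwd in positions:
                yield i, col, batch.r1[i, col]


def test_fully_methylated_reads_keep_cpg_cytosines(small_truth, small_fragments, small_cfg):
    batch = _clean_reads(small_truth, small_fragments.head(40), small_cfg, 1.0)
    hits = list(_cpg_c_positions_in_reads(batch, small_truth, small_cfg))
    assert len(hits) > 100
    assert all(b == C for _, _, b in hits)


def test_fully_unmethylated_reads_convert_cpg_cytosines(small_truth, small_fragments, small_cfg):
    batch = _clean_reads(small_truth, small_fragments.head(40), small_cfg, 0.0)
    hits = list(_cpg_c_positions_in_reads(batch, small_truth, small_cfg))
    assert len(hits) > 100
    assert all(b == seqs.T for _, _, b in hits)


def test_partial_conversion_efficiency_recovered(small_truth, small_fragments, small_cfg):
    """With efficiency 0.99 and no errors, ~1% of non-CpG Cs stay C."""
    cfg = replace(small_cfg, base_error_rate=0.0, conversion_efficiency=0.99,
                  snp_rate=0.0)
    batch = simulate.simulate_bisulfite_reads(
        small_fragments, small_truth, "s", "control", cfg, seed=4
    )
    cpg_pos = {}
    for r in small_truth.methylome.itertuples():
        cpg_pos.setdefault((r.chrom, r.strand), set()).add(r.pos0)
    n_c = 0
    n_tot = 0
    for i, r in enumerate(batch.sidecar.head(4000).itertuples()):
        sites = cpg_pos.get((r.chrom, r.strand), set())
        seq_fwd = small_truth.genome[r.chrom]
        for col in range(cfg.read_length):
            fwd = r.frag_start + col if r.strand == "+" else r.frag_end - 1 - col
            ref_base = seq_fwd[fwd]
            is_c_on_strand = (ref_base == C) if r.strand == "+" else (ref_base == G)
            if is_c_on_strand and fwd not in sites:
                n_tot += 1
                if batch.r1[i, col] == C:
                    n_c += 1
    frac = n_c / n_tot
    se = np.sqrt(0.01 * 0.99 / n_tot)
    assert abs(frac - 0.01) < 3 * se


def test_reads_deterministic(small_truth, small_fragments, small_cfg):
    b1 = simulate.simulate_bisulfite_reads(small_fragments, small_truth, "x", "case",
                                           small_cfg, seed=7)
    b2 = simulate.simulate_bisulfite_reads(small_fragments, small_truth, "x", "case",
                                           small_cfg, seed=7)
    assert b1.names == b2.names
    assert np.array_equal(b1.r1, b2.r1)
    assert np.array_equal(b1.r2, b2.r2)


def test_short_fragment_skipped(small_truth, small_cfg, caplog):
    frag = pd.DataFrame(
        [("chr1", 100, 120, "MspI", "MspI", 20)],
        columns=["chrom", "start", "end", "cutter_at_start", "cutter_at_end", "length"],
    )
    with caplog.at_level("WARNING"):
        batch = simulate.simulate_bisulfite_reads(frag, small_truth, "s", "control",
                                                  small_cfg, seed=1)
    assert len(batch.names) == 0
    assert "shorter than read length" in caplog.text


def test_expression_dosage_and_null_ratio():
    """Law-of-large-numbers check of the planted 1.5x dosage effect over
    >200 trisomic genes; counts are depth-normalised per sample so the
    simulated library-size variation cancels."""
    cfg = simulate.SimConfig(
        genes_per_chrom={"chr1": 1100, "chr2": 1000, "chr21": 260}, seed=21
    )
    truth = simulate.generate_truth(cfg)
    ctrl = simulate.simulate_expression_counts(truth.genes, cfg, "control", seed=1)
    case = simulate.simulate_expression_counts(truth.genes, cfg, "case", seed=2)

    def norm_mean(df):
        mat = df.drop(columns="gene_id").to_numpy(dtype=float)
        cpm = mat / mat.sum(axis=0, keepdims=True)
        return cpm.mean(axis=1)

    tri = (truth.genes.chrom == "chr21").to_numpy()
    mc = norm_mean(ctrl)
    mx = norm_mean(case)
    ok = ctrl.drop(columns="gene_id").mean(axis=1).to_numpy() > 50
    ratio_tri = float((mx[tri & ok] / mc[tri & ok]).mean())
    ratio_bg = float((mx[~tri & ok] / mc[~tri & ok]).mean())
    assert (tri & ok).sum() >= 200
    # non-trisomic genes carry no planted effect (small deflation from the
    # per-million normalisation against the boosted trisomic share)
    assert 0.88 <= ratio_bg <= 1.05
    # relative dosage is library- and composition-free
    assert 1.40 <= ratio_tri / ratio_bg <= 1.60


def test_expression_zero_abundance_zero_counts(small_truth, small_cfg):
    cfg = replace(small_cfg, expression_mean_count=0.0)
    out = simulate.simulate_expression_counts(small_truth.genes, cfg, "control", seed=5)
    assert (out.drop(columns="gene_id").to_numpy() == 0).all()


def test_snp_table_destroys_cpgs(small_truth):
    snps = small_truth.snps
    assert len(snps) > 0
    for r in snps.head(20).itertuples():
        seq = small_truth.genome[r.chrom]
        assert seqs.decode(seq[r.cpg_pos : r.cpg_pos + 2]) == "CG"
        assert (r.ref, r.alt) in (("C", "T"), ("G", "A"))
        assert r.pos0 in (r.cpg_pos, r.cpg_pos + 1)
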
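"""End-to-end study drivers: simulate a cohort, call methylation per
sample, run the differential analyses, and score the calls against the
simulator's ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bsalign, methdiff, simulate

log = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample_id: str
    group: str
    methylome: pd.DataFrame          # polymorphic-filtered
    excluded_sites: pd.DataFrame
    conversion_rate: float
    n_reads: int
    n_aligned: int


@dataclass
class StudyResult:
    cfg: simulate.SimConfig
    truth: simulate.SimTruth
    fragments: pd.DataFrame
    genomes: bsalign.ConvertedGenomePair
    samples: list[SampleResult]
    samplesheet: pd.DataFrame
    cohort: methdiff.CohortTable
    diffcalls: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def process_sample(
    batch: simulate.ReadBatch,
    genomes: bsalign.ConvertedGenomePair,
    q_cutoff: int = 30,
    max_mismatches: int = 2,
) -> SampleResult:
    """Quality-filter, align and call one sample's read batch."""
    n_pairs = len(batch.names)
    reads = np.vstack([batch.r1, batch.r2]) if n_pairs else batch.r1
    quals = np.vstack([batch.q1, batch.q2]) if n_pairs else batch.q1
    pair_ids = np.concatenate([np.arange(n_pairs)] * 2) if n_pairs else np.empty(0, int)
    mate_no = np.concatenate(
        [np.ones(n_pairs, dtype=np.int8), np.full(n_pairs, 2, dtype=np.int8)]
    ) if n_pairs else np.empty(0, np.int8)
    base_mask, read_keep = bsalign.quality_filter(quals, q_cutoff)
    keep_idx = np.nonzero(read_keep)[0]
    aln = bsalign.align_batch(reads[keep_idx], genomes, max_mismatches)
    # re-map alignment read indices to the full matrices
    aln = bsalign.AlignmentSet(
        read_idx=keep_idx[aln.read_idx],
        gpos=aln.gpos, ref=aln.ref, orient=aln.orient, mismatches=aln.mismatches,
    )
    meth, tally = bsalign.call_methylation(
        aln, reads, base_mask, genomes, pair_ids=pair_ids, mate_no=mate_no
    )
    filtered, excluded = bsalign.filter_polymorphic_cpgs(meth)
    try:
        conv = bsalign.conversion_rate(tally)
    except bsalign.AlignmentError:
        conv = float("nan")
    return SampleResult(
        sample_id=batch.sample_id,
        group=batch.group,
        methylome=filtered,
        excluded_sites=excluded,
        conversion_rate=conv,
        n_reads=int(len(reads)),
        n_aligned=int(len(aln)),
    )


def make_samplesheet(cfg: simulate.SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_control_samples):
        rows.append((f"N{i + 1}", "control", "M" if i % 2 == 0 else "F"))
    for i in range(cfg.n_case_samples):
        rows.append((f"T{i + 1}", "case", "M" if i % 2 == 0 else "F"))
    return pd.DataFrame(rows, columns=["sample_id", "group", "sex"])


def run_methylation_study(
    cfg: simulate.SimConfig,
    min_diff: float = 0.10,
    alpha: float = 0.05,
    min_depth: int = 10,
) -> StudyResult:
    """Simulate the full cohort and run the CpG-level differential
    analysis, scoring calls against the planted truth."""
    truth = simulate.generate_truth(cfg)
    fragments = simulate.digest_rrbs(truth.genome, cfg)
    genomes = bsalign.build_converted_genomes(truth.genome)
    sheet = make_samplesheet(cfg)
    root = np.random.SeedSequence([cfg.seed, 77_101])
    sample_seeds = root.spawn(len(sheet))
    samples = []
    for (row, seed) in zip(sheet.itertuples(), sample_seeds):
        batch = simulate.simulate_bisulfite_reads(
            fragments, truth, row.sample_id, row.group, cfg, seed=seed
        )
        res = process_sample(batch, genomes)
        samples.append(res)
        log.info("sample %s: %d reads, %d aligned, conversion %.4f",
                 row.sample_id, res.n_reads, res.n_aligned, res.conversion_rate)
    cohort = methdiff.build_cohort({s.sample_id: s.methylome for s in samples}, sheet)
    analyzable = methdiff.select_analyzable_cpgs(cohort, min_depth=min_depth)
    calls = methdiff.test_differential(analyzable, min_diff=min_diff, alpha=alpha,
                                       min_depth=min_depth)
    metrics = score_against_truth(calls, truth)
    metrics["mean_conversion_rate"] = float(
        np.nanmean([s.conversion_rate for s in samples])
    )
    metrics["n_analyzable_sites"] = int(len(analyzable.sites))
    return StudyResult(
        cfg=cfg, truth=truth, fragments=fragments, genomes=genomes,
        samples=samples, samplesheet=sheet, cohort=cohort,
        diffcalls=calls, metrics=metrics,
    )


def score_against_truth(calls: pd.DataFrame, truth: simulate.SimTruth) -> dict:
    """Sensitivity on spiked CpGs and false-call rate on unspiked CpGs."""
    key = truth.methylome[["chrom", "pos0", "strand", "spiked"]]
    merged = calls.merge(key, on=["chrom", "pos0", "strand"], how="left")
    merged["spiked"] = merged.spiked.fillna(False)
    spiked = merged[merged.spiked]
    unspiked = merged[~merged.spiked]
    sens = float((spiked.call == "hyper").mean()) if len(spiked) else float("nan")
    fcr = float((unspiked.call != "none").mean()) if len(unspiked) else float("nan")
    return {
        "n_spiked_tested": int(len(spiked)),
        "n_unspiked_tested": int(len(unspiked)),
        "sensitivity": sens,
        "false_call_rate": fcr,
    }


def run_expression_study(cfg: simulate.SimConfig, seed_offset: int = 0) -> dict:
    """Simulate counts for both groups and run the expression analyses."""
    from . import expression

    truth = simulate.generate_truth(cfg)
    genes = truth.genes
    ctrl = simulate.simulate_expression_counts(
        genes, cfg, "control", seed=[cfg.seed, 41_000 + seed_offset]
    )
    case = simulate.simulate_expression_counts(
        genes, cfg, "case", seed=[cfg.seed, 42_000 + seed_offset]
    )
    counts = ctrl.merge(case, on="gene_id")
    sheet = pd.DataFrame(
        {
            "sample_id": [c for c in counts.columns if c != "gene_id"],
            "group": ["control" if c.startswith("control") else "case"
                      for c in counts.columns if c != "gene_id"],
        }
    )
    lengths = pd.Series(
        genes.exonic_length_bp.to_numpy(dtype=float), index=genes.gene_id
    )
    de = expression.test_differential_expression(counts, lengths, sheet)
    tri_genes = set(genes[genes.chrom == cfg.trisomic_chrom].gene_id)
    summary = expression.expression_change_summary(
        de, {"trisomic": tri_genes, "all": set(genes.gene_id)}
    )
    return {
        "truth": truth,
        "counts": counts,
        "samplesheet": sheet,
        "de": de,
        "summary": summary,
    }
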
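"""Synthetic-data generator: toy genome, gene models, CpG islands,
group-structured truth methylome, RRBS fragments, paired bisulfite
reads, and overdispersed expression counts.

The generator plants everything the downstream stages are supposed to
recover: a bimodal methylome (most CpGs near 0 or near 1), CG-dense
islands, MspI/TaqaI restriction fragments size-selected into two
windows, hypermethylation spiked into the case group at a fraction of
promoter CpGs, heterozygous CpG-destroying SNPs, and a dosage effect on
genes of the trisomic surrogate chromosome.  Every stage is seeded and
byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import regions as _regions
from . import seqs
from .seqs import A, C, G, T

log = logging.getLogger(__name__)


class SimConfigError(ValueError):
    pass


def _default_chroms() -> dict[str, int]:
    return {"chr1": 800_000, "chr2": 700_000, "chr21": 500_000}


@dataclass
class SimConfig:
    """Study-condition settings for the simulator.

    Sample sizes (6 control / 11 case methylomes, 5/4 expression
    libraries), read geometry (2x36 bp), fragment windows (150-197 and
    207-230 bp) and the bimodal methylome mixture (~30% of CpGs near 0,
    ~10% near 1) mirror the study design this pipeline models.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    trisomic_chrom: str = "chr21"
    # CpG islands
    n_cgis: int = 150
    cgi_length_bp: int = 600
    # gene models
    n_genes: int = 300
    exonic_length_bp: int = 1500
    genes_per_chrom: dict[str, int] | None = None
    # methylome mixture: (near-0, near-1, partial) weights + concentration
    meth_weights: tuple[float, float, float] = (0.30, 0.10, 0.60)
    meth_concentration: float = 30.0
    # cohort design
    n_control_samples: int = 6
    n_case_samples: int = 11
    # planted case-group hypermethylation
    spike_fraction: float = 0.05
    spike_delta: float = 0.20
    # sequencing model
    conversion_efficiency: float = 0.995
    base_error_rate: float = 0.001
    target_depth: int = 30
    fragment_windows: tuple[tuple[int, int], ...] = ((150, 197), (207, 230))
    read_length: int = 36
    # variants
    snp_rate: float = 0.01
    # expression model
    trisomy_expression_factor: float = 1.5
    n_control_rna: int = 5
    n_case_rna: int = 4
    expression_mean_count: float = 500.0
    expression_nb_shape: float = 20.0
    gc_content: float = 0.40
    seed: int = 0

    def validate(self) -> None:
        w = self.meth_weights
        if any(x < 0 or x > 1 for x in w) or sum(w) > 1.0 + 1e-9:
            raise SimConfigError("methylome mixture weights must be in [0,1] and sum to <= 1")
        for frac in (self.spike_fraction, self.snp_rate, self.conversion_efficiency,
                     self.base_error_rate, self.gc_content):
            if not (0.0 <= frac <= 1.0):
                raise SimConfigError("fractions must lie in [0, 1]")
        if self.target_depth < 1:
            raise SimConfigError("target depth must be >= 1")
        wins = sorted(self.fragment_windows)
        for lo, hi in wins:
            if lo >= hi:
                raise SimConfigError("fragment window low must be < high")
        for (_, h1), (l2, _) in zip(wins, wins[1:]):
            if l2 <= h1:
                raise SimConfigError("fragment windows must not overlap")
        if self.trisomic_chrom not in self.chrom_lengths:
            raise SimConfigError("trisomic_chrom must be one of chrom_lengths")
        if self.read_length < 20:
            raise SimConfigError("read_length too short for 16-mer seeding")


@dataclass
class SimTruth:
    """Ground-truth bundle: genome, annotations and methylome truth."""

    cfg: SimConfig
    genome: dict[str, np.ndarray]           # encoded uint8 sequences
    genes: pd.DataFrame                     # gene_id, chrom, strand, tss, tts, exonic_length_bp
    cgis: pd.DataFrame                      # chrom, start, end
    methylome: pd.DataFrame                 # chrom, pos0, strand, p_control, p_case, spiked
    snps: pd.DataFrame                      # chrom, pos0, ref, alt, cpg_pos


@dataclass
class ReadBatch:
    """Paired reads plus their ground-truth sidecar, kept as arrays."""

    sample_id: str
    group: str
    names: list[str]
    r1: np.ndarray      # (n, read_length) uint8
    q1: np.ndarray      # (n, read_length) phred values
    r2: np.ndarray
    q2: np.ndarray
    sidecar: pd.DataFrame  # read, chrom, frag_start, frag_end, strand, hap_alt


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _place_cgis(rng, L: int, n: int, length: int) -> np.ndarray:
    """Non-overlapping CGI starts: one random offset per equal-width bin."""
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    bin_w = L // n
    n = min(n, max(L // max(2 * length, 1), 0))
    bin_w = L // max(n, 1)
    starts = []
    for i in range(n):
        lo = i * bin_w
        hi = min((i + 1) * bin_w, L) - length
        if hi <= lo:
            continue
        starts.append(int(rng.integers(lo, hi)))
    return np.array([[s, s + length] for s in starts], dtype=np.int64)


def generate_truth(cfg: SimConfig) -> SimTruth:
    """Generate genome, gene models, CGIs, truth methylome and SNP table."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_genes, rng_meth, rng_snp = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    gc = cfg.gc_content
    p_bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    p_cgi = [0.15, 0.35, 0.35, 0.15]

    chroms = list(cfg.chrom_lengths)
    genome: dict[str, np.ndarray] = {}
    cgi_rows = []
    total_len = sum(cfg.chrom_lengths.values())
    for chrom in chroms:
        L = cfg.chrom_lengths[chrom]
        seq = rng_genome.choice(4, size=L, p=p_bg).astype(np.uint8)
        n_cgi = max(1, round(cfg.n_cgis * L / total_len))
        iv = _place_cgis(rng_genome, L, n_cgi, cfg.cgi_length_bp)
        for s, e in iv:
            seq[s:e] = rng_genome.choice(4, size=e - s, p=p_cgi).astype(np.uint8)
            cgi_rows.append((chrom, int(s), int(e)))
        genome[chrom] = seq
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])

    # gene models
    if cfg.genes_per_chrom is not None:
        counts = dict(cfg.genes_per_chrom)
    else:
        props = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
        alloc = rng_genes.multinomial(cfg.n_genes, props / props.sum())
        counts = dict(zip(chroms, alloc))
    gene_rows = []
    gid = 0
    for chrom in chroms:
        L = cfg.chrom_lengths[chrom]
        for _ in range(int(counts.get(chrom, 0))):
            glen = int(rng_genes.integers(2000, 8000))
            lo = 1500
            hi = max(lo + 1, L - glen - 1500)
            start = int(rng_genes.integers(lo, hi))
            strand = "+" if rng_genes.random() < 0.5 else "-"
            if strand == "+":
                tss, tts = start, start + glen - 1
            else:
                tss, tts = start + glen - 1, start
            exlen = int(np.clip(rng_genes.lognormal(np.log(cfg.exonic_length_bp), 0.6), 200, glen))
            gene_rows.append((f"G{gid:05d}", chrom, strand, tss, tts, exlen))
            gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "tss", "tts", "exonic_length_bp"]
    )

    # CpG dinucleotides and their truth methylation
    w0, w1, wp = cfg.meth_weights
    wsum = w0 + w1 + wp
    weights = np.array([w0, w1, wp]) / wsum
    conc = cfg.meth_concentration
    meth_rows = []
    snp_rows = []
    for chrom in chroms:
        seq = genome[chrom]
        cpg = np.nonzero((seq[:-1] == C) & (seq[1:] == G))[0]
        n = len(cpg)
        if n == 0:
            continue
        comp = rng_meth.choice(3, size=n, p=weights)
        # promoter CpGs overlapping a CGI are overwhelmingly unmethylated
        prom_iv = _regions.merge_intervals(
            _regions.clip_intervals(
                np.array(
                    [_regions.promoter_interval(int(g.tss), g.strand)
                     for g in genes[genes.chrom == chrom].itertuples()],
                    dtype=np.int64,
                ).reshape(-1, 2),
                cfg.chrom_lengths[chrom],
            )
        )
        cgi_iv = _regions.merge_intervals(
            cgis[cgis.chrom == chrom][["start", "end"]].to_numpy(dtype=np.int64)
        )
        in_prom = _regions._stab(prom_iv, cpg)
        in_cgi = _regions._stab(cgi_iv, cpg)
        pc = in_prom & in_cgi
        if pc.any():
            comp[pc] = rng_meth.choice(3, size=int(pc.sum()), p=[0.90, 0.02, 0.08])
        m = np.empty(n)
        for ci, draw in (
            (0, lambda k: rng_meth.beta(1.0, conc, size=k)),
            (1, lambda k: rng_meth.beta(conc, 1.0, size=k)),
            (2, lambda k: rng_meth.beta(2.0, 2.0, size=k)),
        ):
            sel = comp == ci
            m[sel] = draw(int(sel.sum()))
        # spike hypermethylation into the case group at promoter CpGs
        spiked = np.zeros(n, dtype=bool)
        if cfg.spike_fraction > 0:
            cand = np.nonzero(in_prom)[0]
            pick = cand[rng_meth.random(len(cand)) < cfg.spike_fraction]
            spiked[pick] = True
        p_control = m
        p_case = np.where(spiked, np.clip(m + cfg.spike_delta, 0.0, 1.0), m)
        # heterozygous CpG-destroying SNPs
        if cfg.snp_rate > 0:
            hit = np.nonzero(rng_snp.random(n) < cfg.snp_rate)[0]
            for i in hit:
                pos = int(cpg[i])
                if rng_snp.random() < 0.5:
                    snp_rows.append((chrom, pos, "C", "T", pos))
                else:
                    snp_rows.append((chrom, pos + 1, "G", "A", pos))
        for strand, offset in (("+", 0), ("-", 1)):
            meth_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": cpg + offset,
                        "strand": strand,
                        "p_control": p_control,
                        "p_case": p_case,
                        "spiked": spiked,
                    }
                )
            )
    methylome = (
        pd.concat(meth_rows, ignore_index=True)
        .sort_values(["chrom", "pos0", "strand"], kind="stable")
        .reset_index(drop=True)
    )
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos0", "ref", "alt", "cpg_pos"])
    return SimTruth(cfg=cfg, genome=genome, genes=genes, cgis=cgis,
                    methylome=methylome, snps=snps)


# ---------------------------------------------------------------------------
# In-silico restriction digestion
# ---------------------------------------------------------------------------

_MSPI = np.array([C, C, G, G], dtype=np.uint8)   # C^CGG
_TAQI = np.array([T, C, G, A], dtype=np.uint8)   # T^CGA


def _site_starts(seq: np.ndarray, motif: np.ndarray) -> np.ndarray:
    if len(seq) < 4:
        return np.empty(0, dtype=np.int64)
    m = np.ones(len(seq) - 3, dtype=bool)
    for j, b in enumerate(motif):
        m &= seq[j : j + len(seq) - 3] == b
    return np.nonzero(m)[0].astype(np.int64)


def digest_rrbs(genome: Mapping[str, np.ndarray], cfg: SimConfig) -> pd.DataFrame:
    """Complete double digestion (MspI C^CGG, TaqaI T^CGA) with hard
    size selection into the configured windows.

    Cuts fall after the first base of each recognition site on the
    forward strand (both motifs are their own reverse complements, so a
    forward scan finds every site).  Fragments between consecutive cuts
    are retained when their length falls inside a window.
    """
    rows = []
    for chrom, seq in genome.items():
        if isinstance(seq, str):
            seq = seqs.encode(seq)
        msp = _site_starts(seq, _MSPI) + 1
        taq = _site_starts(seq, _TAQI) + 1
        cuts = np.concatenate([msp, taq])
        labels = np.array(["MspI"] * len(msp) + ["TaqaI"] * len(taq), dtype=object)
        order = np.argsort(cuts, kind="stable")
        cuts, labels = cuts[order], labels[order]
        bounds = np.concatenate([[0], cuts, [len(seq)]])
        blabels = np.concatenate([["chrom_end"], labels, ["chrom_end"]])
        lens = np.diff(bounds)
        keep = np.zeros(len(lens), dtype=bool)
        for lo, hi in cfg.fragment_windows:
            keep |= (lens >= lo) & (lens <= hi)
        for i in np.nonzero(keep)[0]:
            rows.append(
                (chrom, int(bounds[i]), int(bounds[i + 1]),
                 blabels[i], blabels[i + 1], int(lens[i]))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cutter_at_start", "cutter_at_end", "length"]
    )


# ---------------------------------------------------------------------------
# Bisulfite read simulation
# ---------------------------------------------------------------------------

def _phred_value(error_rate: float) -> int:
    if error_rate <= 1e-4:
        return 40
    return int(round(-10.0 * np.log10(error_rate)))


def simulate_bisulfite_reads(
    fragments: pd.DataFrame,
    truth: SimTruth,
    sample_id: str,
    group: str,
    cfg: SimConfig,
    seed: int | Sequence[int] = 0,
) -> ReadBatch:
    """Simulate 2 x read_length paired-end bisulfite reads for one sample.

    Each sampled molecule comes from either original strand of a
    fragment (mate 1 from the molecule's 5' end, mate 2 the reverse
    complement of its 3' end).  Methylation states are per-molecule
    Bernoulli draws from the sample group's truth probability;
    unmethylated cytosines convert to T with the configured efficiency;
    methylated cytosines never convert.  Base errors are independent
    substitutions and quality strings encode the simulated error rate.
    """
    if group not in ("control", "case"):
        raise ValueError("group must be 'control' or 'case'")
    rng = np.random.default_rng(seed)
    rl = cfg.read_length
    pcol = "p_control" if group == "control" else "p_case"

    # per-chromosome lookups: strand-specific site positions and probabilities
    site_lookup: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for chrom, sub in truth.methylome.groupby("chrom"):
        d = {}
        for strand, ssub in sub.groupby("strand"):
            d[strand] = (
                ssub.pos0.to_numpy(dtype=np.int64),
                ssub[pcol].to_numpy(dtype=np.float64),
            )
        site_lookup[chrom] = d
    snp_lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(truth.snps):
        for chrom, sub in truth.snps.groupby("chrom"):
            alt_codes = np.array([seqs.encode(a)[0] for a in sub.alt], dtype=np.uint8)
            snp_lookup[chrom] = (sub.pos0.to_numpy(dtype=np.int64), alt_codes)

    mate1_parts: list[np.ndarray] = []
    mate2_parts: list[np.ndarray] = []
    meta: list[tuple] = []

    for frag in fragments.itertuples():
        L = frag.end - frag.start
        if L < rl:
            log.warning("fragment %s:%d-%d shorter than read length, skipped",
                        frag.chrom, frag.start, frag.end)
            continue
        n_pairs = int(rng.poisson(2 * cfg.target_depth))
        if n_pairs == 0:
            continue
        seq = truth.genome[frag.chrom][frag.start : frag.end]
        top = rng.random(n_pairs) < 0.5
        hap_alt = np.zeros(n_pairs, dtype=bool)
        mol_fwd = np.broadcast_to(seq, (n_pairs, L)).copy()
        if frag.chrom in snp_lookup:
            spos, salt = snp_lookup[frag.chrom]
            inside = (spos >= frag.start) & (spos < frag.end)
            if inside.any():
                hap_alt = rng.random(n_pairs) < 0.5
                for p, a in zip(spos[inside], salt[inside]):
                    mol_fwd[hap_alt, p - frag.start] = a

        for is_top in (True, False):
            rows = np.nonzero(top == is_top)[0]
            if len(rows) == 0:
                continue
            if is_top:
                mol = mol_fwd[rows]
                strand = "+"
            else:
                mol = seqs.revcomp(mol_fwd[rows])
                strand = "-"
            nr, _ = mol.shape
            # methylation protection at this strand's CpG cytosines
            lk = site_lookup.get(frag.chrom, {}).get(strand)
            protect = np.zeros_like(mol, dtype=bool)
            if lk is not None:
                pos, prob = lk
                inside = (pos >= frag.start) & (pos < frag.end)
                if inside.any():
                    offs = pos[inside] - frag.start
                    if not is_top:
                        offs = (L - 1) - offs
                    states = rng.random((nr, len(offs))) < prob[inside]
                    protect[:, offs] = states
            is_c = mol == C
            convert = is_c & ~protect & (rng.random(mol.shape) < cfg.conversion_efficiency)
            mol = mol.copy()
            mol[convert] = T
            mate1_parts.append(mol[:, :rl])
            mate2_parts.append(seqs.revcomp(mol[:, L - rl :]))
            for ri in rows:
                meta.append((frag.chrom, frag.start, frag.end, strand, bool(hap_alt[ri])))

    if not mate1_parts:
        empty = np.empty((0, rl), dtype=np.uint8)
        return ReadBatch(sample_id, group, [], empty, empty.copy(), empty.copy(),
                         empty.copy(), pd.DataFrame(
                             columns=["read", "chrom", "frag_start", "frag_end", "strand", "hap_alt"]))

    r1 = np.ascontiguousarray(np.vstack(mate1_parts))
    r2 = np.ascontiguousarray(np.vstack(mate2_parts))
    # sequencing errors: uniform substitution among the 3 alternatives
    if cfg.base_error_rate > 0:
        for mat in (r1, r2):
            err = rng.random(mat.shape) < cfg.base_error_rate
            k = int(err.sum())
            if k:
                mat[err] = (mat[err] + 1 + rng.integers(0, 3, size=k).astype(np.uint8)) % 4
    q = _phred_value(cfg.base_error_rate)
    q1 = np.full_like(r1, q)
    q2 = np.full_like(r2, q)
    names = [
        f"{sample_id}|{m[0]}|{m[1]}|{m[2]}|{m[3]}|{i}" for i, m in enumerate(meta)
    ]
    sidecar = pd.DataFrame(meta, columns=["chrom", "frag_start", "frag_end", "strand", "hap_alt"])
    sidecar.insert(0, "read", names)
    return ReadBatch(sample_id, group, names, r1, q1, r2, q2, sidecar)


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def simulate_expression_counts(
    genes: pd.DataFrame,
    cfg: SimConfig,
    group: str,
    seed: int | Sequence[int] = 0,
) -> pd.DataFrame:
    """Gene x sample read-count table with a trisomic dosage effect.

    Per-gene abundances are drawn once from the config seed (shared by
    both groups); expected counts scale with abundance and exonic
    length; case-group genes on the trisomic surrogate are multiplied
    by ``trisomy_expression_factor``; counts are negative-binomial with
    shape ``expression_nb_shape`` plus mild library-size variation.
    """
    if group not in ("control", "case"):
        raise ValueError("group must be 'control' or 'case'")
    if len(genes) == 0:
        raise ValueError("genes must be non-empty")
    abund_rng = np.random.default_rng([cfg.seed, 915_001])
    abund = abund_rng.lognormal(0.0, 0.8, size=len(genes))
    abund /= abund.mean()
    rng = np.random.default_rng(seed)
    n_samples = cfg.n_case_rna if group == "case" else cfg.n_control_rna
    lengths = genes.exonic_length_bp.to_numpy(dtype=np.float64)
    mu = cfg.expression_mean_count * abund * lengths / cfg.exonic_length_bp
    if group == "case":
        tri = (genes.chrom == cfg.trisomic_chrom).to_numpy()
        mu = np.where(tri, mu * cfg.trisomy_expression_factor, mu)
    lib = rng.lognormal(0.0, 0.10, size=n_samples)
    r = cfg.expression_nb_shape
    mu_mat = mu[:, None] * lib[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = r / (r + mu_mat)
    counts = np.where(mu_mat > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    cols = [f"{group}_{i + 1}" for i in range(n_samples)]
    out = pd.DataFrame(counts, columns=cols)
    out.insert(0, "gene_id", genes.gene_id.to_numpy())
    return out
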
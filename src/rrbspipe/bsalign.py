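"""Three-letter bisulfite read processing: quality filtering, in-silico
read conversion, dual converted-genome alignment, methylation calling,
conversion-rate estimation and polymorphic-CpG exclusion.

Alignment model
---------------
Two reference genomes are built from the input genome: one with every
cytosine converted to thymine (C2T) and one with every guanine
converted to adenosine (G2A).  Each read is converted in silico
according to its C/G base-count ratio (fewer Cs than Gs -> C -> T;
fewer Gs -> G -> A; a tie is ambiguous and both conversions are tried)
and aligned against *both* converted genomes: a C2T-class read is
searched forward in the C2T genome and reverse-complemented in the G2A
genome, and symmetrically for G2A-class reads.  Candidate loci come
from exact 16-mer seeds (offsets 0 and 16), verified by full ungapped
comparison in converted space; a read is reported only when a single
best hit (by mismatch count, <= ``max_mismatches``) exists across both
references.

Methylation calling reads the *original* (unconverted) bases back over
the reference: on C2T alignments a C over a forward-strand CpG cytosine
is methylated and a T unmethylated; G2A alignments mirror this with G/A
over reverse-strand CpG cytosines.  Forward- and reverse-strand CpG
sites are never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import seqs
from .seqs import A, C, G, N, T, KmerIndex, expand_ranges

log = logging.getLogger(__name__)

_GAP = 50  # run of Ns separating chromosomes in the concatenated genome


class AlignmentError(ValueError):
    pass


@dataclass
class ConvertedGenomePair:
    """Concatenated original + C2T + G2A genomes with seed indexes."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    offsets: dict[str, int]
    fwd: np.ndarray
    c2t: np.ndarray
    g2a: np.ndarray
    idx_c2t: KmerIndex
    idx_g2a: KmerIndex
    fwd_cpg_c: np.ndarray = field(repr=False)   # C of a forward-strand CpG
    rev_cpg_g: np.ndarray = field(repr=False)   # G of a reverse-strand CpG
    noncpg_c: np.ndarray = field(repr=False)
    noncpg_g: np.ndarray = field(repr=False)

    def global_to_chrom(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated positions to (chrom index, local position)."""
        starts = np.array([self.offsets[c] for c in self.chrom_names])
        ci = np.searchsorted(starts, gpos, side="right") - 1
        return ci, gpos - starts[ci]


def build_converted_genomes(genome: Mapping[str, np.ndarray | str], k: int = 16) -> ConvertedGenomePair:
    """Build the C2T/G2A reference pair and their k-mer seed indexes."""
    if not genome:
        raise AlignmentError("genome is empty")
    names = list(genome)
    parts = []
    offsets = {}
    lengths = {}
    cur = 0
    gap = np.full(_GAP, N, dtype=np.uint8)
    for name in names:
        seq = genome[name]
        if isinstance(seq, str):
            seq = seqs.encode(seq)
        offsets[name] = cur
        lengths[name] = len(seq)
        parts.append(seq.astype(np.uint8))
        parts.append(gap)
        cur += len(seq) + _GAP
    fwd = np.concatenate(parts)
    c2t = seqs.c2t(fwd)
    g2a = seqs.g2a(fwd)
    is_c = fwd == C
    is_g = fwd == G
    next_g = np.zeros_like(is_c)
    next_g[:-1] = is_g[1:]
    prev_c = np.zeros_like(is_c)
    prev_c[1:] = is_c[:-1]
    fwd_cpg_c = is_c & next_g
    rev_cpg_g = is_g & prev_c
    return ConvertedGenomePair(
        chrom_names=names,
        chrom_lengths=lengths,
        offsets=offsets,
        fwd=fwd,
        c2t=c2t,
        g2a=g2a,
        idx_c2t=KmerIndex(c2t, k=k),
        idx_g2a=KmerIndex(g2a, k=k),
        fwd_cpg_c=fwd_cpg_c,
        rev_cpg_g=rev_cpg_g,
        noncpg_c=is_c & ~fwd_cpg_c,
        noncpg_g=is_g & ~rev_cpg_g,
    )


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def quality_filter(
    quals: np.ndarray, q_cutoff: int = 30, max_masked_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Mask bases below the Phred cutoff; drop reads mostly masked.

    ``quals`` is an (n, L) integer array of Phred values.  Returns
    (base_keep_mask, read_keep): bases with quality < ``q_cutoff`` are
    excluded from methylation evidence, and a read is dropped when more
    than ``max_masked_fraction`` of its bases are masked.
    """
    quals = np.atleast_2d(np.asarray(quals))
    base_keep = quals >= q_cutoff
    masked_frac = 1.0 - base_keep.mean(axis=1)
    read_keep = masked_frac <= max_masked_fraction
    return base_keep, read_keep


def parse_phred33(qual_string: str) -> np.ndarray:
    q = np.frombuffer(qual_string.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if (q < 0).any() or (q > 60).any():
        raise AlignmentError("malformed Phred+33 quality string")
    return q


def quality_filter_pair(
    qual1: str, qual2: str, q_cutoff: int = 30
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Spec-level convenience for a single read pair with Phred+33 strings."""
    q1, q2 = parse_phred33(qual1), parse_phred33(qual2)
    m1, k1 = quality_filter(q1, q_cutoff)
    m2, k2 = quality_filter(q2, q_cutoff)
    return bool(k1[0] and k2[0]), m1[0], m2[0]


# ---------------------------------------------------------------------------
# In-silico read conversion
# ---------------------------------------------------------------------------

CLS_C2T, CLS_G2A, CLS_AMBIG = 0, 1, 2
_CLS_NAMES = {CLS_C2T: "C2T", CLS_G2A: "G2A", CLS_AMBIG: "ambiguous"}


def classify_reads(reads: np.ndarray) -> np.ndarray:
    """Conversion class per read from the C/G base-count ratio."""
    reads = np.atleast_2d(reads)
    nc = (reads == C).sum(axis=1)
    ng = (reads == G).sum(axis=1)
    cls = np.full(len(reads), CLS_AMBIG, dtype=np.int8)
    cls[nc < ng] = CLS_C2T
    cls[ng < nc] = CLS_G2A
    return cls


def convert_read(bases: str) -> tuple[str | tuple[str, str], str]:
    """Convert one read in silico based on its C/G base counts.

    Fewer Cs than Gs: every C becomes T (class "C2T"); fewer Gs: every
    G becomes A ("G2A"); a tie yields both candidates ("ambiguous").
    """
    arr = seqs.encode(bases)
    cls = classify_reads(arr[None, :])[0]
    if cls == CLS_C2T:
        return seqs.decode(seqs.c2t(arr)), "C2T"
    if cls == CLS_G2A:
        return seqs.decode(seqs.g2a(arr)), "G2A"
    return (seqs.decode(seqs.c2t(arr)), seqs.decode(seqs.g2a(arr))), "ambiguous"


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSet:
    """Unique-best alignments for a batch of reads (parallel arrays)."""

    read_idx: np.ndarray    # row in the input read matrix
    gpos: np.ndarray        # start in concatenated-genome coordinates
    ref: np.ndarray         # 0 = C2T reference, 1 = G2A reference
    orient: np.ndarray      # +1 read as given, -1 reverse-complemented
    mismatches: np.ndarray

    def __len__(self) -> int:
        return len(self.read_idx)


def _candidates(query: np.ndarray, rows: np.ndarray, index: KmerIndex,
                ref_seq: np.ndarray, max_mm: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-and-verify one query set; returns (rows, gpos, mismatches)."""
    n, L = query.shape
    if n == 0:
        return (np.empty(0, np.int64),) * 3
    k = index.k
    cand_rows = []
    cand_pos = []
    for off in (0, k):
        if off + k > L:
            break
        h, valid = index.hash_queries(query[:, off : off + k])
        lo, hi = index.lookup(h)
        lo[~valid] = hi[~valid] = 0
        owners, flat = expand_ranges(lo, hi)
        if len(owners) == 0:
            continue
        pos = index.positions[flat] - off
        ok = pos >= 0
        cand_rows.append(owners[ok])
        cand_pos.append(pos[ok])
    if not cand_rows:
        return (np.empty(0, np.int64),) * 3
    owners = np.concatenate(cand_rows)
    pos = np.concatenate(cand_pos)
    # dedupe identical (read, pos) found via both seeds
    key = owners * np.int64(len(ref_seq) + 1) + pos
    _, uniq = np.unique(key, return_index=True)
    owners, pos = owners[uniq], pos[uniq]
    windows = ref_seq[pos[:, None] + np.arange(L)]
    mm = (windows != query[owners]).sum(axis=1)
    keep = mm <= max_mm
    return rows[owners[keep]], pos[keep], mm[keep].astype(np.int64)


def align_batch(
    reads: np.ndarray,
    genomes: ConvertedGenomePair,
    max_mismatches: int = 2,
) -> AlignmentSet:
    """Align a batch of reads against both converted genomes.

    Only reads with a unique best hit (smallest mismatch count across
    both references and orientations) are reported; ambiguous reads
    contribute nothing downstream.
    """
    reads = np.atleast_2d(reads)
    n, L = reads.shape
    if len(genomes.fwd) < L + _GAP:
        raise AlignmentError("genome shorter than read length")
    cls = classify_reads(reads)
    rc = seqs.revcomp(reads)
    all_rows, all_pos, all_mm, all_ref, all_orient = [], [], [], [], []
    for want, mat, index, ref_seq, ref_id, orient in (
        ((CLS_C2T, CLS_AMBIG), seqs.c2t(reads), genomes.idx_c2t, genomes.c2t, 0, 1),
        ((CLS_C2T, CLS_AMBIG), seqs.g2a(rc), genomes.idx_g2a, genomes.g2a, 1, -1),
        ((CLS_G2A, CLS_AMBIG), seqs.g2a(reads), genomes.idx_g2a, genomes.g2a, 1, 1),
        ((CLS_G2A, CLS_AMBIG), seqs.c2t(rc), genomes.idx_c2t, genomes.c2t, 0, -1),
    ):
        rows = np.nonzero(np.isin(cls, want))[0]
        r, p, mm = _candidates(mat[rows], rows, index, ref_seq, max_mismatches)
        all_rows.append(r)
        all_pos.append(p)
        all_mm.append(mm)
        all_ref.append(np.full(len(r), ref_id, dtype=np.int8))
        all_orient.append(np.full(len(r), orient, dtype=np.int8))
    rows = np.concatenate(all_rows)
    pos = np.concatenate(all_pos)
    mm = np.concatenate(all_mm)
    ref = np.concatenate(all_ref)
    orient = np.concatenate(all_orient)
    if len(rows) == 0:
        return AlignmentSet(*(np.empty(0, np.int64) for _ in range(5)))
    # unique best hit per read across both references
    order = np.lexsort((mm, rows))
    rows, pos, mm, ref, orient = (a[order] for a in (rows, pos, mm, ref, orient))
    first = np.ones(len(rows), dtype=bool)
    first[1:] = rows[1:] != rows[:-1]
    starts = np.nonzero(first)[0]
    best_mm = mm[starts]
    # count hits at the best mismatch level per read
    group_id = np.cumsum(first) - 1
    at_best = mm == best_mm[group_id]
    n_best = np.bincount(group_id[at_best])
    unique_best = n_best == 1
    keep = first & unique_best[group_id]
    return AlignmentSet(
        read_idx=rows[keep],
        gpos=pos[keep],
        ref=ref[keep].astype(np.int8),
        orient=orient[keep].astype(np.int8),
        mismatches=mm[keep],
    )


def align_read(
    read: str, genomes: ConvertedGenomePair, max_mismatches: int = 2
) -> dict | None:
    """Align a single read; returns a record dict or None when unmapped."""
    aln = align_batch(seqs.encode(read)[None, :], genomes, max_mismatches)
    if len(aln) == 0:
        return None
    ci, local = genomes.global_to_chrom(aln.gpos)
    return {
        "chrom": genomes.chrom_names[int(ci[0])],
        "pos0": int(local[0]),
        "ref": "C2T" if aln.ref[0] == 0 else "G2A",
        "orient": int(aln.orient[0]),
        "mismatches": int(aln.mismatches[0]),
    }


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------

@dataclass
class EvidenceTally:
    """Per-genome-position evidence accumulated over aligned reads."""

    glen: int
    meth_f: np.ndarray
    unmeth_f: np.ndarray
    other_f: np.ndarray
    meth_r: np.ndarray
    unmeth_r: np.ndarray
    other_r: np.ndarray
    dinuc_other_f: np.ndarray
    dinuc_total_f: np.ndarray
    dinuc_other_r: np.ndarray
    dinuc_total_r: np.ndarray
    conv_converted: int = 0
    conv_unconverted: int = 0


def _bincount_into(target: np.ndarray, positions: np.ndarray) -> None:
    if len(positions):
        target += np.bincount(positions, minlength=len(target)).astype(target.dtype)


def tally_evidence(
    aln: AlignmentSet,
    reads: np.ndarray,
    base_mask: np.ndarray | None,
    genomes: ConvertedGenomePair,
    pair_ids: np.ndarray | None = None,
    mate_no: np.ndarray | None = None,
) -> EvidenceTally:
    """Accumulate methylation / dinucleotide / conversion evidence.

    ``base_mask`` marks bases retained by the quality filter.  When
    ``pair_ids``/``mate_no`` are given, overlapping mate pairs are
    resolved in favour of mate 1 (mate 2's overlapping bases are
    dropped) so overlapping bases are never double-counted.
    """
    reads = np.atleast_2d(reads)
    n, L = reads.shape
    glen = len(genomes.fwd)
    t = EvidenceTally(
        glen=glen,
        **{k: np.zeros(glen, dtype=np.int32) for k in
           ("meth_f", "unmeth_f", "other_f", "meth_r", "unmeth_r", "other_r",
            "dinuc_other_f", "dinuc_total_f", "dinuc_other_r", "dinuc_total_r")},
    )
    if len(aln) == 0:
        return t
    if base_mask is None:
        base_mask = np.ones_like(reads, dtype=bool)
    # forward-coordinate bases and masks per alignment
    fb = np.where(
        (aln.orient == 1)[:, None], reads[aln.read_idx], seqs.revcomp(reads[aln.read_idx])
    )
    fm = np.where(
        (aln.orient == 1)[:, None],
        base_mask[aln.read_idx],
        base_mask[aln.read_idx][:, ::-1],
    )
    # mate-overlap: drop mate-2 bases overlapping its mate-1 interval
    if pair_ids is not None and mate_no is not None:
        df = pd.DataFrame(
            {
                "row": np.arange(len(aln)),
                "pid": pair_ids[aln.read_idx],
                "mate": mate_no[aln.read_idx],
                "gpos": aln.gpos,
            }
        )
        m1 = df[df.mate == 1].set_index("pid")
        m2 = df[df.mate == 2]
        joined = m2.join(m1, on="pid", rsuffix="_1", how="inner")
        ov = joined[np.abs(joined.gpos - joined.gpos_1) < L]
        for r in ov.itertuples():
            lo = max(int(r.gpos), int(r.gpos_1))
            hi = min(int(r.gpos), int(r.gpos_1)) + L
            cols = np.arange(lo - int(r.gpos), hi - int(r.gpos))
            fm[int(r.row), cols] = False

    P = aln.gpos[:, None] + np.arange(L)
    for ref_id, cpg_mask, meth_base, unmeth_base, (meth_a, unmeth_a, other_a), \
        (din_oth, din_tot), noncpg_mask, conv_base, unconv_base, nb_shift in (
        (0, genomes.fwd_cpg_c, C, T, (t.meth_f, t.unmeth_f, t.other_f),
         (t.dinuc_other_f, t.dinuc_total_f), genomes.noncpg_c, T, C, 1),
        (1, genomes.rev_cpg_g, G, A, (t.meth_r, t.unmeth_r, t.other_r),
         (t.dinuc_other_r, t.dinuc_total_r), genomes.noncpg_g, A, G, -1),
    ):
        rowsel = aln.ref == ref_id
        if not rowsel.any():
            continue
        Pr = P[rowsel]
        b = fb[rowsel]
        m = fm[rowsel]
        sel = cpg_mask[Pr] & m
        _bincount_into(meth_a, Pr[sel & (b == meth_base)])
        _bincount_into(unmeth_a, Pr[sel & (b == unmeth_base)])
        _bincount_into(other_a, Pr[sel & (b != meth_base) & (b != unmeth_base)])
        # dinucleotide check: the CpG's partner base within the read
        if nb_shift == 1:
            nb = np.full_like(b, N)
            nb[:, :-1] = b[:, 1:]
            nm = np.zeros_like(m)
            nm[:, :-1] = m[:, 1:]
            partner_ok = nb == G
        else:
            nb = np.full_like(b, N)
            nb[:, 1:] = b[:, :-1]
            nm = np.zeros_like(m)
            nm[:, 1:] = m[:, :-1]
            partner_ok = nb == C
        dsel = sel & nm
        good = dsel & ((b == meth_base) | (b == unmeth_base)) & partner_ok
        _bincount_into(din_tot, Pr[dsel])
        _bincount_into(din_oth, Pr[dsel & ~good])
        # conversion-rate evidence from non-CpG cytosines
        csel = noncpg_mask[Pr] & m
        t.conv_converted += int((csel & (b == conv_base)).sum())
        t.conv_unconverted += int((csel & (b == unconv_base)).sum())
    return t


def call_methylation(
    aln: AlignmentSet,
    reads: np.ndarray,
    base_mask: np.ndarray | None,
    genomes: ConvertedGenomePair,
    pair_ids: np.ndarray | None = None,
    mate_no: np.ndarray | None = None,
) -> tuple[pd.DataFrame, EvidenceTally]:
    """Build the per-sample strand-specific CpG methylation table.

    Returns (methylome, tally).  The methylome has one row per covered
    strand-specific CpG site: chrom, pos0, strand, meth_count,
    unmeth_count, other_count, dinuc_other, dinuc_total, level.
    """
    t = tally_evidence(aln, reads, base_mask, genomes, pair_ids, mate_no)
    frames = []
    for strand, meth, unmeth, other, din_o, din_t in (
        ("+", t.meth_f, t.unmeth_f, t.other_f, t.dinuc_other_f, t.dinuc_total_f),
        ("-", t.meth_r, t.unmeth_r, t.other_r, t.dinuc_other_r, t.dinuc_total_r),
    ):
        covered = np.nonzero(meth + unmeth + other)[0]
        if len(covered) == 0:
            continue
        ci, local = genomes.global_to_chrom(covered)
        depth = meth[covered] + unmeth[covered]
        with np.errstate(invalid="ignore"):
            level = np.where(depth > 0, meth[covered] / np.maximum(depth, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": np.array(genomes.chrom_names, dtype=object)[ci],
                    "pos0": local,
                    "strand": strand,
                    "meth_count": meth[covered],
                    "unmeth_count": unmeth[covered],
                    "other_count": other[covered],
                    "dinuc_other": din_o[covered],
                    "dinuc_total": din_t[covered],
                    "level": level,
                }
            )
        )
    if frames:
        meth_df = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["chrom", "pos0", "strand"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        meth_df = pd.DataFrame(
            columns=["chrom", "pos0", "strand", "meth_count", "unmeth_count",
                     "other_count", "dinuc_other", "dinuc_total", "level"]
        )
    return meth_df, t


def conversion_rate(tally: EvidenceTally) -> float:
    """Bisulfite conversion rate from non-CpG cytosines:
    converted / (converted + unconverted)."""
    total = tally.conv_converted + tally.conv_unconverted
    if total == 0:
        raise AlignmentError("no non-CpG cytosine observations; conversion rate undefined")
    return tally.conv_converted / total


def filter_polymorphic_cpgs(
    methylome: pd.DataFrame, max_other_fraction: float = 0.20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude CpG sites whose reads show a dinucleotide other than
    CG or TG in more than ``max_other_fraction`` of covering reads
    (strict inequality; exactly 20% is retained).

    Returns (filtered methylome, excluded sites).
    """
    tot = methylome.dinuc_total.to_numpy(dtype=np.float64)
    oth = methylome.dinuc_other.to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, oth / np.maximum(tot, 1), 0.0)
    bad = frac > max_other_fraction
    return (
        methylome[~bad].reset_index(drop=True),
        methylome[bad].reset_index(drop=True),
    )
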
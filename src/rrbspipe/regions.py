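"""Genomic region derivation and CpG-site annotation.

Positional classes follow the study design this pipeline models:

* promoter: -1000 bp to +500 bp around the transcription start site,
  in transcription direction (half-open; a site exactly at +500 on the
  plus strand is not promoter);
* TTR (transcription termination region): -500 to +500 around the
  transcription termination site;
* intragenic: the gene span minus promoter/TTR;
* intergenic: everything else;
* CGI / CGI shore: CpG islands and their 2-kb flanks.

Overlaps between positional classes are resolved by the precedence
promoter > TTR > intragenic > intergenic.  All intervals are 0-based
half-open in forward-genome coordinates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

POSITIONAL_CLASSES = ("promoter", "TTR", "intragenic", "intergenic")
CGI_CLASSES = ("CGI", "CGI_shore", "other")


# ---------------------------------------------------------------------------
# Interval arithmetic (per-chromosome, tiny scales: plain sweeps suffice)
# ---------------------------------------------------------------------------

def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) intervals. iv: (n, 2) ints."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(iv, dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged interval arrays."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append([cur, min(bs, e)])
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append([cur, e])
    return np.asarray(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def complement_intervals(a: np.ndarray, length: int) -> np.ndarray:
    return subtract_intervals(np.array([[0, length]]), a)


def clip_intervals(iv: np.ndarray, length: int, label: str = "") -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64)
    if len(iv) == 0:
        return iv.reshape(0, 2)
    clipped = np.clip(iv, 0, length)
    if (clipped != iv).any() and label:
        log.info("clipped %d %s interval(s) at chromosome bounds", int((clipped != iv).any(axis=1).sum()), label)
    return clipped[clipped[:, 0] < clipped[:, 1]]


def _stab(iv: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of positions in merged intervals (vectorised stabbing)."""
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < iv[idx[ok], 1]
    return res


# ---------------------------------------------------------------------------
# Region derivation
# ---------------------------------------------------------------------------

def promoter_interval(tss: int, strand: str) -> tuple[int, int]:
    """Promoter [-1000, +500) around the TSS in transcription direction."""
    if strand == "+":
        return tss - 1000, tss + 500
    return tss - 500, tss + 1001


def ttr_interval(tts: int, strand: str) -> tuple[int, int]:
    """TTR [-500, +500) around the transcription termination site."""
    if strand == "+":
        return tts - 500, tts + 500
    return tts - 500, tts + 501


def gene_promoters(genes: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-gene promoter intervals (gene identity kept, no merging)."""
    rows = []
    for g in genes.itertuples():
        s, e = promoter_interval(int(g.tss), g.strand)
        L = chrom_lengths[g.chrom]
        s2, e2 = max(0, s), min(L, e)
        if s2 < e2:
            rows.append((g.chrom, s2, e2, "promoter", g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_class", "gene_id"])


def derive_regions(
    genes: pd.DataFrame,
    cgis: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Derive merged positional and CGI region classes.

    ``genes`` needs columns gene_id/chrom/strand/tss/tts; ``cgis`` needs
    chrom/start/end.  Returns one row per merged interval with a
    ``region_class`` column.
    """
    per_class: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for chrom, L in chrom_lengths.items():
        gsub = genes[genes.chrom == chrom]
        prom = []
        ttr = []
        spans = []
        for g in gsub.itertuples():
            prom.append(promoter_interval(int(g.tss), g.strand))
            ttr.append(ttr_interval(int(g.tts), g.strand))
            lo, hi = sorted((int(g.tss), int(g.tts)))
            spans.append((lo, hi + 1))
        prom = clip_intervals(np.array(prom, dtype=np.int64).reshape(-1, 2), L, "promoter")
        ttr = clip_intervals(np.array(ttr, dtype=np.int64).reshape(-1, 2), L, "TTR")
        spans = clip_intervals(np.array(spans, dtype=np.int64).reshape(-1, 2), L)
        prom_m = merge_intervals(prom)
        ttr_m = merge_intervals(ttr)
        span_m = merge_intervals(spans)
        intra = subtract_intervals(span_m, merge_intervals(np.vstack([prom_m, ttr_m]) if len(prom_m) + len(ttr_m) else np.empty((0, 2), np.int64)))
        genic_all = merge_intervals(np.vstack([span_m, prom_m, ttr_m]) if len(span_m) + len(prom_m) + len(ttr_m) else np.empty((0, 2), np.int64))
        inter = complement_intervals(genic_all, L)

        csub = cgis[cgis.chrom == chrom]
        cgi = merge_intervals(csub[["start", "end"]].to_numpy(dtype=np.int64))
        flanks = []
        for s, e in cgi:
            flanks.append((s - 2000, s))
            flanks.append((e, e + 2000))
        flanks = clip_intervals(np.array(flanks, dtype=np.int64).reshape(-1, 2), L)
        shores = subtract_intervals(merge_intervals(flanks), cgi)

        for cls, iv in (
            ("promoter", prom_m),
            ("TTR", ttr_m),
            ("intragenic", intra),
            ("intergenic", inter),
            ("CGI", cgi),
            ("CGI_shore", shores),
        ):
            for s, e in iv:
                rows.append((chrom, int(s), int(e), cls))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_class"])


def _class_intervals(regions: pd.DataFrame, chrom: str, cls: str) -> np.ndarray:
    sub = regions[(regions.chrom == chrom) & (regions.region_class == cls)]
    return merge_intervals(sub[["start", "end"]].to_numpy(dtype=np.int64))


def annotate_cpg_sites(sites: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Assign each strand-specific CpG site one positional class and one
    CGI class (precedence promoter > TTR > intragenic > intergenic and
    CGI > shore > other).

    ``sites`` needs columns chrom/pos0 (strand ignored for annotation).
    """
    out = sites.copy()
    pos_class = np.full(len(sites), "intergenic", dtype=object)
    cgi_class = np.full(len(sites), "other", dtype=object)
    for chrom in sites.chrom.unique():
        m = (sites.chrom == chrom).to_numpy()
        pos = sites.pos0.to_numpy(dtype=np.int64)[m]
        assigned = np.zeros(len(pos), dtype=bool)
        for cls in ("promoter", "TTR", "intragenic"):
            iv = _class_intervals(regions, chrom, cls)
            hit = _stab(iv, pos) & ~assigned
            idx = np.nonzero(m)[0][hit]
            pos_class[idx] = cls
            assigned |= hit
        cgi_hit = _stab(_class_intervals(regions, chrom, "CGI"), pos)
        shore_hit = _stab(_class_intervals(regions, chrom, "CGI_shore"), pos) & ~cgi_hit
        idx_all = np.nonzero(m)[0]
        cgi_class[idx_all[cgi_hit]] = "CGI"
        cgi_class[idx_all[shore_hit]] = "CGI_shore"
    out["positional_class"] = pos_class
    out["cgi_class"] = cgi_class
    return out


# ---------------------------------------------------------------------------
# Region-level aggregation
# ---------------------------------------------------------------------------

def _region_table(regions: pd.DataFrame, classes: Sequence[str] | None) -> pd.DataFrame:
    sub = regions if classes is None else regions[regions.region_class.isin(classes)]
    sub = sub.reset_index(drop=True).copy()
    if "gene_id" in sub.columns:
        ids = [
            g if isinstance(g, str) and g else f"{c}:{ch}:{s}-{e}"
            for ch, s, e, c, g in zip(sub.chrom, sub.start, sub.end, sub.region_class, sub.gene_id)
        ]
    else:
        ids = [f"{c}:{ch}:{s}-{e}" for ch, s, e, c in zip(sub.chrom, sub.start, sub.end, sub.region_class)]
    sub["region_id"] = ids
    return sub


def aggregate_region_methylation(
    methylomes: Mapping[str, pd.DataFrame],
    regions: pd.DataFrame,
    min_cpgs: int = 6,
    min_depth: int = 10,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample unweighted mean methylation per region.

    A region is reported for a sample only when it contains at least
    ``min_cpgs`` CpG sites with depth >= ``min_depth`` in that sample.
    Methylome tables are the bsalign output format (chrom, pos0, strand,
    meth_count, unmeth_count, level).
    """
    reg = _region_table(regions, classes)
    rows = []
    for sample_id, meth in methylomes.items():
        depth = meth.meth_count.to_numpy() + meth.unmeth_count.to_numpy()
        ok = depth >= min_depth
        sub = meth[ok]
        by_chrom = {c: g for c, g in sub.groupby("chrom")}
        for r in reg.itertuples():
            g = by_chrom.get(r.chrom)
            if g is None:
                continue
            pos = g.pos0.to_numpy(dtype=np.int64)
            sel = (pos >= r.start) & (pos < r.end)
            n = int(sel.sum())
            if n >= min_cpgs:
                rows.append(
                    (r.region_id, r.region_class, r.chrom, r.start, r.end, sample_id,
                     float(g.level.to_numpy()[sel].mean()), n)
                )
    return pd.DataFrame(
        rows,
        columns=["region_id", "region_class", "chrom", "start", "end",
                 "sample_id", "mean_level", "n_cpgs"],
    )


def coverage_summary(
    methylomes: Mapping[str, pd.DataFrame],
    regions: pd.DataFrame,
    min_cpgs: int = 3,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Per-sample counts of covered CpGs and covered regions.

    A CpG is covered at depth >= ``min_depth``; a region (CGI, shore or
    promoter) is covered when at least ``min_cpgs`` of its CpGs are.
    """
    classes = ("CGI", "CGI_shore", "promoter")
    totals = {c: int((regions.region_class == c).sum()) for c in classes}
    agg = aggregate_region_methylation(
        methylomes, regions, min_cpgs=min_cpgs, min_depth=min_depth, classes=classes
    )
    rows = []
    for sample_id, meth in methylomes.items():
        depth = meth.meth_count.to_numpy() + meth.unmeth_count.to_numpy()
        n_cpg = int((depth >= min_depth).sum())
        sub = agg[agg.sample_id == sample_id]
        rec = {"sample_id": sample_id, "covered_cpgs": n_cpg}
        for c in classes:
            n = int((sub.region_class == c).sum())
            rec[f"covered_{c}"] = n
            rec[f"fraction_{c}"] = n / totals[c] if totals[c] else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)
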
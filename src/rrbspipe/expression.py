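"""RPKM quantification, differential expression and integration of
promoter methylation with expression change.

Expression is quantified as RPKM = 1e9 * count / (total mapped reads *
exonic length in bp).  Group-average RPKM below 0.5 is floored at 0.5
before ratios are formed.  A gene is differentially expressed when the
pooled-count exact binomial test (case counts against the case share of
library size) survives BH < 0.01 and the floored average ratio is
>= 1.25 or <= 0.8.  Only genes with average RPKM >= 0.5 in at least one
group are considered.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

log = logging.getLogger(__name__)

RPKM_FLOOR = 0.5


class ExpressionError(ValueError):
    pass


def compute_rpkm(
    counts: pd.DataFrame,
    exonic_length_bp: pd.Series | Mapping[str, float],
    total_mapped_reads: pd.Series | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """RPKM = 1e9 * count / (total_mapped_reads * exonic_length_bp).

    ``counts`` is gene x sample with a ``gene_id`` column.  Totals
    default to per-sample column sums.
    """
    genes = counts.gene_id.to_numpy()
    mat = counts.drop(columns="gene_id")
    lengths = pd.Series(exonic_length_bp).reindex(genes).to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ExpressionError("every gene needs a positive exonic length")
    if total_mapped_reads is None:
        totals = mat.sum(axis=0).to_numpy(dtype=np.float64)
    else:
        totals = pd.Series(total_mapped_reads).reindex(mat.columns).to_numpy(dtype=np.float64)
    if np.any(totals <= 0):
        raise ExpressionError("total mapped reads must be positive")
    rpkm = 1e9 * mat.to_numpy(dtype=np.float64) / (totals[None, :] * lengths[:, None])
    out = pd.DataFrame(rpkm, columns=mat.columns)
    out.insert(0, "gene_id", genes)
    return out


def group_average_rpkm(
    rpkm: pd.DataFrame, samplesheet: pd.DataFrame, floor: float = RPKM_FLOOR
) -> pd.DataFrame:
    """Per-group mean RPKM with the reporting floor applied.

    Returns gene_id, avg_control, avg_case (unfloored) and
    floored_control/floored_case used for ratios.
    """
    ctrl = list(samplesheet[samplesheet.group == "control"].sample_id)
    case = list(samplesheet[samplesheet.group == "case"].sample_id)
    avg_c = rpkm[ctrl].mean(axis=1).to_numpy()
    avg_x = rpkm[case].mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "gene_id": rpkm.gene_id.to_numpy(),
            "avg_control": avg_c,
            "avg_case": avg_x,
            "floored_control": np.maximum(avg_c, floor),
            "floored_case": np.maximum(avg_x, floor),
        }
    )


def test_differential_expression(
    counts: pd.DataFrame,
    exonic_length_bp: pd.Series | Mapping[str, float],
    samplesheet: pd.DataFrame,
    alpha: float = 0.01,
    up_ratio: float = 1.25,
    down_ratio: float = 0.8,
) -> pd.DataFrame:
    """Pooled-count binomial differential-expression test.

    Per gene, the pooled case count x is tested against
    n = pooled case+control count with p0 = case library share; BH is
    applied across included genes (average RPKM >= 0.5 in at least one
    group); status is up/down/none from (bh_p, floored ratio).
    """
    ctrl = list(samplesheet[samplesheet.group == "control"].sample_id)
    case = list(samplesheet[samplesheet.group == "case"].sample_id)
    if not ctrl or not case:
        raise ExpressionError("need at least one sample per group")
    rpkm = compute_rpkm(counts, exonic_length_bp)
    avg = group_average_rpkm(rpkm, samplesheet)
    pooled_case = counts[case].sum(axis=1).to_numpy(dtype=np.int64)
    pooled_ctrl = counts[ctrl].sum(axis=1).to_numpy(dtype=np.int64)
    total_case = int(pooled_case.sum())
    total_ctrl = int(pooled_ctrl.sum())
    p0 = total_case / (total_case + total_ctrl)
    included = (avg.avg_control >= RPKM_FLOOR) | (avg.avg_case >= RPKM_FLOOR)
    pvals = np.ones(len(counts))
    for i in np.nonzero(included.to_numpy())[0]:
        n = int(pooled_case[i] + pooled_ctrl[i])
        if n == 0:
            continue
        pvals[i] = stats.exact_binomial_test(int(pooled_case[i]), n, p0).p_value
    ratio = avg.floored_case.to_numpy() / avg.floored_control.to_numpy()
    bh = np.full(len(counts), np.nan)
    inc_idx = np.nonzero(included.to_numpy())[0]
    if len(inc_idx):
        bh[inc_idx] = stats.bh_adjust(pvals[inc_idx]).adjusted
    status = np.full(len(counts), "none", dtype=object)
    sig = included.to_numpy() & (bh < alpha)
    status[sig & (ratio >= up_ratio)] = "up"
    status[sig & (ratio <= down_ratio)] = "down"
    return pd.DataFrame(
        {
            "gene_id": counts.gene_id.to_numpy(),
            "pooled_case": pooled_case,
            "pooled_control": pooled_ctrl,
            "avg_control": avg.avg_control,
            "avg_case": avg.avg_case,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "p": pvals,
            "bh_p": bh,
            "included": included.to_numpy(),
            "status": status,
        }
    )


def expression_change_summary(
    de: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    grid: Sequence[float] | None = None,
    ratio_mode: str = "mean_of_ratios",
) -> dict[str, dict]:
    """Per-gene-set log2-ratio density, mean percent change and shift test.

    ``ratio_mode`` selects how the average change is computed:
    ``mean_of_ratios`` (default) averages per-gene case/control ratios;
    ``ratio_of_means`` forms the ratio of group-mean floored averages.
    The shift test is a two-sided rank-sum of the set's log2 ratios
    against all other included genes; it degenerates (p = NaN) when the
    set spans all included genes.
    """
    if ratio_mode not in ("mean_of_ratios", "ratio_of_means"):
        raise ExpressionError("unknown ratio_mode")
    inc = de[de.included].reset_index(drop=True)
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 401)
    grid = np.asarray(grid, dtype=np.float64)
    out: dict[str, dict] = {}
    all_ids = set(inc.gene_id)
    for name, ids in gene_sets.items():
        sel = inc.gene_id.isin(set(ids)).to_numpy()
        sub = inc[sel]
        if len(sub) == 0:
            log.warning("gene set %r has no included genes", name)
            out[name] = {"n": 0, "mean_percent_change": np.nan,
                         "shift_p": np.nan, "density": None, "log2_ratios": np.array([])}
            continue
        if ratio_mode == "mean_of_ratios":
            mean_change = 100.0 * (float(sub.ratio.mean()) - 1.0)
        else:
            num = float(sub.avg_case.clip(lower=RPKM_FLOOR).mean())
            den = float(sub.avg_control.clip(lower=RPKM_FLOOR).mean())
            mean_change = 100.0 * (num / den - 1.0)
        rest = inc[~sel]
        if len(rest) == 0:
            shift_p = np.nan  # set covers every included gene: not applicable
        else:
            shift_p = stats.wilcoxon_rank_sum(
                sub.log2_ratio.to_numpy(), rest.log2_ratio.to_numpy()
            ).p_value
        dens = (
            stats.kde_density(sub.log2_ratio.to_numpy(), grid)
            if len(sub) >= 2 else None
        )
        out[name] = {
            "n": int(len(sub)),
            "mean_percent_change": mean_change,
            "shift_p": shift_p,
            "density": None if dens is None else pd.DataFrame({"x": grid, "density": dens}),
            "log2_ratios": sub.log2_ratio.to_numpy(),
        }
    return out


def hypermeth_expression_association(
    promoter_calls: pd.DataFrame,
    de: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Pair hypermethylated promoters with expression change.

    ``promoter_calls`` is a region-level differential table whose ``id``
    is the gene id (promoter regions keep gene identity).  Returns a
    per-gene table (baseline control methylation, log2 expression
    ratio) plus a summary with the Spearman rank correlation and the
    set's shift test against the included background.
    """
    hyper = promoter_calls[promoter_calls.call == "hyper"]
    inc = de[de.included]
    joined = hyper.merge(inc, left_on="id", right_on="gene_id", how="inner")
    if len(joined) == 0:
        log.warning("no hypermethylated promoters joinable to expressed genes")
        return (
            pd.DataFrame(columns=["gene_id", "baseline_methylation", "log2_ratio"]),
            {"n": 0, "spearman_rho": np.nan, "spearman_p": np.nan, "shift_p": np.nan},
        )
    table = pd.DataFrame(
        {
            "gene_id": joined.gene_id,
            "baseline_methylation": joined.mean_control,
            "log2_ratio": joined.log2_ratio,
        }
    )
    if len(table) >= 3:
        rho, rho_p = sps.spearmanr(table.baseline_methylation, table.log2_ratio)
    else:
        rho, rho_p = np.nan, np.nan
    rest = inc[~inc.gene_id.isin(set(table.gene_id))]
    shift_p = (
        stats.wilcoxon_rank_sum(table.log2_ratio.to_numpy(), rest.log2_ratio.to_numpy()).p_value
        if len(rest) else np.nan
    )
    summary = {
        "n": int(len(table)),
        "spearman_rho": float(rho) if rho == rho else np.nan,
        "spearman_p": float(rho_p) if rho_p == rho_p else np.nan,
        "shift_p": shift_p,
        "median_log2_ratio": float(table.log2_ratio.median()),
    }
    return table, summary
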
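"""Differential-methylation inference between case and control cohorts.

A CpG (or region) is called differentially methylated when the
case-minus-control difference of group mean levels is at least
``min_diff`` (0.10 of methylation fraction, i.e. 10 percentage points)
and the two-sided Wilcoxon rank-sum p-value across per-sample levels is
below ``alpha`` (0.05).  Sites must be covered at depth >= 10 in at
least 3 control and 6 case samples, and sex chromosomes are excluded.
No multiple-testing correction enters the call (a BH column is emitted
for users).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

log = logging.getLogger(__name__)

DEFAULT_EXCLUDED_CHROMS = ("chrX", "chrY", "X", "Y")


@dataclass
class CohortTable:
    """Site/region x sample methylation levels and depths plus metadata.

    ``sites`` carries one row per row of ``levels``/``depths`` (columns
    at least ``id`` and ``chrom``); ``samples`` has sample_id, group
    (control|case) and optionally sex.
    """

    sites: pd.DataFrame
    levels: pd.DataFrame
    depths: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        groups = set(self.samples.group)
        if not {"control", "case"} <= groups | {"control", "case"}:
            raise ValueError("sample groups must be control/case")
        if self.levels.shape != self.depths.shape:
            raise ValueError("levels and depths must be aligned")

    def sample_ids(self, group: str) -> list[str]:
        return list(self.samples[self.samples.group == group].sample_id)


def build_cohort(
    methylomes: Mapping[str, pd.DataFrame], samplesheet: pd.DataFrame
) -> CohortTable:
    """Assemble a cohort table from per-sample bsalign methylome tables."""
    levels = {}
    depths = {}
    for sid, meth in methylomes.items():
        idx = pd.MultiIndex.from_arrays([meth.chrom, meth.pos0, meth.strand])
        depth = meth.meth_count.to_numpy() + meth.unmeth_count.to_numpy()
        levels[sid] = pd.Series(meth.level.to_numpy(), index=idx)
        depths[sid] = pd.Series(depth, index=idx)
    lv = pd.DataFrame(levels)
    dp = pd.DataFrame(depths).reindex(lv.index).fillna(0).astype(np.int64)
    sites = pd.DataFrame(
        {
            "id": [f"{c}:{p}:{s}" for c, p, s in lv.index],
            "chrom": [c for c, _, _ in lv.index],
            "pos0": [p for _, p, _ in lv.index],
            "strand": [s for _, _, s in lv.index],
        }
    )
    lv = lv.reset_index(drop=True)
    dp = dp.reset_index(drop=True)
    return CohortTable(sites=sites, levels=lv, depths=dp,
                       samples=samplesheet.reset_index(drop=True))


def select_analyzable_cpgs(
    cohort: CohortTable,
    min_control_samples: int = 3,
    min_case_samples: int = 6,
    min_depth: int = 10,
    excluded_chromosomes: Sequence[str] = DEFAULT_EXCLUDED_CHROMS,
) -> CohortTable:
    """Keep sites with enough covered samples per group, off sex chromosomes."""
    ctrl = cohort.sample_ids("control")
    case = cohort.sample_ids("case")
    dp = cohort.depths
    ok_ctrl = (dp[ctrl] >= min_depth).sum(axis=1) >= min_control_samples
    ok_case = (dp[case] >= min_depth).sum(axis=1) >= min_case_samples
    excluded = set(excluded_chromosomes)
    off_sex = ~cohort.sites.chrom.isin(excluded)
    keep = (ok_ctrl & ok_case & off_sex.to_numpy()).to_numpy()
    return CohortTable(
        sites=cohort.sites[keep].reset_index(drop=True),
        levels=cohort.levels[keep].reset_index(drop=True),
        depths=cohort.depths[keep].reset_index(drop=True),
        samples=cohort.samples,
    )


def classify_call(difference: float, p_value: float,
                  min_diff: float = 0.10, alpha: float = 0.05) -> str:
    """Pure hyper/hypo/none classification from (difference, p)."""
    if p_value < alpha and difference >= min_diff:
        return "hyper"
    if p_value < alpha and difference <= -min_diff:
        return "hypo"
    return "none"


def test_differential(
    cohort: CohortTable,
    min_diff: float = 0.10,
    alpha: float = 0.05,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Per-site (or per-region) Wilcoxon differential test.

    Group means use only the samples meeting the depth rule at that
    site.  Rows where a group has no covered sample are skipped.
    """
    ctrl_ids = cohort.sample_ids("control")
    case_ids = cohort.sample_ids("case")
    lv_ctrl = cohort.levels[ctrl_ids].to_numpy(dtype=np.float64)
    lv_case = cohort.levels[case_ids].to_numpy(dtype=np.float64)
    dp_ctrl = cohort.depths[ctrl_ids].to_numpy()
    dp_case = cohort.depths[case_ids].to_numpy()
    rows = []
    skipped = 0
    for i in range(len(cohort.sites)):
        cv = lv_ctrl[i][(dp_ctrl[i] >= min_depth) & ~np.isnan(lv_ctrl[i])]
        xv = lv_case[i][(dp_case[i] >= min_depth) & ~np.isnan(lv_case[i])]
        if len(cv) == 0 or len(xv) == 0:
            skipped += 1
            continue
        res = stats.wilcoxon_rank_sum(xv, cv)
        mean_c = float(cv.mean())
        mean_x = float(xv.mean())
        diff = mean_x - mean_c
        rows.append((i, len(cv), len(xv), mean_c, mean_x, diff, res.p_value))
    if skipped:
        log.info("skipped %d sites with an uncovered group", skipped)
    calls = pd.DataFrame(
        rows, columns=["row", "n_control", "n_case", "mean_control",
                       "mean_case", "difference", "p"]
    )
    meta = cohort.sites.iloc[calls.row].reset_index(drop=True)
    out = pd.concat([meta, calls.drop(columns="row").reset_index(drop=True)], axis=1)
    out["bh_p"] = stats.bh_adjust(out.p.to_numpy()).adjusted if len(out) else []
    out["call"] = [
        classify_call(d, p, min_diff, alpha) for d, p in zip(out.difference, out.p)
    ]
    return out


def difference_density(
    differences: Sequence[float],
    grid: Sequence[float] | None = None,
    bandwidth: float | str = "auto",
) -> pd.DataFrame:
    """Kernel density of methylation differences on a grid (default
    [-1, 1] with 401 points)."""
    d = np.asarray(differences, dtype=np.float64)
    d = d[~np.isnan(d)]
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 401)
    grid = np.asarray(grid, dtype=np.float64)
    if len(d) < 2:
        log.warning("fewer than 2 differences; empty density returned")
        return pd.DataFrame({"x": grid, "density": np.full(len(grid), np.nan)})
    dens = stats.kde_density(d, grid, bandwidth)
    return pd.DataFrame({"x": grid, "density": dens})


def hyper_hypo_summary(calls: pd.DataFrame, by: str = "chrom") -> pd.DataFrame:
    """Counts, percentages and hyper/hypo ratio per chromosome (or any
    annotation column present in ``calls``).

    A ratio with zero hypomethylated calls is reported as ``inf`` with
    ``ratio_defined = False``.
    """
    rows = []
    for key, sub in calls.groupby(by):
        n = len(sub)
        n_hyper = int((sub.call == "hyper").sum())
        n_hypo = int((sub.call == "hypo").sum())
        defined = n_hypo > 0
        rows.append(
            {
                by: key,
                "n_tested": n,
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "pct_hyper": 100.0 * n_hyper / n if n else 0.0,
                "pct_hypo": 100.0 * n_hypo / n if n else 0.0,
                "hyper_hypo_ratio": (n_hyper / n_hypo) if defined else np.inf,
                "ratio_defined": defined,
            }
        )
    return pd.DataFrame(rows)


def methylation_summaries(
    cohort: CohortTable,
    site_classes: pd.Series | None = None,
    bin_width: float = 0.05,
    variability_band: tuple[float, float] = (0.30, 0.70),
    depth_cutoffs: Sequence[int] = (10, 20, 50),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Methylation-level histograms and inter-individual variability.

    Returns (histogram, variability).  The histogram bins per-site group
    mean levels (per positional class if ``site_classes`` is given).
    The variability table reports, per depth cutoff, the across-sample
    standard deviation (ddof=1) of sites whose mean lies in the
    partially-methylated band at that depth.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    classes = (
        site_classes.to_numpy() if site_classes is not None
        else np.full(len(cohort.sites), "all", dtype=object)
    )
    hist_rows = []
    for group in ("control", "case"):
        ids = cohort.sample_ids(group)
        lv = cohort.levels[ids].to_numpy(dtype=np.float64)
        dp = cohort.depths[ids].to_numpy()
        lv = np.where(dp >= 10, lv, np.nan)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(lv, axis=1)
        for cls in np.unique(classes):
            vals = mean[(classes == cls) & ~np.isnan(mean)]
            if len(vals) == 0:
                continue
            counts, _ = np.histogram(np.clip(vals, 0, 1), bins=edges)
            frac = counts / counts.sum()
            for lo, f in zip(edges[:-1], frac):
                hist_rows.append((group, cls, round(float(lo), 6), float(f)))
    hist = pd.DataFrame(hist_rows, columns=["group", "site_class", "bin_low", "fraction"])

    var_rows = []
    lo, hi = variability_band
    all_ids = list(cohort.samples.sample_id)
    lv_all = cohort.levels[all_ids].to_numpy(dtype=np.float64)
    dp_all = cohort.depths[all_ids].to_numpy()
    for cutoff in depth_cutoffs:
        lv = np.where(dp_all >= cutoff, lv_all, np.nan)
        n_cov = (~np.isnan(lv)).sum(axis=1)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(lv, axis=1)
            sd = np.nanstd(lv, axis=1, ddof=1)
        sel = (n_cov >= 2) & (mean >= lo) & (mean <= hi)
        for i in np.nonzero(sel)[0]:
            var_rows.append((cutoff, cohort.sites.id.iloc[i], float(mean[i]), float(sd[i])))
    variability = pd.DataFrame(var_rows, columns=["min_depth", "id", "mean_level", "sd"])
    return hist, variability


def cohort_from_region_table(
    region_meth: pd.DataFrame, samplesheet: pd.DataFrame, min_cpgs: int = 6
) -> CohortTable:
    """Build a region-level cohort from aggregate_region_methylation
    output (regions already satisfy the >= min_cpgs covered-CpG rule
    per contributing sample)."""
    sub = region_meth[region_meth.n_cpgs >= min_cpgs]
    lv = sub.pivot_table(index="region_id", columns="sample_id", values="mean_level")
    meta = sub.drop_duplicates("region_id").set_index("region_id")
    sample_ids = list(samplesheet.sample_id)
    lv = lv.reindex(columns=sample_ids)
    dp = pd.DataFrame(
        np.where(lv.notna(), 10_000, 0), index=lv.index, columns=lv.columns
    )
    sites = pd.DataFrame(
        {
            "id": lv.index,
            "chrom": meta.loc[lv.index, "chrom"].to_numpy(),
            "region_class": meta.loc[lv.index, "region_class"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CohortTable(
        sites=sites,
        levels=lv.reset_index(drop=True),
        depths=dp.reset_index(drop=True),
        samples=samplesheet.reset_index(drop=True),
    )
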
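"""Promoter-level methylation and rank-based differentially methylated promoters.

A promoter's methylation level in a sample is the arithmetic mean of the
beta values of the CpG sites inside its interval (missing sites skipped).
Differentially methylated promoters (DMPs) are a *rank* call, not a p-value
call: promoters are ordered by the two-sample t-statistic (case - ctrl) and
the top and bottom ``tail_fraction`` (default 5%) are called hyper- and
hypo-methylated respectively.  Ranking runs separately within mRNA-gene and
lncRNA-gene promoters when biotypes are supplied.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .promoters import PromoterRecord

logger = logging.getLogger(__name__)


def map_sites_to_promoters(
    manifest: pd.DataFrame,
    promoters: Iterable[PromoterRecord],
) -> dict[str, list[str]]:
    """Assign each CpG site to every promoter whose half-open interval holds it.

    ``manifest`` needs columns site_id / chrom / pos (0-based).  A site at
    ``pos == start`` is included, at ``pos == end`` excluded.  Genes with no
    sites are reported in a log line and omitted from the returned map.
    """
    site_map: dict[str, list[str]] = {}
    by_chrom = {}
    for chrom, sub in manifest.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (sub["pos"].to_numpy(), sub["site_id"].to_numpy())
    n_empty = 0
    for prom in promoters:
        if prom.chrom not in by_chrom:
            logger.warning("no sites on chrom %s for gene %s", prom.chrom, prom.gene_id)
            n_empty += 1
            continue
        pos, ids = by_chrom[prom.chrom]
        lo = np.searchsorted(pos, prom.start, side="left")
        hi = np.searchsorted(pos, prom.end, side="left")
        if hi > lo:
            site_map[prom.gene_id] = list(ids[lo:hi])
        else:
            n_empty += 1
    if n_empty:
        logger.info("%d promoters have zero CpG sites and are excluded", n_empty)
    return site_map


def promoter_methylation(
    beta: pd.DataFrame, site_map: Mapping[str, list[str]]
) -> pd.DataFrame:
    """Gene x sample table of mean beta over each promoter's sites.

    Missing site values are skipped; the mean is missing only when every
    site is missing for that sample.
    """
    if not site_map:
        raise ValueError("empty site map")
    bad = ((beta < 0) | (beta > 1)).any().any()
    if bad:
        raise ValueError("beta values outside [0, 1]")
    rows = {}
    for gene_id, sites in site_map.items():
        rows[gene_id] = beta.loc[sites].mean(axis=0, skipna=True)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _rank_one_stratum(
    means: pd.DataFrame,
    ctrl_ids: list[str],
    case_ids: list[str],
    tail_fraction: float,
    equal_var: bool,
    rank_by: str,
) -> pd.DataFrame:
    ctrl = means[ctrl_ids].to_numpy(dtype=float)
    case = means[case_ids].to_numpy(dtype=float)
    # drop promoters missing an entire group
    ok = (~np.isnan(ctrl).all(axis=1)) & (~np.isnan(case).all(axis=1))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%d promoters dropped: a whole group is missing", n_dropped)
    means = means.loc[ok]
    ctrl, case = ctrl[ok], case[ok]
    delta = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
    t_stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var, nan_policy="omit")
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t_stat)
    t_stat[degenerate] = np.where(np.abs(delta[degenerate]) < 1e-12, 0.0,
                                  np.sign(delta[degenerate]) * np.inf)
    p[~np.isfinite(p)] = 1.0
    df = pd.DataFrame(
        {
            "gene_id": means.index,
            "mean_beta_ctrl": np.nanmean(ctrl, axis=1),
            "mean_beta_case": np.nanmean(case, axis=1),
            "delta_beta": delta,
            "t_stat": t_stat,
            "p": p,
        }
    )
    n = len(df)
    k = _round_half_up(tail_fraction * n)
    if k < 1:
        raise ValueError(f"tail_fraction {tail_fraction} yields zero calls on {n} promoters")
    if 2 * k > n:
        raise ValueError("tails overlap: tail_fraction too large for promoter count")
    key = "t_stat" if rank_by == "t" else "delta_beta"
    order = df.sort_values(
        [key, "delta_beta", "gene_id"],
        key=lambda c: c.abs() if c.name == "delta_beta" and key != "delta_beta" else c,
        ascending=[False, False, True],
    ).reset_index(drop=True)
    calls = pd.Series("none", index=order["gene_id"])
    calls.iloc[:k] = "hyper"
    calls.iloc[n - k:] = "hypo"
    df["call"] = df["gene_id"].map(calls).to_numpy()
    # fraction of promoters with a t-statistic <= this one (ascending rank)
    df["rank_fraction"] = stats.rankdata(df[key], method="average") / n
    return df


def identify_dmps(
    promoter_means: pd.DataFrame,
    groups: Mapping[str, str],
    tail_fraction: float = 0.05,
    biotypes: Mapping[str, str] | None = None,
    n_sites: Mapping[str, int] | None = None,
    equal_var: bool = True,
    rank_by: str = "t",
) -> pd.DataFrame:
    """Call hyper-/hypo-methylated promoters by extreme-tail rank.

    ``k = round(tail_fraction * n)`` (half-up) promoters land in each tail,
    within each biotype stratum when ``biotypes`` is given.  Ties in the
    ranking statistic break by |delta_beta|, then gene id.  ``rank_by`` may
    be ``"t"`` (signed t-statistic, default) or ``"delta"`` (mean-beta
    difference).
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if rank_by not in ("t", "delta"):
        raise ValueError("rank_by must be 't' or 'delta'")
    ctrl_ids = [s for s in promoter_means.columns if groups.get(s) in ("ctrl", "control", "normal")]
    case_ids = [s for s in promoter_means.columns if groups.get(s) in ("uc", "case", "disease")]
    if len(ctrl_ids) < 2 or len(case_ids) < 2:
        raise ValueError("need >=2 samples per group")
    if biotypes is None:
        strata = {"all": promoter_means}
    else:
        bt = pd.Series({g: biotypes[g] for g in promoter_means.index})
        strata = {b: promoter_means.loc[bt[bt == b].index] for b in sorted(bt.unique())}
    parts = []
    for name, sub in strata.items():
        part = _rank_one_stratum(sub, ctrl_ids, case_ids, tail_fraction, equal_var, rank_by)
        part.insert(1, "biotype", name)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    if n_sites is not None:
        out.insert(2, "n_sites", out["gene_id"].map(n_sites).astype("Int64"))
    return out


def crosstab_percent(count: int, total: int) -> float:
    """Percentage (count / total * 100) rounded to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(count / total * 100.0, 2)


def dmp_crosstab(dmps: pd.DataFrame, classes: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate DMP calls against promoter CpG classes.

    One row per (biotype, class) plus a total row per biotype: total
    promoters, hyper count and percentage, hypo count and percentage.
    """
    cls = classes.set_index("gene_id")
    missing = set(dmps["gene_id"]) - set(cls.index)
    if missing:
        raise ValueError(f"{len(missing)} DMP genes missing from classes table")
    merged = dmps.merge(
        cls[["biotype", "class"]], left_on="gene_id", right_index=True, suffixes=("_rank", "")
    )
    rows = []
    for biotype, bio_sub in merged.groupby("biotype", observed=True):
        for klass, sub in bio_sub.groupby("class", observed=True):
            total = len(sub)
            n_hyper = int((sub["call"] == "hyper").sum())
            n_hypo = int((sub["call"] == "hypo").sum())
            rows.append(
                {
                    "biotype": biotype,
                    "class": klass,
                    "total": total,
                    "hyper": n_hyper,
                    "hyper_pct": crosstab_percent(n_hyper, total),
                    "hypo": n_hypo,
                    "hypo_pct": crosstab_percent(n_hypo, total),
                }
            )
        total = len(bio_sub)
        n_hyper = int((bio_sub["call"] == "hyper").sum())
        n_hypo = int((bio_sub["call"] == "hypo").sum())
        rows.append(
            {
                "biotype": biotype,
                "class": "total",
                "total": total,
                "hyper": n_hyper,
                "hyper_pct": crosstab_percent(n_hyper, total),
                "hypo": n_hypo,
                "hypo_pct": crosstab_percent(n_hypo, total),
            }
        )
    return pd.DataFrame(rows)
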
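"""Direction-concordant intersection of expression and methylation calls.

A feature becomes a candidate marker when it is differentially expressed,
its promoter carries a DMP call, and the two directions are concordant with
promoter-methylation repression: up-regulated with a hypo-methylated
promoter, or down-regulated with a hyper-methylated promoter.  Discordant
combinations are excluded by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: allowed (expression direction, methylation call) pairs
CONCORDANT = {("up", "hypo"), ("down", "hyper")}


def integrate(de_results: pd.DataFrame, dmp_results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join DE and DMP tables by gene id and keep concordant calls.

    ``de_results`` needs feature_id / biotype / is_de / direction / log2fc;
    ``dmp_results`` needs gene_id / call / delta_beta.  Returns the candidate
    table and per-(biotype, category) counts.  DE features without promoter
    methylation data simply cannot become candidates (inner join).
    """
    if de_results["feature_id"].duplicated().any():
        raise ValueError("duplicate feature_id in DE results")
    if dmp_results["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in DMP results")
    de = de_results[de_results["is_de"]][["feature_id", "biotype", "direction", "log2fc"]]
    dmp = dmp_results[dmp_results["call"].isin(["hyper", "hypo"])][
        ["gene_id", "call", "delta_beta"]
    ].rename(columns={"call": "dmp_call"})
    merged = de.merge(dmp, left_on="feature_id", right_on="gene_id", how="inner").drop(
        columns="gene_id"
    )
    mask = np.fromiter(
        ((d, c) in CONCORDANT for d, c in zip(merged["direction"], merged["dmp_call"])),
        dtype=bool,
        count=len(merged),
    )
    candidates = merged.loc[mask].rename(columns={"direction": "de_direction"})
    candidates = candidates[
        ["feature_id", "biotype", "de_direction", "dmp_call", "log2fc", "delta_beta"]
    ].sort_values("feature_id").reset_index(drop=True)
    counts = (
        candidates.groupby(["biotype", "de_direction", "dmp_call"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return candidates, counts


def integration_report(
    candidates: pd.DataFrame, n_de_by_biotype: dict[str, int] | None = None
) -> pd.DataFrame:
    """Candidate counts per biotype with the grand total (and % of DE retained)."""
    rows = []
    total = 0
    biotypes = sorted(candidates["biotype"].unique()) if len(candidates) else []
    if n_de_by_biotype:
        biotypes = sorted(set(biotypes) | set(n_de_by_biotype))
    for biotype in biotypes:
        n = int((candidates["biotype"] == biotype).sum()) if len(candidates) else 0
        total += n
        row = {"biotype": biotype, "n_candidates": n}
        if n_de_by_biotype and n_de_by_biotype.get(biotype):
            row["pct_of_de"] = round(100.0 * n / n_de_by_biotype[biotype], 2)
        rows.append(row)
    rows.append({"biotype": "total", "n_candidates": total})
    return pd.DataFrame(rows)
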
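"""Site-to-promoter mapping, promoter means, and rank-based DMP calls."""

import numpy as np
import pandas as pd
import pytest

from methex.methylation import (
    crosstab_percent,
    dmp_crosstab,
    identify_dmps,
    map_sites_to_promoters,
    promoter_methylation,
)
from methex.promoters import PromoterRecord

# ---------------------------------------------------------------------------


def _promoter(gene_id, chrom, start, end):
    return PromoterRecord(gene_id, chrom, start, end, "+")


def test_site_mapping_half_open_convention():
    manifest = pd.DataFrame(
        {"site_id": ["s1", "s2", "s3"], "chrom": ["c"] * 3, "pos": [100, 150, 200]}
    )
    proms = [_promoter("g", "c", 100, 200)]
    site_map = map_sites_to_promoters(manifest, proms)
    assert site_map["g"] == ["s1", "s2"]  # pos=start in, pos=end out


def test_site_mapping_matches_double_loop_oracle(rng):
    pos = rng.integers(0, 5000, size=300)
    manifest = pd.DataFrame(
        {"site_id": [f"s{i}" for i in range(300)], "chrom": "c", "pos": pos}
    )
    proms = [
        _promoter(f"g{i}", "c", int(s), int(s) + 400)
        for i, s in enumerate(rng.integers(0, 4800, size=40))
    ]
    got = map_sites_to_promoters(manifest, proms)
    for p in proms:
        expected = sorted(
            manifest.loc[(manifest["pos"] >= p.start) & (manifest["pos"] < p.end), "site_id"]
        )
        assert sorted(got.get(p.gene_id, [])) == expected


def test_site_mapping_chrom_mismatch_yields_nothing():
    manifest = pd.DataFrame({"site_id": ["s1"], "chrom": ["c1"], "pos": [10]})
    assert map_sites_to_promoters(manifest, [_promoter("g", "c2", 0, 100)]) == {}


def test_promoter_methylation_means():
    beta = pd.DataFrame(
        {"a": [0.2, np.nan, 0.6, 0.7], "b": [0.2, 0.4, 0.6, np.nan]},
        index=["s1", "s2", "s3", "s4"],
    )
    means = promoter_methylation(beta, {"g1": ["s1", "s2", "s3"], "g2": ["s4"]})
    assert means.loc["g1", "a"] == pytest.approx(0.4)  # skip-missing mean
    assert means.loc["g1", "b"] == pytest.approx(0.4)
    assert means.loc["g2", "a"] == pytest.approx(0.7)  # mean of one
    assert np.isnan(means.loc["g2", "b"])  # all sites missing


def test_promoter_methylation_validates_range():
    beta = pd.DataFrame({"a": [1.2]}, index=["s1"])
    with pytest.raises(ValueError):
        promoter_methylation(beta, {"g": ["s1"]})


# ---------------------------------------------------------------------------
# rank-based DMP calls

GROUPS = {f"c{i}": "ctrl" for i in range(1, 4)} | {f"u{i}": "uc" for i in range(1, 9)}


def _means(n, rng, shift_idx=(), shift=0.0):
    vals = rng.uniform(0.3, 0.7, size=(n, 11))
    vals[:, 3:] += rng.normal(0, 0.02, size=(n, 8))
    for i in shift_idx:
        vals[i, 3:] += shift
    vals = np.clip(vals, 0, 1)
    return pd.DataFrame(vals, index=[f"g{i:03d}" for i in range(n)], columns=list(GROUPS))


def _t_stats(means):
    from scipy.stats import ttest_ind

    t, _ = ttest_ind(means[[c for c in means if c.startswith("u")]],
                     means[[c for c in means if c.startswith("c")]],
                     axis=1, equal_var=True)
    return pd.Series(t, index=means.index)


def test_dmp_exact_tail_counts(rng):
    means = _means(100, rng)
    res = identify_dmps(means, GROUPS, tail_fraction=0.05)
    assert (res["call"] == "hyper").sum() == 5
    assert (res["call"] == "hypo").sum() == 5
    hyper = set(res.loc[res["call"] == "hyper", "gene_id"])
    hypo = set(res.loc[res["call"] == "hypo", "gene_id"])
    assert not hyper & hypo


def test_dmp_tails_match_full_sort_oracle(rng):
    means = _means(80, rng)
    res = identify_dmps(means, GROUPS, tail_fraction=0.05)
    t = _t_stats(means)
    k = 4  # round(0.05 * 80)
    assert set(res.loc[res["call"] == "hyper", "gene_id"]) == set(t.nlargest(k).index)
    assert set(res.loc[res["call"] == "hypo", "gene_id"]) == set(t.nsmallest(k).index)
    # separation property: called tails dominate everything uncalled
    called_hyper_min = res.loc[res["call"] == "hyper", "t_stat"].min()
    uncalled_max = res.loc[res["call"] == "none", "t_stat"].max()
    assert called_hyper_min >= uncalled_max


def test_dmp_label_swap_exchanges_tails(rng):
    means = _means(60, rng)
    swapped = {s: ("ctrl" if g == "uc" else "uc") for s, g in GROUPS.items()}
    a = identify_dmps(means, GROUPS).set_index("gene_id")
    b = identify_dmps(means, swapped).set_index("gene_id")
    assert set(a.index[a["call"] == "hyper"]) == set(b.index[b["call"] == "hypo"])
    assert set(a.index[a["call"] == "hypo"]) == set(b.index[b["call"] == "hyper"])


def test_dmp_biotype_stratified_ranking(rng):
    means = _means(100, rng)
    biotypes = {g: ("mRNA" if i < 60 else "lncRNA") for i, g in enumerate(means.index)}
    res = identify_dmps(means, GROUPS, biotypes=biotypes)
    per = res.groupby("biotype")["call"].value_counts()
    assert per[("mRNA", "hyper")] == 3  # round(0.05 * 60)
    assert per[("lncRNA", "hyper")] == 2  # round(0.05 * 40)


def test_dmp_validation(rng):
    means = _means(30, rng)
    with pytest.raises(ValueError):
        identify_dmps(means, GROUPS, tail_fraction=0.5)
    with pytest.raises(ValueError):
        identify_dmps(means, {"c1": "ctrl", "u1": "uc"})
    with pytest.raises(ValueError):
        identify_dmps(means.iloc[:5], GROUPS, tail_fraction=0.05)  # k = 0


def test_dmp_planted_recovery(cohort):
    from methex.methylation import map_sites_to_promoters, promoter_methylation

    groups = {s: ("uc" if "_uc_" in s else "ctrl") for s in cohort.beta.columns}
    site_map = map_sites_to_promoters(cohort.sites, cohort.promoters)
    means = promoter_methylation(cohort.beta, site_map)
    biotypes = {g.gene_id: g.biotype for g in cohort.genes}
    res = identify_dmps(means, groups, biotypes=biotypes).set_index("gene_id")
    for g in cohort.truth.planted_down_hyper:
        assert res.loc[g, "call"] == "hyper"
    for g in cohort.truth.planted_up_hypo:
        assert res.loc[g, "call"] == "hypo"


# ---------------------------------------------------------------------------
# crosstab report


@pytest.mark.parametrize(
    "count,total,expected", [(119, 6067, 1.96), (642, 9779, 6.57), (0, 100, 0.0)]
)
def test_crosstab_percent(count, total, expected):
    assert crosstab_percent(count, total) == expected


def test_dmp_crosstab_self_consistency(rng):
    means = _means(100, rng)
    biotypes = {g: ("mRNA" if i < 60 else "lncRNA") for i, g in enumerate(means.index)}
    res = identify_dmps(means, GROUPS, biotypes=biotypes)
    classes = pd.DataFrame(
        {
            "gene_id": means.index,
            "biotype": [biotypes[g] for g in means.index],
            "class": [("HCP", "ICP", "LCP")[i % 3] for i in range(100)],
        }
    )
    tab = dmp_crosstab(res, classes)
    for row in tab.itertuples(index=False):
        assert row.hyper_pct == crosstab_percent(row.hyper, row.total)
        assert row.hypo_pct == crosstab_percent(row.hypo, row.total)
    totals = tab[tab["class"] == "total"]
    assert totals["total"].sum() == 100
    # missing class entry is an error
    with pytest.raises(ValueError):
        dmp_crosstab(res, classes.iloc[:50])
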
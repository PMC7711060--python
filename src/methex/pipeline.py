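"""End-to-end orchestration: simulate -> classify -> DE -> DMP -> integrate ->
network -> diagnose, with a stage-by-stage run report.

Each stage writes its table(s) into the run directory; ``run_report.json``
records parameters, wall time and record counts per stage, so reruns with
the same seed are checkable for exact agreement.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .diagnostics import fit_logistic, predict_proba, roc_auc
from .expression import differential_expression, quantile_normalize
from .integration import integrate, integration_report
from .methylation import dmp_crosstab, identify_dmps, map_sites_to_promoters, promoter_methylation
from .network import build_network, rank_hubs, write_sif
from .promoters import classify_all, derive_promoter
from .simulate import SimConfig, simulate_cohort, simulate_diagnostic_cohort, write_fixture

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "methex_run"
    seed: int = 0
    upstream: int = 1500
    downstream: int = 500
    window: int = 500
    hcp_ratio: float = 0.75
    hcp_gc: float = 0.55
    lcp_ratio: float = 0.48
    lfc_cut: float = 1.0
    fdr_cut: float = 0.05
    tail_fraction: float = 0.05
    r_cut: float = 0.98
    p_cut: float = 0.01
    diag_n_per_group: int = 20
    sim: SimConfig = field(default_factory=SimConfig)
    log_level: str = "INFO"


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every invariant; returns the (possibly empty) list of violations."""
    v = []
    if config.upstream < 0 or config.downstream < 0:
        v.append("upstream/downstream must be non-negative")
    if config.window < 2:
        v.append("window must be >= 2")
    if not 0 < config.tail_fraction < 0.5:
        v.append("tail_fraction must be in (0, 0.5) for disjoint tails")
    if config.lfc_cut < 0:
        v.append("lfc_cut must be non-negative")
    if not 0 <= config.fdr_cut <= 1:
        v.append("fdr_cut must be in [0, 1]")
    if not -1 <= config.r_cut <= 1:
        v.append("r_cut must be in [-1, 1]")
    if not 0 <= config.p_cut <= 1:
        v.append("p_cut must be in [0, 1]")
    for thr, name in (
        (config.hcp_ratio, "hcp_ratio"),
        (config.lcp_ratio, "lcp_ratio"),
    ):
        if thr < 0:
            v.append(f"{name} must be non-negative")
    if not 0 <= config.hcp_gc <= 1:
        v.append("hcp_gc must be in [0, 1]")
    if config.diag_n_per_group < 2:
        v.append("diag_n_per_group must be >= 2")
    return v


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the run report dict."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    report: dict = {
        "seed": config.seed,
        "params": {
            k: v for k, v in dataclasses.asdict(config).items() if k not in ("sim",)
        },
        "sim_params": dataclasses.asdict(sim),
        "stages": [],
        "counts": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                counts = fn()
            except Exception as exc:  # partial outputs stay on disk
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            dt = time.perf_counter() - t0
            report["stages"].append({"stage": name, "wall_time_s": round(dt, 4), "counts": counts})
            report["counts"].update(counts)
            logger.info("stage %-20s %6.2fs %s", name, dt, counts)
            return counts

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        cohort = simulate_cohort(sim)
        write_fixture(cohort, out / "fixture")
        state["cohort"] = cohort
        return {"n_genes": len(cohort.genes), "n_sites": len(cohort.sites)}

    @stage("classify_promoters")
    def _classify():
        cohort = state["cohort"]
        biotypes = {g.gene_id: g.biotype for g in cohort.genes}
        classes, summary = classify_all(cohort.promoters, biotypes, window=config.window)
        classes.to_csv(out / "classes.tsv", sep="\t", index=False)
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
        state["classes"] = classes
        return {"n_classified": len(classes)}

    @stage("differential_expression")
    def _de():
        cohort = state["cohort"]
        groups = mio.groups_for_assay(cohort.samples, "expr")
        de = {}
        for biotype, matrix in (("mRNA", cohort.expr_mrna), ("lncRNA", cohort.expr_lncrna)):
            normed = quantile_normalize(matrix)
            res = differential_expression(normed, groups, config.lfc_cut, config.fdr_cut)
            res.insert(1, "biotype", biotype)
            res.to_csv(out / f"de_{biotype.lower()}.tsv", sep="\t", index=False)
            de[biotype] = res
        state["de"] = de
        return {
            "n_de_mrna": int(de["mRNA"]["is_de"].sum()),
            "n_de_lncrna": int(de["lncRNA"]["is_de"].sum()),
        }

    @stage("differential_methylation")
    def _dmp():
        cohort = state["cohort"]
        groups = mio.groups_for_assay(cohort.samples, "meth")
        site_map = map_sites_to_promoters(cohort.sites, cohort.promoters)
        means = promoter_methylation(cohort.beta, site_map)
        biotypes = {g.gene_id: g.biotype for g in cohort.genes}
        n_sites = {g: len(s) for g, s in site_map.items()}
        dmps = identify_dmps(
            means,
            groups,
            tail_fraction=config.tail_fraction,
            biotypes=biotypes,
            n_sites=n_sites,
        )
        dmps.to_csv(out / "dmp.tsv", sep="\t", index=False)
        crosstab = dmp_crosstab(dmps, state["classes"])
        crosstab.to_csv(out / "crosstab.tsv", sep="\t", index=False)
        state["dmps"] = dmps
        return {"n_dmp_calls": int((dmps["call"] != "none").sum())}

    @stage("integrate")
    def _integrate():
        de_all = pd.concat(state["de"].values(), ignore_index=True)
        candidates, counts = integrate(de_all, state["dmps"])
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        n_de_by_biotype = {b: int(d["is_de"].sum()) for b, d in state["de"].items()}
        integration_report(candidates, n_de_by_biotype).to_csv(
            out / "integration_report.tsv", sep="\t", index=False
        )
        state["candidates"] = candidates
        return {"n_candidates": len(candidates)}

    @stage("network")
    def _network():
        cohort = state["cohort"]
        edges, summary = build_network(
            cohort.expr_mrna,
            cohort.expr_lncrna,
            state["candidates"],
            r_cut=config.r_cut,
            p_cut=config.p_cut,
        )
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        write_sif(edges, out / "network.sif")
        pd.DataFrame(summary.hubs, columns=["node", "degree"]).to_csv(
            out / "degrees.tsv", sep="\t", index=False
        )
        state["summary"] = summary
        return {"n_edges": summary.n_edges, "n_nodes": summary.n_nodes}

    @stage("diagnose")
    def _diagnose():
        cohort = state["cohort"]
        truth = cohort.truth
        mrna_ids = [g.gene_id for g in cohort.genes if g.biotype == "mRNA"]
        hub_mrna = [n for n, _ in state["summary"].hubs if n in set(mrna_ids)]
        panel = hub_mrna[:3]
        if not panel:
            planted_mrna = sorted(truth.planted_genes & set(mrna_ids))
            panel = (planted_mrna or mrna_ids)[:3]
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(9,)))
        n = config.diag_n_per_group
        informative = truth.planted_genes
        X_train, y_train = simulate_diagnostic_cohort(
            panel, informative, n, n, sim.expr_log2fc_effect, sim.expr_sd, rng
        )
        X_test, y_test = simulate_diagnostic_cohort(
            panel, informative, n, n, sim.expr_log2fc_effect, sim.expr_sd, rng
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_logistic(X_train, y_train)
        roc_train = roc_auc(predict_proba(model, X_train), y_train)
        roc_test = roc_auc(predict_proba(model, X_test), y_test)
        model.to_json(out / "model.json")
        pd.DataFrame(
            {"threshold": roc_test.thresholds, "fpr": roc_test.fpr, "tpr": roc_test.tpr}
        ).to_csv(out / "roc.tsv", sep="\t", index=False)
        (out / "auc.txt").write_text(
            f"train_auc\t{roc_train.auc:.4f}\ntest_auc\t{roc_test.auc:.4f}\n"
        )
        return {
            "panel": panel,
            "auc_train": round(roc_train.auc, 4),
            "auc_test": round(roc_test.auc, 4),
        }

    # consistency of the stage ledger
    c = report["counts"]
    assert c["n_candidates"] <= c["n_de_mrna"] + c["n_de_lncrna"]
    assert c["n_candidates"] <= c["n_dmp_calls"]
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
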
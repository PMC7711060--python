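"""Synthetic paired expression + methylation cohorts with known planted truth.

The simulator emulates the structure of a small two-group disease study:

* a panel of mRNA and lncRNA genes tiled on one synthetic chromosome, each
  with a 2-kb promoter sequence generated to a requested CpG-density class
  (HCP / ICP / LCP, validated against :func:`methex.promoters.classify_promoter`);
* an Infinium-style CpG-site beta matrix (values in [0, 1]) for a
  methylation cohort, with class-typical baselines (HCP lowest, LCP highest)
  and planted promoter shifts in the case group;
* log2-scale expression intensity matrices for a separate expression cohort,
  with planted fold changes whose direction is anti-correlated with the
  planted methylation shift (up-regulated genes get hypo-methylated
  promoters and vice versa);
* planted lncRNA-mRNA co-expression pairs driven by a shared latent factor.

Defaults mirror the emulated study design: 3 control vs 3 case expression
samples and 3 control vs 8 case methylation samples.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .promoters import (
    HCP,
    ICP,
    LCP,
    GeneModel,
    PromoterRecord,
    classify_promoter,
)

logger = logging.getLogger(__name__)

# beta-value baselines per promoter class; HCP promoters are the least
# methylated and LCP the most, matching the canonical CpG-density gradient
CLASS_BASELINE_BETA = {HCP: 0.15, ICP: 0.50, LCP: 0.80}

# co-expression latent factor scale and residual noise for planted pairs;
# with sd 2.5 vs 0.1 the population correlation is ~0.998
_EDGE_LATENT_SD = 2.5
_EDGE_NOISE_SD = 0.1


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; one seed drives every stage."""

    n_genes_mrna: int = 120
    n_genes_lncrna: int = 80
    n_samples_ctrl_expr: int = 3
    n_samples_uc_expr: int = 3
    n_samples_ctrl_meth: int = 3
    n_samples_uc_meth: int = 8
    promoter_len: int = 2000
    frac_hcp: float = 0.3
    frac_icp: float = 0.4
    frac_lcp: float = 0.3
    n_planted_up_hypo: int = 6
    n_planted_down_hyper: int = 6
    expr_log2fc_effect: float = 2.0
    beta_shift_effect: float = 0.3
    beta_concentration: float = 50.0
    expr_sd: float = 0.1
    n_planted_edges: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes_mrna",
            "n_genes_lncrna",
            "n_samples_ctrl_expr",
            "n_samples_uc_expr",
            "n_samples_ctrl_meth",
            "n_samples_uc_meth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.promoter_len < 500:
            raise ValueError("promoter_len must be >= 500")
        if abs(self.frac_hcp + self.frac_icp + self.frac_lcp - 1.0) > 1e-9:
            raise ValueError("frac_hcp + frac_icp + frac_lcp must sum to 1")
        if min(self.frac_hcp, self.frac_icp, self.frac_lcp) < 0:
            raise ValueError("class fractions must be non-negative")
        if not 0.0 < self.beta_shift_effect < 1.0:
            raise ValueError("beta_shift_effect must be in (0, 1)")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")
        if self.expr_sd <= 0:
            raise ValueError("expr_sd must be positive")
        if min(self.n_planted_up_hypo, self.n_planted_down_hyper, self.n_planted_edges) < 0:
            raise ValueError("planted counts must be non-negative")


@dataclass
class Truth:
    """Ground truth of the planted structure, for parameter-recovery tests."""

    planted_up_hypo: set[str] = field(default_factory=set)
    planted_down_hyper: set[str] = field(default_factory=set)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    promoter_class_by_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.planted_up_hypo & self.planted_down_hyper:
            raise ValueError("planted sets must be disjoint")

    @property
    def planted_genes(self) -> set[str]:
        return self.planted_up_hypo | self.planted_down_hyper

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_up_hypo": sorted(self.planted_up_hypo),
            "planted_down_hyper": sorted(self.planted_down_hyper),
            "planted_edges": sorted(map(list, self.planted_edges)),
            "promoter_class_by_gene": dict(sorted(self.promoter_class_by_gene.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Truth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_up_hypo=set(payload["planted_up_hypo"]),
            planted_down_hyper=set(payload["planted_down_hyper"]),
            planted_edges={tuple(e) for e in payload["planted_edges"]},
            promoter_class_by_gene=dict(payload["promoter_class_by_gene"]),
        )


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    # one root seed; per-stage streams via the spawn-key mechanism so that
    # stages stay reproducible independently of each other
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def _class_counts(n: int, config: SimConfig) -> dict[str, int]:
    n_hcp = int(round(n * config.frac_hcp))
    n_icp = int(round(n * config.frac_icp))
    n_lcp = n - n_hcp - n_icp
    if n_lcp < 0:
        raise ValueError("class fractions round to more genes than available")
    return {HCP: n_hcp, ICP: n_icp, LCP: n_lcp}


def simulate_genes(config: SimConfig) -> tuple[list[GeneModel], Truth]:
    """Lay out gene models on one synthetic chromosome and pick planted genes.

    Promoters are tiled with >= 1 kb gaps so they can never overlap; strands
    alternate.  Planted (differential) genes are drawn from ICP promoters of
    each biotype so the +/- beta shift stays inside [0, 1] around the
    mid-range ICP baseline; planted co-expression pairs are a disjoint
    lncRNA-mRNA matching over the remaining (non-differential) genes.
    """
    rng = _stage_rng(config, 0)
    gap = 1000
    pitch = config.promoter_len + gap
    genes: list[GeneModel] = []
    classes: dict[str, str] = {}
    class_pool: list[str] = []
    for biotype, count in (("mRNA", config.n_genes_mrna), ("lncRNA", config.n_genes_lncrna)):
        counts = _class_counts(count, config)
        labels = [c for c in (HCP, ICP, LCP) for _ in range(counts[c])]
        rng.shuffle(labels)
        class_pool.extend(labels)
    n_total = config.n_genes_mrna + config.n_genes_lncrna
    for i in range(n_total):
        biotype = "mRNA" if i < config.n_genes_mrna else "lncRNA"
        prefix = "MR" if biotype == "mRNA" else "LNC"
        idx = i if biotype == "mRNA" else i - config.n_genes_mrna
        strand = "+" if i % 2 == 0 else "-"
        start = gap + i * pitch  # promoter interval is [start, start+len)
        # invert the strand-relative promoter rule to recover the TSS
        tss = start + 1500 if strand == "+" else start + 500
        gene_id = f"{prefix}{idx:04d}"
        genes.append(GeneModel(gene_id, "chrS", strand, tss, biotype))
        classes[gene_id] = class_pool[i]

    truth = Truth(promoter_class_by_gene=classes)
    for biotype in ("mRNA", "lncRNA"):
        icp_pool = sorted(
            g.gene_id for g in genes if g.biotype == biotype and classes[g.gene_id] == ICP
        )
        n_up = _split_count(config.n_planted_up_hypo, biotype)
        n_down = _split_count(config.n_planted_down_hyper, biotype)
        if n_up + n_down > len(icp_pool):
            raise ValueError(
                f"not enough ICP {biotype} promoters ({len(icp_pool)}) for "
                f"{n_up + n_down} planted genes; increase gene count or frac_icp"
            )
        chosen = list(rng.choice(icp_pool, size=n_up + n_down, replace=False))
        truth.planted_up_hypo.update(chosen[:n_up])
        truth.planted_down_hyper.update(chosen[n_up:])

    truth.planted_edges = _pick_edges(genes, truth, config, rng)
    return genes, truth


def _split_count(n: int, biotype: str) -> int:
    # split a planted count across the two biotypes: mRNA gets the ceiling
    return (n + 1) // 2 if biotype == "mRNA" else n // 2


def _pick_edges(
    genes: list[GeneModel],
    truth: Truth,
    config: SimConfig,
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """A disjoint lncRNA-mRNA matching for the planted co-expression modules."""
    mrna = [g.gene_id for g in genes if g.biotype == "mRNA"]
    lnc = [g.gene_id for g in genes if g.biotype == "lncRNA"]
    # edge genes are kept disjoint from planted differential genes: the shared
    # latent factor that drives the pair correlation acts as within-group
    # variance and would mask a planted fold change at these group sizes
    free_lnc = [g for g in lnc if g not in truth.planted_genes]
    free_mrna = [g for g in mrna if g not in truth.planted_genes]
    rng.shuffle(free_lnc)
    rng.shuffle(free_mrna)
    pairs = list(zip(free_lnc, free_mrna))
    if len(pairs) < config.n_planted_edges:
        raise ValueError("not enough genes for the requested number of planted edges")
    return set(pairs[: config.n_planted_edges])


# ---------------------------------------------------------------------------
# promoter sequence generation (generate-and-check against the classifier)

_CLASS_PARAMS = {
    # (GC fraction, probability of breaking each CpG dinucleotide)
    HCP: (0.60, 0.0),
    ICP: (0.46, 0.40),
    LCP: (0.40, 0.90),
}


def simulate_promoter_sequence(
    target_class: str,
    length: int,
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> str:
    """Draw a promoter sequence whose classifier output is ``target_class``.

    Sequences are iid draws at a class-typical GC content with CpG
    dinucleotides thinned to a class-typical observed/expected ratio (iid
    sequences have o/e ~ 1, so depletion must be simulated explicitly); each
    draw is verified with the classifier and resampled on mismatch.
    """
    if length < 500:
        raise ValueError("length must be >= 500")
    if target_class not in _CLASS_PARAMS:
        raise ValueError(f"unknown promoter class {target_class!r}")
    gc, p_break = _CLASS_PARAMS[target_class]
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(max_attempts):
        seq = rng.choice(alphabet, size=length, p=base_p)
        if p_break > 0:
            cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
            broken = cg[rng.random(len(cg)) < p_break]
            # replacing the G with A/T cannot create a new CpG
            seq[broken + 1] = rng.choice(
                np.frombuffer(b"AT", dtype=np.uint8), size=len(broken)
            )
        s = seq.tobytes().decode("ascii")
        if classify_promoter(s).cls == target_class:
            return s
    raise RuntimeError(f"could not generate a {target_class} promoter in {max_attempts} tries")


def build_promoters(
    genes: list[GeneModel],
    truth: Truth,
    config: SimConfig,
) -> list[PromoterRecord]:
    """Attach a class-matched sequence to every gene's promoter interval.

    Planted genes are guaranteed at least one CpG site (resampled otherwise)
    so the methylation stage can always observe them.
    """
    rng = _stage_rng(config, 1)
    up, down = 1500, 500
    promoters: list[PromoterRecord] = []
    for gene in genes:
        if gene.strand == "+":
            start, end = gene.tss - up, gene.tss + down
        else:
            start, end = gene.tss - down, gene.tss + up
        target = truth.promoter_class_by_gene[gene.gene_id]
        seq = simulate_promoter_sequence(target, end - start, rng)
        if gene.gene_id in truth.planted_genes:
            attempts = 0
            while "CG" not in seq:
                attempts += 1
                if attempts > 50:
                    raise RuntimeError(
                        f"planted gene {gene.gene_id} promoter has no CpG site"
                    )
                seq = simulate_promoter_sequence(target, end - start, rng)
        promoters.append(
            PromoterRecord(gene.gene_id, gene.chrom, start, end, gene.strand, sequence=seq)
        )
    return promoters


# ---------------------------------------------------------------------------
# methylation and expression matrices


def _sample_ids(n_ctrl: int, n_case: int, assay: str) -> list[str]:
    return [f"{assay}_ctrl_{i + 1}" for i in range(n_ctrl)] + [
        f"{assay}_uc_{i + 1}" for i in range(n_case)
    ]


def simulate_methylation(
    promoters: list[PromoterRecord],
    truth: Truth,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG-site beta matrix (sites x samples) plus its site manifest.

    Sites are the CG dinucleotide positions in each promoter.  Per-site means
    sit near the class baseline (HCP 0.15, ICP 0.50, LCP 0.80) with a small
    per-site jitter; planted hyper promoters gain ``+beta_shift_effect`` in
    the case group and planted hypo promoters lose it.  Values are Beta draws
    with the configured concentration, so they stay inside [0, 1].
    """
    rng = _stage_rng(config, 2)
    samples = _sample_ids(config.n_samples_ctrl_meth, config.n_samples_uc_meth, "meth")
    n_ctrl = config.n_samples_ctrl_meth
    manifest_rows = []
    betas = []
    site_counter = 0
    for prom in promoters:
        if prom.sequence is None:
            raise ValueError(f"{prom.gene_id}: promoter has no sequence")
        seq = np.frombuffer(prom.sequence.encode("ascii"), dtype=np.uint8)
        offsets = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        planted = prom.gene_id in truth.planted_genes
        if planted and len(offsets) == 0:
            raise ValueError(f"planted gene {prom.gene_id} has no CpG site in its promoter")
        base = CLASS_BASELINE_BETA[truth.promoter_class_by_gene[prom.gene_id]]
        shift = 0.0
        if prom.gene_id in truth.planted_down_hyper:
            shift = config.beta_shift_effect
        elif prom.gene_id in truth.planted_up_hypo:
            shift = -config.beta_shift_effect
        site_means = np.clip(base + rng.normal(0.0, 0.03, size=len(offsets)), 0.02, 0.98)
        case_means = np.clip(site_means + shift, 0.02, 0.98)
        for off, m_ctrl, m_case in zip(offsets, site_means, case_means):
            mean_vec = np.full(len(samples), m_ctrl)
            mean_vec[n_ctrl:] = m_case
            a = mean_vec * config.beta_concentration
            b = (1.0 - mean_vec) * config.beta_concentration
            betas.append(rng.beta(a, b))
            manifest_rows.append(
                {
                    "site_id": f"cg{site_counter:06d}",
                    "chrom": prom.chrom,
                    "pos": prom.start + int(off),
                }
            )
            site_counter += 1
    manifest = pd.DataFrame(manifest_rows, columns=["site_id", "chrom", "pos"])
    beta = pd.DataFrame(
        np.asarray(betas), index=manifest["site_id"].to_numpy(), columns=samples
    )
    beta.index.name = "site_id"
    return beta, manifest


def simulate_expression(
    genes: list[GeneModel],
    truth: Truth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_ctrl: int | None = None,
    n_case: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2-scale expression matrices (features x samples) for mRNA and lncRNA.

    Case samples of planted up-regulated genes are shifted by
    ``+expr_log2fc_effect`` (down-regulated by the negative); each planted
    co-expression pair shares a per-sample latent factor with small residual
    noise so its sample-wise correlation is ~0.998 in expectation.
    """
    if rng is None:
        rng = _stage_rng(config, 3)
    n_ctrl = config.n_samples_ctrl_expr if n_ctrl is None else n_ctrl
    n_case = config.n_samples_uc_expr if n_case is None else n_case
    samples = _sample_ids(n_ctrl, n_case, "expr")
    n_samp = n_ctrl + n_case
    edge_genes: dict[str, int] = {}
    for k, (lnc_id, mrna_id) in enumerate(sorted(truth.planted_edges)):
        edge_genes[lnc_id] = k
        edge_genes[mrna_id] = k
    latent = rng.normal(0.0, _EDGE_LATENT_SD, size=(len(truth.planted_edges), n_samp))

    values = {}
    for gene in genes:
        base = rng.normal(8.0, 1.5)
        sd = _EDGE_NOISE_SD if gene.gene_id in edge_genes else config.expr_sd
        x = base + rng.normal(0.0, sd, size=n_samp)
        if gene.gene_id in truth.planted_up_hypo:
            x[n_ctrl:] += config.expr_log2fc_effect
        elif gene.gene_id in truth.planted_down_hyper:
            x[n_ctrl:] -= config.expr_log2fc_effect
        if gene.gene_id in edge_genes:
            x = x + latent[edge_genes[gene.gene_id]]
        values[gene.gene_id] = x
    mrna_ids = [g.gene_id for g in genes if g.biotype == "mRNA"]
    lnc_ids = [g.gene_id for g in genes if g.biotype == "lncRNA"]
    expr_mrna = pd.DataFrame(
        np.array([values[g] for g in mrna_ids]), index=mrna_ids, columns=samples
    )
    expr_lnc = pd.DataFrame(
        np.array([values[g] for g in lnc_ids]), index=lnc_ids, columns=samples
    )
    expr_mrna.index.name = expr_lnc.index.name = "feature_id"
    return expr_mrna, expr_lnc


def simulate_diagnostic_cohort(
    panel: list[str],
    informative: set[str],
    n_ctrl: int,
    n_case: int,
    effect: float,
    sd: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One samples x predictors expression table with binary labels.

    Genes in ``informative`` are shifted by ``effect`` in cases; the rest are
    pure noise.  Used to demonstrate the diagnostic model on train/test
    cohorts drawn from the same truth.
    """
    n = n_ctrl + n_case
    y = np.concatenate([np.zeros(n_ctrl, dtype=int), np.ones(n_case, dtype=int)])
    cols = {}
    for g in panel:
        x = rng.normal(8.0, sd, size=n)
        if g in informative:
            x[n_ctrl:] += effect
        cols[g] = x
    X = pd.DataFrame(cols, index=[f"s{i + 1}" for i in range(n)])
    return X, y


# ---------------------------------------------------------------------------
# cohort bundle and on-disk fixture


@dataclass
class Cohort:
    config: SimConfig
    genes: list[GeneModel]
    promoters: list[PromoterRecord]
    truth: Truth
    beta: pd.DataFrame
    sites: pd.DataFrame
    expr_mrna: pd.DataFrame
    expr_lncrna: pd.DataFrame

    @property
    def samples(self) -> pd.DataFrame:
        rows = []
        for s in self.expr_mrna.columns:
            rows.append({"sample_id": s, "group": "uc" if "_uc_" in s else "ctrl", "assay": "expr"})
        for s in self.beta.columns:
            rows.append({"sample_id": s, "group": "uc" if "_uc_" in s else "ctrl", "assay": "meth"})
        return pd.DataFrame(rows, columns=["sample_id", "group", "assay"])


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run every simulation stage and bundle the results."""
    genes, truth = simulate_genes(config)
    promoters = build_promoters(genes, truth, config)
    beta, sites = simulate_methylation(promoters, truth, config)
    expr_mrna, expr_lnc = simulate_expression(genes, truth, config)
    return Cohort(config, genes, promoters, truth, beta, sites, expr_mrna, expr_lnc)


FIXTURE_FILES = (
    "genes.bed",
    "promoters.fa",
    "beta.tsv",
    "sites.tsv",
    "expr_mrna.tsv",
    "expr_lncrna.tsv",
    "samples.tsv",
    "truth.json",
)


def write_fixture(cohort: Cohort, outdir: str | Path) -> Path:
    """Serialise the cohort as plain-text files re-readable by every stage."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_genes_bed(cohort.genes, out / "genes.bed", out / "genes_biotype.tsv")
    mio.write_fasta(
        {p.gene_id: p.sequence for p in cohort.promoters if p.sequence}, out / "promoters.fa"
    )
    mio.write_matrix(cohort.beta, out / "beta.tsv", index_label="site_id")
    cohort.sites.to_csv(out / "sites.tsv", sep="\t", index=False)
    mio.write_matrix(cohort.expr_mrna, out / "expr_mrna.tsv")
    mio.write_matrix(cohort.expr_lncrna, out / "expr_lncrna.tsv")
    cohort.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    cohort.truth.to_json(out / "truth.json")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1)
    return out
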
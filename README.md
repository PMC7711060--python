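# methex

Integrated promoter-methylation / expression analysis for two-group disease
cohorts, built around the workflow used to screen candidate RNA biomarkers in
ulcerative colitis (UC): classify gene promoters by CpG density, call
differentially expressed mRNAs and lncRNAs, call differentially methylated
promoters by rank, intersect the two into direction-concordant candidate
markers, build a thresholded lncRNA–mRNA co-expression network, and evaluate
a logistic diagnostic model. A synthetic-cohort simulator with planted ground
truth makes the entire pipeline testable end to end without any external
data.

## The analysis

**Promoters and CpG density.** A promoter is the strand-relative interval
from 1500 bp upstream to 500 bp downstream of the TSS. Scanning every 500-bp
window of its sequence, with the observed/expected CpG ratio

```
CpG ratio = (#CpG × L) / (#C × #G)
```

a promoter is **HCP** (high-CpG) if some window has CpG ratio > 0.75 *and*
GC content > 0.55, **LCP** (low-CpG) if no window has CpG ratio > 0.48, and
**ICP** (intermediate) otherwise.

**Differential expression.** Quantile-normalised log2 intensities are tested
per feature with an equal-variance two-sample t-test and Benjamini–Hochberg
adjustment (separately within mRNAs and lncRNAs); a feature is called DE
when |log2FC| > 1 and FDR < 0.05 (strict).

**Differential methylation.** Promoter methylation is the mean beta value of
the CpG sites inside the promoter interval. Promoters are ranked by the
case-vs-control t-statistic and the extreme 5% tails are called
hyper-/hypo-methylated (a rank call, not a p-value call), separately per
RNA type.

**Integration.** Candidate markers are features that are DE, carry a DMP
call, and are direction-concordant with promoter repression: up-regulated
with hypo-methylated promoter, or down-regulated with hyper-methylated
promoter.

**Network and diagnostics.** Candidate lncRNA × mRNA pairs with Pearson
r > 0.98 and p < 0.01 across samples become co-expression edges; hubs are
ranked by degree. A maximum-likelihood logistic model over a small gene
panel is scored by ROC/AUC on held-out samples, and qPCR fold changes are
computed with the 2^−ΔΔCt rule.

## Worked example

One command simulates a default cohort (120 mRNAs + 80 lncRNAs; 3 vs 3
expression samples, 3 vs 8 methylation samples; 12 planted differential
genes and 4 planted co-expression pairs) and runs every stage:

```bash
methex run-all --outdir demo --seed 1
```

prints the stage-count ledger

```json
{
 "n_genes": 200,
 "n_sites": 16425,
 "n_classified": 200,
 "n_de_mrna": 6,
 "n_de_lncrna": 4,
 "n_dmp_calls": 20,
 "n_candidates": 10,
 "n_edges": 12,
 "n_nodes": 10,
 "panel": ["MR0029", "MR0058", "MR0061"],
 "auc_train": 1.0,
 "auc_test": 1.0
}
```

Reading it: all 200 generated promoters were classified (and match their
generated class); the t-test/FDR screen recovered 6 DE mRNAs and 4 DE
lncRNAs at n = 3 vs 3; the 5% rank tails called 20 DMPs; 10 features
survived the concordance intersection (of 12 planted); the network over the
candidates has 12 edges, e.g.

```
lncrna_id  mrna_id  r        p          n
LNC0046    MR0061   0.99523  3.41e-05   6
```

and a 3-mRNA hub panel separates held-out synthetic cases from controls
perfectly (test AUC 1.0). Every stage is also available as a standalone
subcommand (`simulate`, `classify-promoters`, `de`, `dmp`, `integrate`,
`network`, `diagnose`, `ddct`) and as plain library functions.

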
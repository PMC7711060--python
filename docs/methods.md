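# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical conventions at the edges.

## Promoter derivation and CpG-density classes

Promoters are the interval −1500/+500 bp around the TSS, strand-relative
(for a "−" gene the genomic interval is mirrored), 0-based half-open,
clipped at chromosome edges. Classification scans 500-bp windows of the
forward-strand sequence; CpG dinucleotides read the same on both strands,
so no reverse-complement pass is needed — a property asserted by test.

The CpG ratio of a window of length L is the observed/expected form
(#CpG × L) / (#C × #G), the standard normalisation under which the 0.75 and
0.48 thresholds are meaningful; it returns 0 when the window lacks C or G,
and `N` bases count toward L only. Thresholds are strict inequalities:
HCP requires some window with ratio > 0.75 *and* GC > 0.55; LCP requires no
window with ratio > 0.48; ICP is the remainder. Because 0.75 > 0.48, an
HCP-qualifying window always defeats the LCP criterion, so the three
classes partition the input.

The window step defaults to 1 bp: "contains at least one 500-bp region" is
an existential claim and the exhaustive scan is its faithful reading. The
scan is vectorised with prefix sums, so exhaustiveness costs little; a
`step` parameter exists for very long inputs, and a regression test checks
that step 5 agrees with step 1 on ≥99% of a simulated panel.

## Differential expression

Inputs are features × samples log2 intensities (linear input is transformed
with log2(x + 1)). Quantile normalisation maps each column onto the
row-mean of the sorted columns, with ties receiving the mean of the
reference values at their tied ranks; it is idempotent and equalises column
sums, both asserted. An upper-quartile scaling alternative is provided for
users who prefer 75th-percentile normalisation.

Per feature, an ordinary equal-variance two-sample t-test compares case vs
control, with Benjamini–Hochberg adjustment across the features of one
call — running mRNAs and lncRNAs separately yields per-RNA-type FDR,
mirroring how DEM and DEL sets are reported separately. A feature is DE
when |log2FC| > 1 and FDR < 0.05, both strict, so an effect of exactly 1 is
not called. Zero-variance features get p = 1 when the group means agree and
p = 0 (t = ±∞) otherwise — the t-test limit — and the |log2FC| > 1 gate
keeps such degenerate features from becoming spurious calls.

The unmoderated t-test is a deliberate simplification: with n = 3 vs 3 its
per-feature variance estimates are noisy, which empirical-Bayes moderation
(limma-style) would shrink. The tests therefore validate *ranking* and
calibration properties rather than absolute power at tiny n.

A caveat worth knowing: at desk-scale feature counts (hundreds rather than
tens of thousands), quantile normalisation can map a feature to identical
values in every sample of a group (its rank never changes), producing
zero-variance artifacts. The pipeline still normalises by default for
fidelity to array practice, but the simulator's matrices are drawn from a
common distribution, so analyses of simulated data may run the t-test on
the raw log2 matrix.

## Promoter methylation and rank-based DMP calls

A CpG site belongs to a promoter iff start ≤ pos < end (a site on two
overlapping promoters would count for both). Promoter methylation per
sample is the arithmetic mean beta over its sites, skipping missing values;
a promoter is dropped only when an entire group is missing.

DMP calling is a rank procedure: promoters are ordered by the equal-variance
t-statistic (case − ctrl) and the top and bottom k are called hyper- and
hypo-methylated, k = round(tail_fraction × n) with half-up rounding,
default tail 5%. Ranking runs separately within mRNA-gene and lncRNA-gene
promoters. Ties in t break by |Δβ| then gene id, so the calls are
deterministic; swapping group labels exchanges the hyper and hypo sets
exactly. The signed t-statistic (not |t|, not Δβ) is the default ranking
statistic; `rank_by="delta"` switches to the mean-beta difference, and a
Welch option exists behind `equal_var=False`. The published grand totals
are internally inconsistent with any single symmetric tail rule (797 vs 798
and 836 vs 837), so the rule here is explicit and configurable rather than
reverse-engineered.

The cross-tabulation writer reports, per biotype × CpG class, the promoter
total and hyper/hypo counts with percentages rounded to two decimals; the
percentages always recompute from their own counts.

## Integration and the co-expression network

Candidates are the inner join of DE features and DMP promoters by gene id,
filtered to the two repression-concordant combinations (up ↔ hypo,
down ↔ hyper). DE features lacking promoter methylation data simply cannot
become candidates. The candidate set is therefore a subset of both input
sets, and loosening the fold-change cut can only grow it — both asserted.

Edges test every candidate lncRNA × candidate mRNA pair: Pearson r across
all samples with the two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df
(r = ±1 → p = 0). The retention rule is strict signed r > 0.98 and
p < 0.01 — "correlation above 0.98" read literally as positive
co-expression; `absolute=True` offers |r|. At n = 6, r > 0.98 corresponds
to p ≈ 1.5 × 10⁻⁴, so the correlation threshold dominates the joint filter.
Correlation is computed over all samples of both groups, the only reading
consistent with those p-values at n = 6. Hubs are nodes sorted by degree,
ties by id.

## Diagnostic model and qPCR

The logistic model is a plain maximum-likelihood fit (no regularisation, as
a default `glm`) by IRLS, converging when the largest coefficient change
drops below 1e-8, capped at 100 iterations. Perfect separation — diverging
coefficients, or every fitted probability saturating at its label — is
flagged `converged=False` with a warning; predictions remain usable because
the probabilities simply saturate. A grid-search likelihood oracle and an
independent GLM implementation (statsmodels) cross-check the fit in tests.

AUC is the normalised Mann–Whitney statistic with ties counted 0.5, which
equals trapezoidal integration of the ROC step curve (asserted to 1e-12);
thresholds sweep the unique scores plus a +∞ endpoint. The original study
trains on one accession and tests on another; this package demonstrates
the procedure on synthetic train/test cohorts drawn from a shared truth
(default 20 + 20 samples per cohort) — cross-platform harmonisation is out
of scope. qPCR relative expression is 2^−ΔΔCt with ΔCt = Ct(target) −
Ct(reference) per condition, reference gene configurable (GAPDH by
convention).

## The synthetic cohort

The simulator emulates the emulated study's *structure*, not its content:

* **Design**: 3 control vs 3 case expression samples and 3 control vs 8
  case methylation samples by default (separate cohorts, joined only by
  gene identity, as in the study design); 120 mRNA + 80 lncRNA genes tiled
  on one synthetic chromosome with ≥1-kb gaps so promoters never overlap;
  alternating strands.
* **Promoter sequences** are drawn per target class — iid bases at a
  class-typical GC content with CpG dinucleotides explicitly thinned (iid
  sequences have observed/expected ≈ 1, so depletion must be simulated):
  HCP ≈ 60% GC with no thinning, ICP ≈ 46% GC with 40% of CpGs broken,
  LCP ≈ 40% GC with 90% broken. Each draw is verified against the
  classifier and resampled on mismatch, so generated class equals
  classified class by construction.
* **Methylation**: sites are the CG positions of each promoter; per-site
  means sit near class baselines 0.15 (HCP), 0.50 (ICP), 0.80 (LCP) —
  the canonical CpG-density/methylation gradient — with Beta-distributed
  noise at concentration 50 (site-level sd ≈ 0.07 at mid-range), bounded
  support matching array beta values. Planted promoters shift by ±0.3 in
  cases. Planted genes are drawn from ICP promoters so the shift stays
  inside [0, 1] around the mid-range baseline.
* **Expression**: log2 intensities with per-gene baselines ~N(8, 1.5) and
  replicate noise sd 0.1 (typical array replicate scale); planted genes
  shift by ±2 log2 units in cases, anti-correlated with their planted
  methylation direction (up ↔ hypo, down ↔ hyper).
* **Co-expression pairs** share a per-sample latent factor (sd 2.5) with
  small residual noise (sd 0.1), putting the population correlation near
  0.998 so most pairs survive the r > 0.98 filter even at n = 6. Edge
  pairs are kept disjoint from planted differential genes: the latent
  factor acts as within-group variance and would mask a planted fold
  change at these group sizes.
* **Seeding**: one root seed; each stage derives its generator through the
  seed-sequence spawn mechanism, so fixtures are byte-identical across
  runs with the same config.

What the simulator does **not** emulate: Infinium type I/II probe
chemistry, batch and platform effects, realistic chromosome structure,
transcript multiplicity per gene, or technical distribution shifts between
samples (hence normalisation is a no-op in expectation on simulated data).
Passing tests therefore demonstrate the correctness and calibration of the
procedures, not their power on real arrays.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use cohorts of 60–200 genes: 20 seeds for DMP recovery
(≥95% of promoters planted at Δβ = 0.3 recovered in the called tails),
50 seeds for planted-edge retention (≥90%) and specificity (≤1% spurious
over ~11,000 null pairs), 50 seeds for planted-DE top-ranking (≥90%), and
30 seeds for the diagnostic model's held-out AUC (median > 0.9; the AUC
fixture uses effect 2.0 with sd 0.5 so the check exercises a non-trivial
classifier rather than a separable one). Null calibration uses 1000
features (raw p < 0.05 fraction within [0.03, 0.07]) and a no-effect
pipeline run (zero candidates at the default joint thresholds). These
sizes keep the whole suite under a minute while leaving the binomial
tolerances meaningful.

## Known limitations

* The unmoderated t-test at n = 3 vs 3 has low power; real studies at this
  size should prefer moderated variance estimators.
* Rank-based DMP calling always calls 2k promoters regardless of signal;
  it is a screening rule, not an error-controlled test.
* The r > 0.98 edge rule at n = 6 admits pairs whose correlation is driven
  by the shared disease effect rather than co-regulation; the network is a
  hypothesis-generating object.
* Percentage formatting follows round-half-even (Python's `round`) to two
  decimals; published tables that used half-up rounding could differ by
  0.01 in edge cases.
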
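# Methods

## The decomposition

The package analyses a 2×2 factorial expression design — arm ∈ {treated,
control} × day ∈ {early, late}, with r replicates per cell — entirely in
log₂(TPM+1) space. Write the cell-mean vector of gene g as μ(arm, day).
Four per-gene effect vectors summarize the design:

    t   = μ(control, late) − μ(control, early)     control-arm time effect
    t*  = μ(treated, late) − μ(treated, early)     treated-arm time effect
    h2  = μ(treated, early) − μ(control, early)    treatment effect, early day
    h7  = μ(treated, late) − μ(control, late)      treatment effect, late day

Since the late treated cell can be reached along either path from the early
control cell, h7 − h2 = t* − t holds *exactly*; the implementation verifies
this closure on every run (it is pure arithmetic on means, so the residual
is rounding-level, ≤ ~1e−15). The scientific hypotheses — that both arms
share one temporal program (t ∝ t*) and that the treatment effect drifts
over time (h7 vs h2) — are operationalized three ways, none privileged:
cosine similarity, the least-squares scalar b minimizing ‖v₂ − b·v₁‖, and a
Jaccard overlap of sets obtained by thresholding each vector at ±1.0 log₂
units (`set_threshold`; the paper-level practical proxy is the DEG Venn
below, which is computed separately and does not use this threshold).

## DEG selection

Each comparison uses Cohen's d with the pooled denominator

    d = (M_X − M_Y) / sqrt((n_X s_X² + n_Y s_Y²) / (n_X + n_Y)),

where s_X, s_Y are (n−1)-denominator sample SDs. Note the pooled form
weights the variances by n (not n−1): the formula is implemented exactly in
this shape rather than replaced by the textbook pooled-SD variant. A `ddof`
flag switches the inner SDs to population (n-denominator) form for
sensitivity analyses. Degenerate genes with zero pooled variance resolve by
sign: d = ±∞ when the means differ, d = 0 when they agree — this makes the
exactly-noiseless limit fully deterministic and well tested. Up = d > 0.8,
down = d < −0.8; X is always the "later/treated" population (late day in
time comparisons, treated arm in cross-sectional ones), so positive d means
higher late/treated expression. No multiplicity correction is applied at
this step: selection is an effect-size cutoff, not a test.

### How noisy is the cutoff at small n

d is scale-invariant, so its null sampling distribution depends only on the
replicate count. At r = 4 vs 4, the null one-sided exceedance
P(d > 0.8 | no effect) ≈ 0.15 (d behaves like 0.707·t₆ to first order).
Consequences, all reproduced by the test suite and acceptance script:

* exclusive Venn cells absorb ≈ 13% of null genes each and ≈ 2.3% land in
  common cells, so cell *precision* against planted classes is low
  (≈ 0.22–0.56 at the default scale) even though *recall* is high (≥ 0.8);
* lowering the noise SD does not help: an early-effect gene's inactive-day
  comparison is a pure null at every positive noise level, so ≈ 15% of
  early/delayed genes co-trigger at the other day and shift into the
  constant cell regardless of how small the noise is;
* with few replicates the exclusive time-axis cells can outgrow the common
  cell even when a genuine shared program exists, unless the shared program
  involves many more genes than the null background. Users should read cell
  sizes with these base rates in mind (or raise r; precision ≥ 0.8 at this
  threshold needs roughly 16 replicates per cell).

This is a faithful property of effect-size-cutoff selection, not an
implementation artifact; the package reports per-cell counts, an optional
normalized-entropy evenness score, and (for synthetic runs) full
precision/recall/F1 tables so the operating characteristics are visible.

## Venn stratification

Up- and down-sets are partitioned by exact set algebra. "Common" always
means same-direction regulation in both comparisons; a gene up in one
comparison and down in the other lands in the two respective exclusive
cells. Within one comparison up and down are mutually exclusive by
construction.

Two identifiability facts about the scheme (deterministic in the exact
zero-variance limit, and tested there): a gene whose temporal shift exists
in only one arm is indistinguishable from a delayed (or early-fading)
treatment effect in the cross-sectional contrasts, and treatment effects
that change between days necessarily appear in the treated arm's
longitudinal contrast. The two axes are complementary views of one design,
not independent measurements.

## Over-representation analysis

One-sided upper-tail hypergeometric probability P(X ≥ k) for overlap k
between a cell's gene set (size n) and a term (size K) in universe N,
computed with `scipy.stats.hypergeom` and verified against exhaustive
enumeration of all draws for every N ≤ 12. The default universe is the
annotated ∩ measured genes ("measured" policy), switchable to all annotated
genes; the measured background is the statistically defensible default.
Correction is Benjamini–Hochberg (step-up, via statsmodels) or Bonferroni —
deliberately a standard, reproducible correction rather than any
tool-specific simulation-calibrated scheme. Term-size filters default to
3..2000. Tables sort by (adjusted p, raw p, term id); `top_terms` takes the
first N of significant rows by default, with a flag to rank all rows.
Because the hypergeometric test is discrete its achievable size is below
the nominal level for small terms; the calibration check therefore uses
terms large enough relative to the universe (a few hundred genes in a
universe of 4000, subset 250) that the exact size at 0.05 is ≈ 0.047–0.050,
making the nominal 5% reference meaningful.

## Term-related-gene counts

For selected terms (by default: terms unique to the common time-axis cell,
and the innermost intersection of the treatment-axis top-term Venn) the
package counts |members(term) ∩ cell| for every cell — raw counts, no
normalization, restricted to the measured universe by default (flag to use
the full annotation). The dominance check requires the reference cell to
*strictly* out-count every other cell; ties fail. This is the conservative
reading of "by far the greatest".

## Synthetic data

`simulate_expression` draws gene baselines from Normal(5, 2) log₂ units
truncated at 0 (typical bulk log-TPM magnitudes), adds class-specific mean
shifts of ±2.0 log₂ units, and i.i.d. Normal(0, 0.5) noise per measurement,
flooring final values at 0. Defaults: 5000 genes, 4 replicates per cell,
days {2, 7}; a 300-gene shared temporal program (150 up, 150 down in both
arms), 50 arm-exclusive temporal genes per arm (upward at the late day by
convention — the class has no direction suffix), and 200 genes in each of
the six treatment-effect classes (early/constant/delayed × up/down).
Simulation is done directly in log space because every downstream statistic
lives there; there is deliberately no count layer, no library-size or
composition artifacts, no batch effects, and no gene–gene correlation.
Passing recovery tests therefore shows the pipeline recovers planted mean
structure under i.i.d. log-scale noise — not that it is robust to the
correlation structure, outliers, or annotation incompleteness of real data.
Real tissue time courses can also move far more genes than the default
shared program does, which changes the relative size of common vs exclusive
cells substantially.

`simulate_annotation` builds terms of ~30 genes (`genes_per_term`) that
draw a fraction `term_purity` (default 1.0) from one planted class and the
rest uniformly elsewhere, plus uniform background terms; when a class is
smaller than requested the term shrinks rather than diluting its purity.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; the pipeline derives the annotation seed from the simulation
  seed so stages never perturb each other's draws. Two runs with one config
  and seed write byte-identical tables (no timestamps in any table).
* PCA (scikit-learn, full SVD) is centered but not variance-scaled by
  default (flag available); each component's sign is fixed by making the
  largest-|loading| gene positive, so score plots and extreme-gene lists
  are deterministic across platforms. Loading ties break lexicographically.
* Matrix files round-trip bit-exactly (readers use round-trip float
  parsing). The raw-TPM loader applies NaN→0 *then* log₂(TPM+1), exactly
  once; processed matrices are re-read by a separate function so the
  transform cannot be applied twice.
* Enrichment of an empty (or fully unannotated) subset returns a structured
  empty table with a warning rather than an error; zero-norm effect vectors
  report NaN similarity with a warning.

## Limitations

Exactly two levels per factor (the scheme is pairwise); no moderated or
shrunken effect sizes; no GO-graph propagation (the annotation file is
taken as given); no statistical test on term-related-gene count
differences; no figures — outputs are tables and gene/term lists. The
collinearity scalars are descriptive operationalizations, not estimators
with standard errors.
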
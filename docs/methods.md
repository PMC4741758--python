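# Methods

## Model and assumptions

`immfocus` treats a bulk tumor expression profile as a two-component
mixture. For gene *g* and biopsy *s* the package assumes

    x(g, s) ≈ m_g · w(g, s) · ε(g, s)

where *m_g* is a gene-specific baseline, ε is multiplicative measurement
noise, and the weight *w* is proportional to the biopsy's immune-cell
fraction φ_s for genes expressed by the immune compartment and is
independent of φ_s for tumor-intrinsic genes. Under this model the mean
abundance of a set of immune-tracking genes is an estimator of φ_s (up to
a constant), and dividing by it cancels the sampling nuisance for immune
genes while injecting 1/φ_s noise into non-immune genes — which is what
the CVR screen detects.

Assumptions that matter in practice:

* the anchor (PTPRC/CD45 by default) is expressed by essentially all
  immune cells and little else, so its abundance is a noisy readout of
  total immune content;
* input values are nonnegative abundances on a linear scale, already
  comparable across samples (e.g. RSEM normalized counts). No
  between-sample library-size renormalization is applied. A log2(x+1)
  switch exists in `immfocus.io` but is off: the CV magnitudes the method
  relies on are only meaningful on the linear scale;
* survival follows standard right-censoring; the log-rank test is the
  unstratified Mantel–Haenszel form with hypergeometric variance and no
  continuity correction, the conventional default of survival toolkits.

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `anchor` | `PTPRC` | pan-leukocyte marker; configurable, so a subset marker (e.g. a T-cell gene) derives a subset-specific signature |
| `r2_threshold` | 0.5 | provisional-set cut on squared Pearson correlation with the anchor; strictly `>` |
| `require_positive` | on | anti-correlated genes would *anti*-track immune content; a flag restores the literal r²-only rule |
| `cvr_threshold` | 0.8 | refinement keeps genes with CVR ≤ 0.8 (strictly greater values are omitted) |
| `group_size` | 500 | size of the CVR-low/high/random evaluation groups |
| `alpha` | 0.05 | family-wise level; Bonferroni divides by the number of genes with a defined test (Benjamini–Hochberg optional) |
| tertile size | floor(N/3) | symmetric and standard; ties in expression are broken by sample id so stratification is deterministic |

Refinement is a single pass: leave-one-out factors come from the
provisional set, and genes above the CVR threshold are dropped once. An
iterate-to-fixpoint mode exists but is off — the single pass is the
method's definition, and iterating changes membership only marginally on
simulated cohorts. The final factors are computed once from the final
INGS and reused for every gene; refinement-time factors are internal to
the derivation.

## Numerical conventions

* CV uses the sample (n−1) standard deviation over the mean; genes with
  nonpositive mean or zero raw variance are excluded from ranking rather
  than assigned infinite CVR.
* Zero raw values stay zero after normalization; no pseudocounts — the
  normalization is a ratio, not a transform.
* p-values are floored at 1e−300 before the LOD log-ratio.
* The 2×2 clinical χ² tests apply the Yates continuity correction; the
  k×2 enrichment χ² does not (df > 1). A `legacy_rounding` option
  reproduces the convention of published per-gene stage tables (raw p
  rounded to 4 decimals, then ×n_tests, capped at 1); it exists only for
  that reproduction and is off for new analyses.
* Sample order is fixed to sorted sample ids at alignment; the CVR-random
  group and the simulation are driven by explicit seeds recorded in the
  outputs. Group-boundary ties rank by (CVR, gene id).
* For the normalized-data survival test, tertile groups are re-derived
  from normalized ranks (stratification is "by expression of the dataset
  tested"). A fixed-grouping mode reuses the raw-derived groups; since
  the log-rank statistic depends only on group membership, that mode
  necessarily reproduces the raw p-value and serves as a consistency
  check rather than an analysis option.

## The synthetic cohort generator

`immfocus.simulate` draws cohorts directly from the mixture model above,
plus a latent immune *activity* a_s ~ N(0, 1) that captures the
biologically meaningful state of the immune compartment:

* φ_s ~ Beta(2, 5) (mean ≈ 0.29, typical of moderately infiltrated
  tumors); baselines m_g lognormal(ln 500, 1.5²) spanning the RSEM range;
  mean-1 lognormal noise with CV 0.15;
* 150 immune genes and the anchor scale with φ_s; 20 prognostic-immune
  genes scale with φ_s·exp(γ_g a_s), |γ_g| = 0.5 with alternating signs
  (half protective, half deleterious, as observed in real cohorts);
  the remaining genes are tumor-intrinsic (w = 1);
* survival is exponential with log-hazard 0.8·a_s around a median of
  ~1200 days, with uniform censoring calibrated to a 50% censored
  fraction; age/gender are independent; stage can optionally be linked to
  a_s through a logit model.

Because hazard depends only on a_s while raw immune-gene expression mixes
φ_s and a_s, raw expression is confounded by biopsy composition — the
exact nuisance the method claims to remove. The alternating γ signs also
keep the derived factor free of any systematic activity component, so
tumor genes remain clean survival nulls.

What the generator does **not** emulate: correlated co-expression modules
within the tumor compartment, tumor-intrinsic prognostic programs,
cell-subtype structure inside the immune block, count-level technical
artifacts, or batch effects. Passing tests therefore demonstrate that the
pipeline recovers its own generative model under realistic noise — not
that a real cohort satisfies that model.

Expected behavior at the defaults (480 samples, 2000 genes), measured by
the test suite and `scripts/acceptance.py` rather than asserted here:
signature precision, factor–fraction correlation, immune-vs-tumor CVR
separation, null calibration of the screen over 200 replicates, and
median LOD over 50 replicate cohorts for prognostic-immune vs tumor
genes. Problem sizes (2000 genes rather than a full transcriptome, 5
null genes per calibration replicate, 20 tumor genes per LOD replicate)
were chosen so the whole evaluation stays desk-scale while keeping every
estimate's Monte-Carlo error well inside its decision margin.

One caveat is worth stating explicitly: for truly null tumor genes the
LOD distribution is symmetric about zero (both stratifications are
independent of survival), so the *sign* of a finite-sample median LOD
over tumor genes is a coin flip concentrated near zero. The meaningful
claim — and the one the prognostic-immune side tests sharply — is that
normalization systematically improves confounded immune genes while
leaving nulls centred at zero.

## Design choices on genuinely open points

* **Correlation sign.** Whether the original signature derivation used
  r > 0 or |r| cannot be settled from a frozen snapshot; both modes are
  provided, with the positive-only rule as the default because a factor
  averaging anti-correlated genes would not estimate immune content.
* **Bonferroni denominator.** Defaults to the size of the scanned gene
  set (per-group in the grouped design), configurable, with undefined
  tests excluded when counting.
* **Stage-table contingency.** Rows are the low/high expression tertiles
  and columns the combined early (I+II) vs late (III+IV) stages; unknown
  stage/gender/age are dropped per-test, never imputed.
* **Library use.** χ², t, Fisher and distribution functions come from
  scipy; BH from statsmodels. The product-limit estimator and the
  two-group log-rank are implemented in numpy (they sit directly under
  the LOD statistic and are called thousands of times per scan) and are
  cross-validated in the tests against lifelines and against an exact
  permutation enumeration.

## Limitations

* The method estimates *total* immune content; it cannot separate
  subpopulations unless re-anchored on a subset marker, and genes
  expressed by both tumor and immune cells (e.g. some checkpoint
  ligands) respond poorly to the normalization by construction.
* Survival screening is univariate (no Cox modeling, no multivariate
  adjustment); stage associations are descriptive χ² tests.
* Thresholds (r² > 0.5, CVR ≤ 0.8) are the method's empirical constants,
  not fitted quantities; their sensitivity on a new cancer type should be
  checked by the monotonicity relations the tests encode.
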
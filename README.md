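# immfocus

Immune-content normalization of bulk tumor expression profiles.

## The problem

A tumor biopsy is a mixture: malignant cells plus a variable admixture of
immune and stromal cells. In bulk RNA-seq of such biopsies, much of the
apparent variability of immune-gene expression across patients reflects
*how much immune tissue the biopsy happened to capture*, not the
biological state of the tumor-associated immune compartment. This sampling
noise obscures immune signals that are relevant for prognosis — for
example, the expression of immune-checkpoint genes.

`immfocus` removes this nuisance variation without any reference
deconvolution signature. For whom: computational biologists working with
tumor cohorts of the TCGA kind (an RSEM-normalized gene × sample matrix
plus per-patient survival and staging), who want immune-gene expression
levels that are comparable across biopsies and survival screens that are
not confounded by biopsy composition.

## The method

1. **Immune-normalizing gene set (INGS).** Using the pan-leukocyte marker
   *PTPRC* (CD45) as an anchor, every gene *g* is Pearson-correlated with
   the anchor across samples; genes with *r*² > 0.5 (and *r* > 0 by
   default) form a provisional set. Each provisional gene's CV ratio
   (below) is computed with leave-one-out factors, and genes with
   CVR > 0.8 are dropped, yielding the final INGS.
2. **Per-sample factor.** For sample *s*,
   *f*(*s*) = mean over INGS genes of *x*(*g*, *s*) — a proxy for the
   immune-cell fraction of the biopsy. Every gene is normalized as
   *x*(*g*, *s*) / *f*(*s*); an INGS member *i* is instead divided by the
   leave-one-out factor *f*⁽*i*⁾(*s*) (the mean over INGS ∖ {*i*}) to
   avoid self-normalization.
3. **CVR screening.** For each gene, CVR = CV(normalized) / CV(raw),
   with CV the sample standard deviation over the mean across samples.
   CVR < 1 means normalization reduced the gene's apparent variability —
   the signature of a gene whose variation was driven by immune sampling.
   Three 500-gene groups (lowest CVR, highest CVR, random) support
   enrichment and survival comparisons.
4. **Survival screening.** Per gene, patients are split into bottom and
   top expression tertiles and compared with the Kaplan–Meier / log-rank
   machinery, once on raw and once on normalized values, with Bonferroni
   adjustment (FDR optional). The gain from normalization is
   LOD = ln(*p*′/*p*) with *p*′ the normalized-data p-value; LOD ≤ −2 is a
   more than e² ≈ 7-fold gain in significance.
5. **Clinical associations.** Expression tertiles are tested against
   pathological stage (I+II vs III+IV, Yates-corrected χ²), age
   (Student's t) and gender (χ²), and gene groups against annotation
   lists (k×2 χ² enrichment).

A seeded synthetic-cohort generator (`immfocus.simulate`) produces
tumor/immune mixtures with known per-sample immune fraction, latent
immune activity linked to survival, and lognormal measurement noise, so
every stage of the pipeline is testable without external data.

## Worked example

```python
import numpy as np
import immfocus as im
from immfocus.simulate import SimulationConfig, simulate_cohort

expr, clin, truth = simulate_cohort(SimulationConfig(seed=7))
ings = im.derive_ings(expr)                      # PTPRC-anchored signature
norm = im.normalize(expr, ings)
f = im.compute_factors(expr, ings).f
print(f"INGS size: {len(ings)}")
print(f"corr(f, true immune fraction): {np.corrcoef(f, truth.phi)[0,1]:.3f}")

table = im.compute_cvr_table(expr, norm)
print(f"mean CVR, immune block: {table.loc[truth.genes_of('immune'),'cvr'].mean():.3f}")
print(f"mean CVR, tumor block:  {table.loc[truth.tumor_block,'cvr'].mean():.3f}")

genes = truth.genes_of("prognostic_immune")
scan = im.gene_survival_scan(expr, norm, clin, genes)
print(f"prognostic-immune genes significant (raw):        {int(scan['sig_raw'].sum())}/20")
print(f"prognostic-immune genes significant (normalized): {int(scan['sig_norm'].sum())}/20")
print(f"median LOD: {np.median(scan['lod']):.2f}")
```

Output:

```
INGS size: 151
corr(f, true immune fraction): 0.999
mean CVR, immune block: 0.254
mean CVR, tumor block:  7.513
prognostic-immune genes significant (raw):        20/20
prognostic-immune genes significant (normalized): 20/20
median LOD: -18.83
```

The derived signature is the anchor plus the full 150-gene immune block
(nothing else), its per-sample mean tracks the true immune fraction
almost perfectly, normalization shrinks immune-gene variability ~4-fold
while inflating tumor-gene variability, and the survival association of
the confounded prognostic-immune genes strengthens enormously
(median LOD −18.8, i.e. p-values drop by a factor of e^18.8).

A command-line interface mirrors the library
(`immfocus simulate | build-ings | normalize | cvr | survival-scan |
associate | enrich | run-all`); `run-all` writes every stage's table plus
a manifest and summary into a run directory.

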
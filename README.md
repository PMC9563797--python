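# cdcmeth

Paired blood DNA-methylation analysis for Cri du chat syndrome (5p-deletion)
cohorts, built as a tested, reusable pipeline.

Cri du chat syndrome is caused by a hemizygous deletion of the short arm of
chromosome 5. Comparing genome-wide blood DNA methylation between patients
and matched controls raises several coupled analysis problems, each covered
by a module here:

- **`synthetic`** — a fully specified paired cohort generator: bimodal beta
  baselines, lognormal total array intensities, hemizygous intensity halving
  up to a per-patient 5p breakpoint, promoter hypo-/hyper-methylation planted
  in chosen gene sets (preferentially on bivalent-marked CpGs), detection-p
  failures, covariates, and a truth record for every planted effect.
- **`preprocess`** — detection-p / SNP / sex-chromosome probe filtering with
  per-rule bookkeeping; beta = meth/(meth+unmeth+offset); M = logit2(beta).
- **`diffmeth`** — paired differential methylation. Per-pair M differences
  ΔM are modelled per CpG as ΔM ~ 1 (+ covariates); residual variances are
  shrunk by the empirical-Bayes scaled-inverse-χ² model (prior df d₀ and
  variance s₀² fit by the method of moments on log variances), giving the
  moderated t statistic t = β̂ / (s̃·√v₁₁) with s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g),
  p-values on d₀+d_g degrees of freedom, and Benjamini–Hochberg FDR.
- **`deletion`** — the 5p breakpoint caller: per-CpG log₂(patient total
  signal / mean control total), degree-2 tricube local regression
  (span 0.05), breakpoint = lowest position > 5 Mb where the smoothed track
  recovers above −0.25.
- **`gsea`** — a preranked GSEA engine used at two levels: CpG t-statistics →
  per-gene promoter/gene-body enrichment (weighted KS running sum, random
  same-size permutation null, sign-conditional NES), condensed into the gene
  score sign(NES)·(−log₁₀ p.adj); that score ranking → functional-category
  enrichment, with chromosome-exclusion reruns that re-rank from the t-stage.
- **`ora`** — direction-split (hypo/hyper) hypergeometric over-representation
  of significant CpGs in CpG-category databases (chromHMM, TF binding,
  histone marks, island relation), minGSSize 4, fixed universe.
- **`signatures`** — bivalent-promoter mark counting (EZH2, SUZ12, H3K27me3,
  H3K4me2, H3K4me3), the top-CpG-per-gene heatmap matrix, external-signature
  correlation, linear epigenetic clocks, constrained-least-squares cell
  deconvolution, and PCA QC.

## Worked example

```python
import cdcmeth
from cdcmeth.pipeline import chained_analysis, cohort_m_values

cfg = cdcmeth.SimConfig(
    n_cpgs=7000, n_genes=200, n_categories=15, genes_per_category=20,
    planted_sets=[("SET000", "hypo", 0.2)], seed=1,
)
bundle = cdcmeth.make_annotation(cfg)
intensities, design, truth = cdcmeth.simulate_cohort(bundle, cfg)

M, log = cohort_m_values(intensities, bundle.annotation)
print("filter log:", log)

total = cdcmeth.total_signal(intensities)
calls, _ = cdcmeth.call_patient_deletions(total, design, bundle.annotation,
                                          "chr5", cfg.chr5_centromere)
for c in calls[:3]:
    print(f"{c.patient_id}: called {c.breakpoint/1e6:.2f} Mb, "
          f"true {truth.breakpoints[c.patient_id.lstrip('p')]/1e6:.2f} Mb")

res = chained_analysis(M, design, bundle.annotation, bundle.gene_sets,
                       nperm=500, seed=1)
print(res.categories.sort_values("p_adj")[["nes", "p", "p_adj", "size"]].head(3).round(4))
```

Output:

```
filter log: {'n_input': 7000, 'removed_unannotated': 0, 'removed_detection': 7, 'removed_snp': 0, 'removed_sex': 0, 'n_retained': 6993}
p1: called 13.74 Mb, true 13.59 Mb
p2: called 14.92 Mb, true 14.66 Mb
p3: called 29.62 Mb, true 29.61 Mb
           nes       p   p_adj  size
set_id
SET000 -1.9772  0.0024  0.0355    20
SET001 -1.1585  0.2837  0.4681    20
SET005  1.2318  0.1772  0.4681    20
```

Seven of 7000 simulated probes fail the detection filter; each patient's
deletion breakpoint is recovered to within a few hundred kb; and the one
category with planted promoter hypomethylation (`SET000`) tops the
second-level enrichment with a negative NES (less methylation in patients)
at p.adj < 0.05, while unplanted categories stay null.

A `cdcmeth` command-line interface exposes the same stages
(`simulate`, `preprocess`, `diffmeth`, `deletion`, `gsea`, `enrich`,
`clock`, `cells`, `pca`, `signature`); see `cdcmeth --help`.

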
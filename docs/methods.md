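# Methods

## Scope and model overview

The package analyses paired patient/control DNA-methylation array data for a
5p-deletion (Cri du chat) cohort. The chain is: probe filtering → beta/M
conversion → paired moderated t per CpG → (a) breakpoint calling from total
intensity, (b) two-level preranked GSEA (CpG→gene, gene→category),
(c) directional CpG-category over-representation, (d) downstream
characterisations (bivalent marks, heatmap matrix, clocks, deconvolution,
signature correlation, PCA QC). A synthetic cohort generator supplies data
with the statistical structure the analysis assumes, plus a truth record, so
every stage is testable end to end.

Coordinates are 1-based; intervals are half-open `[start, end)`. Promoters
span TSS−2000..TSS+500. One convention everywhere.

## Preprocessing

A probe is retained iff its detection p-value is below the threshold
(default 0.01) in **every** sample, it is not SNP/cross-reactive-flagged,
and it is not on a sex chromosome; probes missing from the annotation are
dropped and counted. The retained set is exactly the intersection of the
three single-rule sets, so removal counts per rule can overlap.

Beta values use the Illumina offset convention `meth/(meth+unmeth+100)`;
M values are `log2(b/(1−b))` with b clipped to `[1e-6, 1−1e-6]`. The offset
and clip are recorded in the matrix provenance and exposed as flags, since
different array toolchains use slightly different dialects. Normalisation is
a pass-through: the synthetic data needs no dye/background correction, and
the plug-in point keeps the contract explicit for real data.

## Paired moderated t

The paired design is reduced to one-sample inference on the per-pair
difference ΔM (mean over a set's patient samples minus mean over its control
samples, so multi-sample sets collapse to one column). Per CpG g,
ΔM_g ~ 1 (+ set-level covariates) is fit by least squares; the empirical
Bayes model takes s²_g ~ s₀²·χ²_{d_g}/d_g with a scaled-inverse-χ² prior
(d₀, s₀²), estimated by the method of moments on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2):

- trigamma(d₀/2) = Var(e)·G/(G−1) − trigamma(d_g/2), solved by Newton
  iteration on the strictly decreasing trigamma function;
- s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2));
- non-positive excess spread ⇒ d₀ = ∞ (no variance heterogeneity).

The moderated statistic is t = β̂₀ / √(s̃²·v₁₁) with
s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g), two-sided p on d₀+d_g df (normal when
d₀ = ∞), BH-adjusted. The limits are exact: d₀ = 0 reproduces the ordinary
one-sample t; d₀ = ∞ the z statistic with σ = s₀. Covariate adjustment
operates on the per-set differences with set-level covariates (age
difference, sex, cell fractions), preserving the paired structure; the
alternative — adjusting across individual samples — is not implemented.
CpGs that are exactly constant (zero effect and zero variance, which occurs
only in noiseless simulations) are assigned t = 0, p = 1 rather than 0/0.

## Deletion breakpoint caller

One lost allele halves total (meth+unmeth) signal, so the per-CpG
log₂(patient/mean-control) track sits near −1 inside the deleted region.
The track is smoothed by local polynomial regression: for each CpG the
⌈span·N⌉ nearest neighbours (contiguous in 1-D) get tricube distance
weights, a degree-2 polynomial is fit by weighted least squares (offsets
rescaled by the window radius for conditioning), evaluated at the CpG
itself — the classic loess recipe with least-squares fitting and no
robustness iterations. Span defaults to 0.05.

The breakpoint is the lowest position above the telomeric noise guard
(5 Mb) whose smoothed value exceeds −0.25 (half-way between the one- and
two-copy levels). Degenerate cases are made explicit rather than silent:

- a track that never drops below the threshold is flagged `no_deletion`
  (size undefined) instead of yielding a spurious ~5 Mb call — controls run
  through the caller must not acquire deletions;
- no qualifying position at all means the loss extends past the arm
  ("none detected");
- transient dips below the threshold after the first recovery (interstitial
  loss) are logged in `later_dips`, not re-called.

Calls are invariant to common intensity rescaling (the ratio cancels it).
With ~2000 p-arm CpGs and lognormal intensity noise σ = 0.2 the call shows a
small positive bias (~0.25 Mb, the smoothing half-window effect) and is
reliably within ±1 Mb of truth.

## Preranked GSEA engine

Both enrichment levels share one engine. For a ranked list of N items and a
member set of size m, the running sum adds `|r_i|^p / Σ_hits |r_j|^p` at
hits and subtracts `1/(N−m)` at misses (weight exponent p = 1 by default);
ES is the extremum of largest magnitude (exact ties favour the positive
side); the leading edge holds members at or before the extremum (at or
after, for negative ES). The implementation is verified against exhaustive
enumeration of the running sum over all subsets of short lists.

The permutation null draws `nperm` random same-size subsets of the ranked
items without replacement; nulls are cached per set size and seeded per
size, so results do not depend on set iteration order. NES divides the
observed ES by the mean magnitude of same-sign null scores;
p = (#same-sign nulls at least as extreme + 1)/(#same-sign nulls + 1), so p
is never zero; BH across tested sets. Null ES values are computed from the
sorted hit indices alone (the running sum only changes slope at hits),
keeping the null O(m) per permutation.

Level one tests each gene's promoter (or gene-body) CpG set against the
full CpG ranking (min 5 mapped CpGs per gene) and condenses the result into
sign(NES)·(−log₁₀ p.adj), with p.adj floored at 1e-16 so scores stay
finite. Level two ranks genes by that score and tests functional categories
(size window 10–500). Negative NES means less methylation in patients.
Region-exclusion reruns drop the region's CpGs **before** the t-stage, so
ranking, gene scores and category tests all live on the reduced universe.

## Over-representation analysis

Significant CpGs (p < 0.01 by default) are split by direction — hypo means
less methylation in patients (negative t) — and tested per category with
the upper-tail hypergeometric P(X ≥ k) in a fixed universe; categories are
intersected with the universe before the size filter (min 4). The effect
measure is the sample odds ratio of the 2×2 table with a Haldane 0.5
correction when any cell is zero — reported descriptively, the test is the
tail probability. The exclusion rerun recomputes statistics, selection and
universe on the reduced CpG set.

## Signatures

- **Bivalent marks**: per-CpG count over {EZH2, SUZ12, H3K27me3, H3K4me2,
  H3K4me3} with a ≥4/5 and =5/5 summary.
- **Heatmap matrix**: genes in the leading edge of ≥2 of the chosen
  categories; per gene the promoter-leading-edge CpG with the largest |t|
  (ties to the lower probe id); values are per-pair patient-minus-control M
  differences; rows ordered by |t| (an explicit choice — the display order
  is not otherwise determined), truncated to the top 100.
- **Signature correlation**: Pearson r over the CpGs shared with an external
  patient-minus-control delta list; beta-scale deltas by default (M-scale
  input works identically).
- **Clocks**: age = transform⁻¹(intercept + Σ coef·beta); the piecewise
  transform maps m < 0 to (1+a)·e^m − 1 and m ≥ 0 to m·(1+a)+a with anchor
  age a = 20. At least 95 % of clock CpGs must be present; a missing CpG has
  no cohort values, so it is imputed with the per-sample mean beta over the
  present clock CpGs (logged). Coefficient files load generically; no
  published coefficient set ships with the package.
- **Deconvolution**: w = argmin‖b − Aw‖² with w ≥ 0, Σw ≤ 1, solved by
  SLSQP from a non-negative least-squares start — the same model as
  reference-based cell-count estimation, with a testable contract.
- **PCA QC**: SVD of the column-centred top-variance CpG submatrix (top
  20,000 by default; configurable since the input subset is a free choice);
  PC–covariate associations by Pearson correlation (numeric) or rank-sum
  (binary).

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults are the study conditions: 8 patient/control pairs
(multi-sample sets configurable, mirroring paired designs where one member
contributes two samples), chromosomes 1/2/5 at realistic lengths, breakpoints
uniform in 6–35 Mb of the 5p arm (0 = no deletion), total intensity
lognormal (median 5000, σ = 0.2), bimodal beta baseline (Beta(2,18) and its
mirror, half each), per-sample beta noise σ = 0.03, detection failures in
0.1 % of probes (one random sample each), and age/sex covariates independent
of effects unless the confounding flag is set.

Planted effects shift promoter CpGs of the chosen gene sets by ±δ in
patients; planted CpGs keep baseline headroom so the realised mean delta is
δ rather than a clip-truncated value. On top of this, every promoter carries
a per-(gene, pair) background patient-vs-control shift (σ = 0.02 beta),
shared by the promoter's CpGs. This emulates the inter-individual,
regionally correlated epigenetic variation real cohorts show, and it is what
gives the gene-score ranking a continuum; without it the ranking degenerates
to planted-vs-zero and weighted GSEA loses its null resolution. Bivalent
marks are seeded on promoter CpGs (EZH2 fraction 0.10, boosted on planted
genes) with tunable co-occurrence of the other four marks.

Not emulated: probe chemistry (type I/II design, dye bias), background
fluorescence, detection-p computation from control probes, genome-scale CpG
density structure (islands are labels, not sequence-derived), linkage
between covariates and cell composition. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to array artefacts that normalisation handles on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: cohorts of 3,000–8,200
CpGs, 60–200 genes, 15–20 categories, 300–1,000 permutations, 10–20 seeds
per Monte-Carlo claim — sizes chosen so the full suite completes in well
under a minute per stage while keeping each check's Monte-Carlo error far
below its tolerance. Tie-breaks are deterministic everywhere (ranking ties
by item id; heatmap CpG ties by lower probe id; ES sign ties positive).
Seeds flow from a single generator per cohort; GSEA nulls are seeded per
set size. The trigamma inverse uses Newton iteration with the standard
asymptotic endpoints; batched loess adds a 1e-10 ridge on the rescaled
normal equations to guard exactly singular windows.

## Known limitations

- The engine's permutation null is gene-label sampling; competitive
  sample-permutation nulls are out of scope.
- No trend/robust variants of the variance prior.
- The caller assumes a single terminal deletion; interstitial losses are
  logged but not segmented (no CBS/HMM).
- Detection p-values are consumed, never computed.
- Real-database retrieval (GO/DGN, ENCODE, chromHMM) is out of scope; the
  package reads any such database from GMT.
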
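# Methods

## The activity model

`teactivity` treats log2 gene expression as additive in a gene basal level
`c_p`, a sample offset `d_s`, and the summed cis-regulatory contributions of
TE subfamilies, `Σ_m N_pm A_ms`, plus i.i.d. Gaussian noise. The
susceptibility `N_pm` is a fixed, annotation-derived quantity; the activity
`A_ms` is the log2 expression change one integrant of subfamily m confers on
a gene within reach in sample s. Column-centering expression absorbs `d_s`,
row-centering absorbs `c_p`; differencing each treatment/control pair then
cancels everything shared within a pair, leaving the per-pair response

    ΔE'_p = ΔA_0 + Σ_m N_pm ΔA_m + ε.

Replicate pairs are concatenated and the susceptibility matrix row-expanded
to match, which pools information across pairs under one coefficient vector.
The fit is ordinary least squares with an intercept; standard errors come
from `σ̂²(XᵀX)⁻¹` with `σ̂² = RSS/df`, each coefficient is t-tested against
zero, and Benjamini-Hochberg adjustment runs across the subfamily
coefficients only (never the intercept). A subfamily is called
differentially cis-regulatory at adjusted p ≤ 0.05. The overall F-test and
adjusted R² summarize how much genome-wide expression change the TE geometry
explains (typically a few percent, with very small F-test p-values when a
real perturbation is present).

Assumptions worth keeping in mind: activities are linear in integrant count
(the tenth integrant contributes as much as the first); all integrants of a
subfamily share one activity (the functional split below relaxes this);
noise is homoskedastic Gaussian on the log2 scale; and the susceptibility
matrix is treated as known without error.

## Building the susceptibility matrix

TE annotations are read from BED6 or RepeatMasker `.out` (coordinates
converted to 0-based half-open; strand `C` mapped to minus). Because
RepeatMasker fragments degenerate integrants, fragments of one subfamily and
strand separated by **< 100 bp** are merged first; merging is idempotent and
order-invariant.

Per protein-coding gene: transcription start sites are clustered by
single-linkage at spacing **< 1 kb**, each cluster padded by **500 bp** per
side to form promoter regions (stored as a disjoint union; clusters whose
padded intervals abut are unioned — the downstream logic only ever consumes
the union, so this choice is inconsequential). In hard-threshold mode the
cis-regulatory windows are the promoters extended by a **50 kb** flank per
side, and `N_pm` counts merged integrants overlapping any window. In
weighted mode no window is imposed: every same-chromosome integrant
contributes `exp(-x²/2L²)` where `x` is the distance between the integrant's
center (floor of the interval midpoint) and the center of the gene's
*closest* promoter. At the reference bandwidth L = 250 kb this gives weight
0.61 at 250 kb and 0.01 at 750 kb, so contributions effectively vanish
beyond ~3 bandwidths; the weight at 2L, exp(−2) ≈ 0.135, serves as the
cutoff when counting putatively regulated genes per subfamily.

In both modes, integrants overlapping the gene's promoters or exon union are
excluded **per gene** — a TE inside gene A's exon still counts for a
neighboring gene B. This per-gene reading implies that a TE intronic to one
gene can be cis-regulatory for another; the alternative (global exclusion)
would discard such TEs everywhere.

TAD restriction (optional, weighted mode): weights are zeroed when the TE
center and the closest-promoter center fall in different TADs, or either
falls in no TAD. Membership is decided by the center coordinate under
half-open semantics, matching the distance convention.

Filtering: subfamilies whose susceptibility column sums to **< 150** are
removed (strict inequality); in weighted mode the same threshold applies to
the weighted sums. Genes with raw counts < 10 in all samples, and
experimentally perturbed genes (the overexpressed transgene, the CRISPR
target), are removed from the expression side.

## Normalization

Per sample, a pseudocount equal to the **5th percentile of the non-zero raw
counts** of that sample (linear interpolation between order statistics — the
percentile definition is not canonical, so it is recorded here) is added to
every count; counts are divided by gene length — taken as the exon-union
length — scaled to transcripts-per-million, and log2-transformed. The
pseudocount stabilizes the log at weakly expressed genes at the cost of a
mild shrinkage of their fold-changes.

## Bandwidth selection

The bandwidth L is chosen by 5-fold cross-validation **on the gene space**:
folds partition genes (a deterministic function of the gene list and the
seed), and all stacked replicate rows of a gene follow its fold, so no gene
leaks between training and validation. For each candidate L the model is
fit on the training genes and evaluated by RMSE (including the training-fit
intercept) on the held-out genes; the L minimizing the mean RMSE wins, ties
going to the smaller L. To keep errors comparable, all candidates share the
gene and subfamily sets of the unweighted 50 kb-flank matrix after
filtering. The default grid —
{1e3, 5e3, 1e4, 5e4, 1e5, 2.5e5, 5e5, 1e6, 1e7, 1e8, 1e10} bp — spans
1 kb to 10 Gb with the biologically plausible 50–500 kb region densely
covered, and is user-overridable. At extreme bandwidths all columns converge
to near-constant vectors; rank-deficient folds record an infinite RMSE and
are logged rather than silently regularized, since coefficient inference
requires a full-rank design.

## Functional / non-functional splitting

Given a set F of "functional" intervals (e.g. differential ATAC or ChIP
peaks), each merged integrant overlapping F by ≥ 1 bp joins the functional
fraction of its subfamily; the rest form the non-functional fraction. The
two fraction columns are built with exactly the geometry of the unsplit
matrix, so their sum reconstructs the unsplit column (exactly in hard mode,
to rounding in weighted mode) — a conservation property the tests enforce.
Fractions with susceptibility sum **< 100** make unreliable predictors, so
any subfamily with a thin fraction is collapsed back to its unsplit column
unless explicitly protected by the caller. Subfamilies removed by the
main ≥ 150 filter stay removed after splitting.

## DE-enrichment baseline and AUC

The competing detector takes externally called DE genes (the negative
binomial exact-test caller itself is out of scope — any caller's up/down
gene lists can be supplied as TSV), and per subfamily and direction computes
the hypergeometric probability of observing at least as many DE genes among
the genes with `N_pm ≥ 1` in the hard matrix — "near" shares its definition
with the regression's geometry. Up and down tables are concatenated and
BH-adjusted together. Both methods score subfamilies by 1 − (adjusted p) and
are compared by the Mann-Whitney AUC against a known causal subfamily set.
For simulations, `de_from_observed_deltas` provides a lenient stand-in
caller that thresholds the observed per-gene mean delta; deriving labels
from the noisy data (rather than from the generative truth) is what real DE
calling does, and is what makes the comparison informative: the baseline
dichotomizes noisy per-gene evidence, while the regression aggregates
magnitudes.

## Synthetic data

The generator emulates the input structure at desk scale: by default two
25 Mb chromosomes carrying 500 genes (~100 kb apart, so 50 kb-flank windows
tile the sequence as in gene-dense human regions) and 20 subfamilies of 250
integrants of 300–3000 bp — enough incidences per subfamily to clear the
≥ 150 filter, as real retained subfamilies do. Genes carry 1–3 TSS, some
clustered within 1 kb and some in a second cluster, plus three exons.
A `fragmentation_rate` fraction (default 0.1) of integrants is emitted as
two fragments with a gap < 100 bp; same-subfamily, same-strand integrants
are kept ≥ 150 bp apart so fragment merging exactly restores the parent set.

Expression is drawn from the additive model itself — basal levels
`c_p ~ N(5, 1.5)` (log2-TPM-like scale), sample offsets `d_s ~ N(0, 0.3)`,
per-entry noise sd 0.5, library sizes varying up to 2× across samples, three
active subfamilies at ΔA ∈ {−0.15, +0.10, +0.20}, two replicate pairs —
and converted to integer counts by inverting the normalization: counts
satisfy `counts = round(x − π)` where `π` is the 5th percentile of the
resulting non-zero counts, solved by damped fixed-point iteration. Without
this inversion the pipeline's pseudocount would shrink simulated effects by
~20% and confidence intervals would under-cover; with it, the only
model-misfit left is count rounding. Because noise is Gaussian on the log
scale by construction, passing recovery and calibration tests demonstrates
the estimator and its inference are correct *under the model's own
assumptions*; they do not probe robustness to overdispersed counts, outlier
genes, mappability artifacts, shared-sequence mis-assignment between related
subfamilies, or annotation error, all of which real data contain. The
generator's `active_fraction` option makes only a random subset of a
subfamily's integrants active, which is the ground truth against which the
functional-split machinery is tested.

## Numerical choices

- Interval arithmetic is 0-based half-open throughout; interval centers are
  floors of midpoints; "overlap" always means ≥ 1 bp shared.
- All threshold comparisons follow the strict/non-strict conventions stated
  above (< 100 bp merge gap, < 1 kb TSS clustering, < 150 and < 100 column
  sums, ≤ 0.05 significance).
- OLS uses a QR-based solver with an explicit rank check; rank deficiency is
  an error naming the collinear columns, not a silent minimum-norm fix.
- Fold-change confidence intervals use the normal quantile (1.96 at 95%);
  the residual degrees of freedom are reported so callers preferring
  t-quantiles can substitute them (at the problem sizes involved the
  difference is negligible).
- Cross-validation folds come from a seeded generator permutation of the
  gene list; reruns are bit-identical on fixed inputs.

## Known limitations

- Activities are assumed identical across a subfamily's integrants; the
  functional split mitigates but does not remove this.
- The model cannot distinguish direct TE enhancer effects from correlated
  confounders sharing the TE's spatial distribution (e.g. a TF binding both
  a subfamily and independent sites near the same genes).
- Collinear subfamilies (common for closely related families at large L)
  are rejected rather than regularized; a penalized variant is out of scope.
- No between-sample normalization beyond the model's centering (TMM-style
  scaling belongs to upstream count production).
- Coordinates must share one assembly and naming scheme; no liftover.
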
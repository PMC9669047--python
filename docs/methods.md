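# Methods

This note documents the models, estimators and numerical choices behind
`turnomix`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Kinetic model and half-life estimation

A transcript with synthesis rate α (transcripts/h) and first-order decay
rate δ (1/h) has steady-state abundance A = α/δ. During a 4sU pulse of
length *t* hours, newly made molecules are labelled, so the labelled share
of the pool is θ = 1 − e^(−δt); synthesis during the pulse is captured by
this form. Inverting gives δ = −ln(1 − θ)/t and t½ = ln2/δ. The estimator
assumes steady state; transcripts far from steady state (e.g. strongly
induced genes early after activation) have their stability underestimated,
and no correction is attempted. No correction for 4sU incorporation
efficiency is applied; `LabelingDesign.separation_purity` (default 1.0)
models incomplete capture of labelled molecules in the labelled fraction.

**Correction factors.** The labelled (L), unlabelled (U) and total (T)
fractions are sequenced as separate libraries, so after within-assay
median-of-ratios normalisation their scales differ by unknown factors.
Because L and U partition the total pool, T_g = c_L·L_g + c_U·U_g holds
across genes, and (c_L, c_U) can be fit per biological sample. A plain
least-squares fit of this identity is badly biased here: both regressors
are noisy counts, they are strongly collinear (both scale with abundance),
and with over-dispersed counts the errors-in-variables attenuation is
amplified by the collinearity — in simulations at realistic depth the
labelled coefficient is overestimated by 50% or more. The package
therefore fits the identity by instrumented weighted regression:

* instruments: the mean L and U of the *other* biological samples, which
  are correlated with the true per-gene signal but independent of the
  focal sample's count noise, giving a consistent moment estimator;
* weights: inverse NB variance 1/(μ + d·μ²), with μ the mean normalised
  total over the other samples and d a pooled moment estimate of
  dispersion (median of (s² − m)/m² over well-covered genes);
* eligibility: genes with reference mean normalised total ≥ 10 (floor
  suppresses zero-inflation leverage), at least 50 genes required.

With a single sample the estimator degenerates to weighted least squares
on the sample itself (exact on noiseless data, as is the instrumented fit).
Samples with singular fits or non-positive coefficients are flagged
invalid and excluded from the across-sample means.

**Half-lives.** Group-mean normalised counts (per genotype × batch by
default; per genotype when batches are pooled) are combined as
θ = c_L·L̄ / (c_L·L̄ + c_U·Ū), using the across-sample mean factors. The
denominator is the *reconstructed* total, which guarantees θ ∈ (0, 1)
whenever both components are positive; rows with θ on a boundary or with
reconstructed totals below a count floor are flagged with a reason code
rather than dropped silently.

**Stability change.** Per batch, d = log2(t½_KO/t½_control) is divided by
the batch-wide SD of d (ddof 1) — batches can differ substantially in
labelling efficiency and depth, and standardising before averaging puts
them on a common scale. The per-gene score is the mean of the standardised
values over the batches where the gene is measurable. Swapping genotype
labels negates the score exactly.

## Expression-local z statistic

For gene g with mean expression e_g and difference d_g (a log fold change,
a stability score, ...), the window W(g) is the w nearest genes to g in
mean expression, g included, with w = max(200, ⌈0.01·G⌉) clamped to G.
Then z_g = (d_g − mean_W d)/sd_W d with a two-sided standard-normal p and
Benjamini–Hochberg FDR. Choices that the underlying idea leaves open, and
how they are pinned here:

* the window includes the focal gene; at w = 200 the resulting deflation
  of |z| is below 0.3%;
* expression ties are broken by gene-id order; in the sorted order the
  w-nearest set is a contiguous block found by a two-pointer sweep, with
  equidistant neighbours resolved toward the lower-expression side;
* window statistics are computed from prefix sums, so the statistic is
  O(G·w) worst-case but O(G) in arithmetic after the sweep;
* a window with zero SD raises an error rather than emitting infinities.

Under a null where differences are independent of expression the p < 0.05
fraction is 4.7–5.0% at G = 10⁴ (tested), and the statistic agrees with
the global z (median |Δz| < 0.1) when the noise is homoscedastic. In
pooled mode several contrasts share one set of windows so their z-scores
are comparable; results are reported per contrast.

The expression axis used for stability significance is the mean normalised
count across the total and newly-synthesised libraries, since the
stability score itself carries no expression information.

Fold changes computed inside the package are plain log2 ratios of
group-mean normalised counts with pseudocount 0.5. No shrinkage is
implemented; externally shrunken fold changes can be supplied to
`zscore_from_lfc` directly. Negative-binomial GLM fitting is out of scope.

## Regulatory modes

Derepressed genes are the union, over the four measures, of genes
*increased* at that measure's threshold (defaults: newly-synthesised
FDR < 0.1, total FDR < 0.001, stability z > 2 with positive score,
ribosome-protected FDR < 0.05). The increase requirement applies per
criterion. Clustering uses only the (new, stability, ribo) z columns:
pairwise distance 1 − Pearson(rows), complete linkage, tree cut into k
clusters (default 5, exposed as a parameter). Total-mRNA z is carried for
reporting but excluded from distances. Rows constant across the three
clustering columns have undefined correlation and are excluded with a
warning. Cluster labels are assigned by per-measure medians: `++` above
1.2, `+` above 0.4, `-` below −0.4, blank otherwise. Rows are clustered on
their z-scores as-is, with no additional per-row standardisation.

## CLIP

Sites are single-nucleotide, strand-specific (BED-style 0-based
half-open, a site at p occupies [p, p+1)). Feature assignment prioritises
3'UTRs; the remaining order (CDS > 5'UTR > intron > non-coding) is a fixed
package convention, with priority ties broken by gene id. The iCLIP target
rule requires a sub-α site in the gene's 3'UTR from *both* antibody
groups; the HITS-CLIP rule requires the *identical* (chrom, position,
strand) significant site in at least `min_replicates` replicates — exact
equality, by design. The summary score sums 3'UTR reads over sites with
FDR < 0.25 (duplicate rows at one position are aggregated first: reads
summed, minimum FDR), normalises to the 90th percentile of sums over
detected genes (linear interpolation between order statistics — pinned for
reproducibility) and takes log2 with no pseudocount; undetected genes get
no score. Motif scanning counts overlapping occurrences and treats T and U
as equivalent. Conservation smoothing is a centred moving average (window
7 by default) whose window shrinks at sequence edges.

## Matched-control enrichment

For each focal gene, candidates are genes outside the focal set not
already used in the current control set; reuse across sets is allowed.
Length-eligible candidates differ by < 25% in 3'UTR length relative to the
focal gene (the denominator is the focal gene's length, pinned for
determinism); if fewer than 1000 qualify, the 1000 closest by absolute
length difference are taken. From these, the 100 closest in expression
(log2 FPKM) are kept and one is drawn uniformly with the seeded generator.
Distance ties break by gene id. 100 control sets give the median and
5th/95th percentiles of the control count distribution; the observed count
is reported normalised to the median. When the control median is 0, the
normalised value is undefined and absolute counts are reported.

The matching resolution depends on the universe size: below ~3,600 genes
(for the UTR-length spread used in the generator) the < 25% pool drops
under 1000 and the fallback coarsens length matching. On a 4,000-gene
universe — comparable to the number of well-expressed genes in a real
dataset — the mean Kolmogorov–Smirnov statistic between focal and control
distributions is ≈ 0.04 (expression) and ≈ 0.09 (UTR length).

The expression vector is an explicit input: different CLIP datasets should
be matched against expression from their own stimulation condition.
Rate-limiting-enzyme annotation is consumed as a two-column file; the
group comparison is an unpaired equal-variance t-test per assay with BH
correction across assays.

## Isotopologue correction

A fragment's measured spectrum y (ion counts at M+0 … M+k) relates to the
true MID m (length n_tracer + 1) by y = C·m. Column j of C is the
convolution of (i) the natural heavy-isotope mass-shift distributions of
every atom in the fragment formula (C, H, N, O, Si, S — TBDMS-derivatised
fragments carry Si), computed per element by exponentiation-by-squaring
under convolution, and (ii) natural ¹³C at the n_tracer − j unlabelled
tracer positions, shifted by j. Consequently C[i][j] = 0 for i < j and
columns sum to 1 when the measured range is wide enough. Correction of the
tracer positions themselves can be disabled for sensitivity analysis.
Isotope frequencies are pinned in `turnomix.isotopes` for bit
reproducibility.

m is recovered by non-negative least squares (not matrix inversion, which
can return negative isotopologue fractions on noisy spectra) and
renormalised to sum to one; fractional labelling is FL = Σ j·m_j/n_tracer.
The labelled/unlabelled split of a metabolite's relative ion count is
total×FL and total×(1 − FL); the unlabelled definition is the complement
convention, and both columns are reported so the alternative reading
(unlabelled = total ion counts) remains computable. Fragment formulas are
user-supplied inputs — they depend on derivatisation chemistry.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the study's data — not its
biology. Defaults (one place, never tuned per test):

* 2,000 genes; NB dispersion 0.05; ~10⁶ expected reads per fraction
  library; two batches with per-gene log-normal batch factors (sd 0.2 on
  log2, applied to transcription); two replicates per genotype × batch;
* half-lives log-normal, median 4 h (log-sd 0.7); synthesis rates
  log-normal (log-sd 1.0); translation efficiencies log-normal (log-sd
  0.4); 4sU pulse 1 h;
* fraction-scale factors (c_L, c_U) = (1.6, 0.8) applied to the labelled/
  unlabelled library means, so correction-factor estimation has real work
  to do; optional per-library depth jitter (sd 0.1 log2) — note that such
  jitter is mathematically part of the correction factors (a library scale
  *is* a correction factor), so recovery against the nominal (1.6, 0.8) is
  assessed with jitter disabled;
* 5% direct targets (dKO: δ×0.5, TE×2), 10% indirect (dKO: α×2) — effect
  magnitudes are generator choices, not measured values;
* 3'UTR lengths log-normal (median 800 nt, log-sd 0.6, floor 60 nt) laid
  end-to-end on one synthetic chromosome, plus strand; direct targets
  carry one planted TATTTATT; crosslink tables plant identical sites at
  the motif across replicates with Beta(1, 80) FDRs (mean ≈ 0.012, ~1.6%
  of planted sites miss the 0.05 cut per replicate) over a uniform-FDR
  random background;
* LC–MS: 52 metabolites, 6 replicates per genotype, log-normal abundances
  with 0.15 log2 replicate noise and per-sample internal-standard scales;
  planted dKO:control folds include glutamine 7.5 (the emulated condition
  is an increase *over* seven-fold) and α-ketoglutarate 3.0; GC–MS
  spectra are true MIDs convolved with each fragment's natural-abundance
  matrix plus multiplicative noise, with the truth stored for recovery
  tests.

Not emulated: read-level artefacts (mapping, duplication), transcript
isoforms, expression-dependent dispersion trends, non-steady-state
kinetics, crosslink sequence bias, chromatographic peak shape. Passing
tests therefore demonstrate correctness of the estimators under the
declared model, not robustness to every artefact of real data.

## Acceptance measurements

`scripts/acceptance.py` recomputes, from a single seed: half-life recovery
at study scale (2,000 genes, 10⁶ reads/fraction, dispersion 0.05; Spearman
and median relative error over genes with mean total ≥ 50, pooling the two
batch estimates per genotype); correction-factor recovery (noiseless
exactness and NB-noise recovery of (1.6, 0.8)); local-z null calibration
(G = 10⁴) and exact agreement with a brute-force window oracle (G = 20,
w = 5); five-archetype clustering recovery (ARI at noise sd 0.3); the CLIP
worked examples and planted-target sensitivity/false-discovery at 1,000
genes; matched-control calibration (200 null focal sets of 100 genes,
coverage of the 5th–95th band) and detection of a planted 2× target rate
(100 sets); MID round-trip error and unlabelled-sample correction; and the
metabolic-profiling table (52 metabolites, glutamine and α-KG folds,
α-KG:succinate ratio fold). These sizes keep the full run under ~2 minutes
on one CPU while leaving each measurement's sampling error well inside its
tolerance.
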
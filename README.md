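# turnomix

Quantitative multiomics for mRNA turnover and its metabolic consequences.

`turnomix` reimplements, as a tested and reusable Python pipeline, the
analysis framework used to dissect how an mRNA-destabilising RNA-binding
protein family (the ZFP36/tristetraprolin family) shapes gene expression in
activated CD4⁺ T cells. The same questions arise in any system where a
regulator acts simultaneously on transcription, mRNA stability and
translation: which layer changed, for which genes, and are the affected
transcripts direct binding targets?

The pipeline covers five analysis stages, each usable on its own:

* **stability** — mRNA half-life estimation from 4-thiouridine (4sU)
  three-fraction RNA-seq. After a pulse of length *t*, the labelled share of
  a transcript pool at steady state is θ = 1 − e^(−δt), so
  δ = −ln(1 − θ)/t and t½ = ln2/δ. Because the labelled (L), unlabelled (U)
  and total (T) fractions are sequenced as separate libraries, per-sample
  correction factors (c_L, c_U) mapping L and U onto T are estimated from
  the partition identity T = c_L·L + c_U·U across genes. Knockout-vs-control
  changes in t½ are standardised per experimental batch before averaging.
* **diffstats** — median-of-ratios normalisation, FPKM, and z statistics:
  a global z (fold change over dataset-wide SD) and the expression-local z,
  which standardises each gene's difference against the mean and SD of the
  *w* genes closest in mean expression. This removes the strong
  expression-dependence of count noise without fitting a variance model.
* **modes** — selection of derepressed genes by multi-assay thresholds
  (newly-synthesised FDR < 0.1, total FDR < 0.001, stability z > 2,
  ribosome-protected FDR < 0.05, increases only), then complete-linkage
  hierarchical clustering on 1 − Pearson correlation of the
  (transcription, stability, translation) z profiles into regulatory modes.
* **clip** — CLIP crosslink-site annotation with 3'UTR priority, target
  calling under the iCLIP rule (both antibodies, site FDR < 0.05 in the
  3'UTR) and the HITS-CLIP rule (identical significant site in ≥ 2
  replicates), a per-gene 3'UTR read-sum score normalised to the dataset's
  90th percentile, AU-rich-element (UAUUUAUU) scanning, and sliding-window
  conservation smoothing.
* **enrichment** — resampled control gene sets matched in 3'UTR length
  (< 25% difference, or the 1000 closest) and expression (closest 100 in
  log2 FPKM), 100 sets per query, giving median-normalised enrichments with
  5th–95th percentile bands; plus the rate-limiting-enzyme group t-test.
* **metabolism** — LC–MS metabolite table normalisation (internal standard,
  total ion content), per-metabolite t-tests and fold changes, metabolite
  ratio tracks, and ¹³C-tracing isotopologue correction: a
  natural-abundance matrix built from pinned isotope frequencies is
  inverted by non-negative least squares to recover mass isotopomer
  distributions (MIDs) and fractional labelling.

Every input the pipeline consumes can be generated, with known ground
truth, by the **synthetic** module: NB-distributed fraction counts from a
steady-state kinetic model with planted direct (stability/translation) and
indirect (transcription) effects, 3'UTRs with planted AREs and crosslink
pileups, and isotopologue spectra convolved with natural abundance. All
generators are seed-deterministic.

## Worked example

```python
from turnomix.synthetic import SimulationConfig, simulate_bundle
from turnomix.stability import run_stability_pipeline

cfg = SimulationConfig(n_genes=2000, depth=1e6, size_factor_log2_sd=0.0)
bundle = simulate_bundle(cfg, seed=1)
res = run_stability_pipeline(
    bundle.counts["total"], bundle.counts["new"], bundle.counts["pre"],
    bundle.samples,
)
f = res["factors"]
print(f"correction factors: c_L = {f.mean_c_l:.3f}, c_U = {f.mean_c_u:.3f}")
hl = res["halflives"]
ctrl = hl[(hl.genotype == "control") & hl.valid]
print(f"valid control half-lives: {ctrl.shape[0]} rows, "
      f"median t1/2 = {ctrl.half_life.median():.2f} h")
sig = res["significance"]
print(f"stabilised genes at z > 2: {(sig.z > 2).sum()}")
```

prints

```
correction factors: c_L = 1.647, c_U = 0.797
valid control half-lives: 3994 rows, median t1/2 = 4.08 h
stabilised genes at z > 2: 68
```

The generator planted (c_L, c_U) = (1.6, 0.8) and a median half-life of
4 h; the 68 genes called at z > 2 are dominated by the 5% of genes planted
as direct targets (2× half-life in the knockout). The same stages are
available from the shell:

```
turnomix simulate --seed 1 --outdir sim/
turnomix stability --total sim/counts_total.tsv --new sim/counts_new.tsv \
    --pre sim/counts_pre.tsv --samples sim/samples.tsv --out stab/
turnomix clip --sites sim/hitsclip_rep1.bed --sites sim/hitsclip_rep2.bed \
    --annotation sim/utrs.bed --fasta sim/utrs.fa --out clip/
```

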
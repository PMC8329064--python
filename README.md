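# gbmregio

Region-resolved analysis of glioblastoma histology: from whole-slide H&E
images and 8-class region masks to region-area tables, spatially resolved
gene signatures, cell-type assignment and paracrine ligand–receptor
nominations.

Glioblastomas are spatially organised: a leading edge (LE) grades into
infiltrating tumour (IT) and the cellular tumour bulk (CT), which contains
microvascular proliferation (CTmvp), pseudopalisading cells around necrosis
(CTpan), perinecrotic zones (CTpnz) and necrosis (CTne). The composition of
these compartments carries prognostic information, and the genes whose bulk
expression tracks a compartment's area nominate both the compartment's
resident cell types and the tumour–microenvironment interactions occurring
there. This package implements that full analysis chain at desk scale, for
computational biologists who want each stage verifiable:

1. **segmentation** — patch-based semantic segmentation of H&E images into
   the 8 classes with a fully convolutional DenseNet (encoder/decoder with
   dense blocks), trained with sparse categorical cross-entropy + L2 under
   RMSprop. The global metric is micro-averaged pixel accuracy,
   (TP+TN)/(TP+TN+FP+FN) under one-vs-rest pooling, which equals the
   fraction of correctly classified pixels. A random hyperparameter-search
   harness and a prior-based review report (the machine half of an expert
   review loop) are included.
2. **region_quant** — *averaged pixel counting*: for each patient, pixels of
   each region are counted across all masks and averaged over the number of
   sections; areas are normalised to per-patient fractions; outliers are
   screened with an iterative two-sided Grubbs test, G = max|x−x̄|/s against
   G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)).
3. **association** — Pearson correlation of region areas with survival days,
   overall and stratified by mutation carriers, plus vectorised Spearman
   correlation of every gene against every region area. Two-sided p-values
   come from the t transform t = ρ√((n−2)/(1−ρ²)) and are deliberately
   **not** corrected for multiple comparisons; `pvalue_diagnostics`
   computes the distributional evidence (non-uniform per-region p-value
   distributions, correlated region areas) behind that choice.
4. **signatures** — a gene is a region marker iff ρ > 0.1 and p < 0.05
   (strict), after a detection filter (expressed in ≥ 25 patients); markers
   are partitioned by the sign of their survival correlation (IT^neg,
   CTmvp^neg, CT^pos, CTpnz^pos, …).
5. **cell_ontology** — signatures are matched against a multi-source ranked
   marker reference with a rank-based score
   `(1/n_c) Σ_g [(n_c−r_C(g)+1)/n_c]·[1−|r_Q(g)−r_C(g)|/max(n_Q,n_c)]`,
   aggregated per cell type by occurrence-weighted summation and called at
   mean + 1 SD; hierarchical clustering (Euclidean, average linkage) maps
   signature genes across expression clusters.
6. **interactions** — paracrine ligand–receptor pairs between expression
   clusters scored by the regularised product `√(l·r)/(μ+√(l·r))`, filtered
   to receptors in the IT/CTmvp signatures expressed in all pseudo-patients,
   and assessed by median-split Kaplan–Meier / log-rank survival analysis.

Because the real inputs (large annotated whole-slide atlases, bulk RNA-seq
cohorts) are external, a first-class **synthetic_data** module generates
every input with planted ground truth — nested region geometry, Dirichlet
region areas, a log-linear survival model with mutation-specific
coefficients, planted gene–region effects, multi-source marker references
and planted ligand–receptor pairs — so every stage is testable by parameter
recovery. See `docs/methods.md` for the models and their assumptions.

## Worked example

Run the full chain on the default synthetic study (100 deceased patients,
50 planted markers per region at effect size 1.5):

```python
import gbmregio as g

cfg = g.PipelineConfig.from_dict({"seed": 1, "outdir": "out"})
pipe = g.run_pipeline(cfg)
m = pipe.manifest["stages"]
print(m["signatures"]["sizes"])
print(m["ontology"]["called"])
print(m["interactions"]["pairs"])
```

prints

```
{'LE': 51, 'IT': 55, 'CT': 55, 'CTmvp': 55, 'CTpan': 55, 'CTpnz': 58, 'CTne': 55}
['microglial cell']
['RTN4:GENE00150']
```

Each region signature recovers its 50 planted markers (sizes 51–58: all 50
plus a few false positives at the calibrated ~2.5% null rate). The IT
signature query calls exactly the planted "microglial cell" reference type
(aggregate 0.38 > mean + 1 SD across types; decoys score 0), and the
ligand–receptor filter nominates exactly the pair planted in 3 of 3
pseudo-patients whose receptor (here the synthetic CTmvp marker
`GENE00150`) lies in the CTmvp signature, discarding the 2-of-3 decoy. The
final stage runs a median-split log-rank test on the nominated receptor
(here χ² = 2.54, p = 0.11 at n = 50 + 50).

The same chain is available from the shell:

```bash
gbmregio run-all --seed 1 --outdir out
gbmregio simulate --config cfg.yaml --seed 1 --outdir out   # single stage
```

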
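# Methods

This note documents the models, parameter choices and numerical decisions
behind `gbmregio`, and what the synthetic study design does and does not
establish.

## Synthetic study design

### Slide geometry

A slide is a square RGB image with a circular tissue disk (default radius
0.92 × half-size). Anatomy is concentric, mirroring the canonical schematic
of glioblastoma compartments: a leading-edge (LE) ring outermost, an
infiltrating-tumour (IT) ring, and the cellular-tumour (CT) bulk inside.
Necrosis (CTne) blobs within CT are wrapped by a pseudopalisading (CTpan)
ring and then a perinecrotic (CTpnz) ring; microvascular-proliferation
(CTmvp) blobs are scattered through CT. Label 0 is background; labels 1–7
follow the order LE, IT, CT, CTmvp, CTpan, CTpnz, CTne.

Two invariants are enforced by construction and tested: background is
exactly the complement of the tissue disk, and every CTne boundary pixel is
8-adjacent to a CTpan pixel. When a layout's pan budget is smaller than the
necrosis perimeter, a sparse greedy shell guarantees adjacency at roughly a
third of the full-shell cost; conversely when exact pixel-area targets are
supplied (the cohort path), ring pixels are assigned by distance rank so
measured areas track targets closely. Area-targeted placement keeps the
rasterised region fractions within ±0.02 of the planted values at the
default 96 px cohort slides.

Textures are H&E-like only in palette: per-region base colours (pinks,
purples, a dark necrotic tone) plus Gaussian noise (σ = 6 grey levels) and
dark 3×3 nuclei stamped at region-specific Poisson densities (defaults, per
1000 px²: CT 40, CTpan 55, CTmvp 30, IT 15, CTpnz 10, LE 5, CTne 3 —
cellular tumour dense, necrosis nearly acellular). No stain calibration,
scanner artefacts, pyramidal formats, or annotation noise are emulated;
passing segmentation tests therefore demonstrate the correctness of the
training/prediction machinery on separable textures, not performance on
real slides.

### Cohort model

Patient region *fractions* are drawn from a 7-part Dirichlet with
concentration (LE 3, IT 3, CT 14, CTmvp 1.5, CTpan 2, CTpnz 2.5, CTne 4) —
CT-dominant with substantial necrosis, matching the observation that
resected material over-represents the tumour bulk, with total concentration
30 giving realistic patient-to-patient spread. Each patient contributes 1–3
slides whose geometry is solved from the drawn fractions; the *true* area
table is then measured from the generated masks, so downstream recovery is
judged against what the rasteriser actually produced.

Survival is log-linear: with z_r the cohort-standardised normalised area of
region r,

    log T_i = β₀ + Σ_{(c,r)} β_{c,r} · 1[i carries c] · z_{r,i} + ε_i,
    ε ~ N(0, σ²),  default σ = 0.4,  β₀ = log 450 days.

Coefficients act on *standardised* areas so each β is a per-SD log-fold
change in survival — raw Dirichlet fractions have SD ≈ 0.05, which would
make any slope-on-raw-fraction parameterisation numerically inert. All
patients are deceased (the cohort emulates a vital-status-filtered
registry), so survival analysis uses days-to-death; censoring is
nevertheless supported in the Kaplan–Meier module for reuse. Default study
conditions plant CT +0.6, CTpnz +0.4, IT −0.8, CTmvp −0.6 for everyone and
IT −2.0 in PIK3R1 carriers — the qualitative pattern of favourable central
and adverse infiltrative compartments. An OLS regression of log-survival on
the true standardised areas recovers every planted coefficient within two
standard errors at n = 500 (generator self-check in the test suite).

### Expression model

Marker gene g for region r follows
`log e = baseline_g + effect · z_r + ε`, ε ~ N(0, 1), baseline ~ N(2, 1),
exponentiated to FPKM-like positive values; non-markers omit the area term.
Effect 1.5 against unit noise gives a true latent correlation of
1.5/√(1.5²+1) ≈ 0.83, so planted markers sit far above the ρ > 0.1 gate
while remaining noisy enough that the detection filter, dropout (default
5% of cells zeroed uniformly at random) and rank-based estimation are
genuinely exercised. Dropout is intentionally missing-completely-at-random
— it exercises the ≥ 25-patient detection filter, not any biological
zero-inflation mechanism.

### Reference and cluster-average data

The cell-type reference emulates multi-source marker collections: each type
appears once per mock source dataset, entries of a type share ~60% of their
genes with permuted ranks, and different types have disjoint gene universes
unless a caller pins a type's pool (the pipeline pins "microglial cell" to
the planted IT markers so end-to-end calling is testable). Cluster-average
expression matrices for three pseudo-patients carry lognormal background
plus planted ligand/receptor values well above the matrix mean; a decoy
pair is planted in only two of three patients, giving the nomination filter
a true negative.

## Statistical procedures

- **Correlations.** Pearson r from the covariance formula; Spearman as
  Pearson on average ranks (ties share the mean rank). Two-sided p-values
  use the t transform for all n; an exact permutation p is available for
  n ≤ 9. The genes × regions screen is a vectorised implementation of the
  same estimator (verified cell-wise against `scipy.stats.spearmanr` to
  1e-12). Constant inputs raise an error rather than returning 0.
- **No multiplicity correction.** Raw p-values are reported by design; the
  diagnostics operation quantifies the two arguments for this (per-region
  p-value distributions deviating from Uniform(0,1) by KS distance, and the
  Spearman dependence matrix among region areas showing the tests are not
  independent) so users can audit the choice. FDR/Bonferroni wiring is
  deliberately out of scope.
- **Grubbs screen.** Iterative two-sided at α = 0.05, removing one extreme
  value per iteration while G > G_crit; the critical value uses the upper
  α/(2n) Student-t quantile with n−2 df. Zero-variance samples return a
  warned no-outlier result. The screen is applied to log survival by
  default (survival is lognormal here); a flag screens region-area columns
  instead — which variable the screen historically targeted is ambiguous,
  so both paths share one audit trail.
- **Signatures.** Strict inequalities at ρ > 0.1 and p < 0.05; genes may
  mark several regions. Survival direction calls (pos/neg) additionally
  require p < 0.05 on the survival correlation — without a significance
  gate the pos/neg partition would be noise-dominated; the gate is
  configurable and documented as a choice.
- **Match score.** The reference matcher's published description is
  qualitative (rank weight, rank-difference penalty, list-length
  normalisation); the formula here realises those three properties and is
  pinned by tests — scores are bounded by (n_c+1)/(2n_c), attained exactly
  at identical rank order (brute-force verified over all permutations for
  n_c ≤ 5). It is not claimed to reproduce any proprietary score
  numerically. Occurrence weighting is a sum over entries (= mean ×
  occurrence count); the calling line is mean + 1 SD (sample SD) of the
  aggregates, multiplier configurable.
- **Ligand–receptor score.** √(l·r)/(μ+√(l·r)) with μ the mean of the
  positive entries of the patient's cluster-average matrix; threshold 0.5.
  "Expressed in all patients" means threshold-passing in each (a flag can
  relax to detection). Only paracrine pairs (source ≠ receiver cluster)
  onto the designated neoplastic cluster are considered.
- **Survival comparison.** Median split with ties to the low group
  (quantile configurable), Kaplan–Meier per group via lifelines, log-rank
  χ² with 1 df. Groups without an observed event are an error.

## Segmentation model

A fully convolutional DenseNet: initial 3×3 conv (2×growth channels), down
blocks of 3×3 conv layers each emitting `growth` channels concatenated onto
the stack, 1×1 transition + 2×2 max-pool between blocks, a dense
bottleneck, and an up path of nearest-neighbour upsampling, skip
concatenation, a 3×3 compression conv (4×growth) and a dense block, ending
in a 1×1 conv to 8 classes. The desk preset (2 blocks, 2 layers/block,
growth 8; 85,608 parameters — the count is a closed-form function of the
config and tested as such) trains in ~20 s on one CPU; the 103-layer layout
(5 blocks of 4/5/7/10/12 layers, bottleneck 15, growth 16) is expressible
through the same config for completeness but is GPU-scale and not exercised
by tests.

Training uses sparse categorical cross-entropy plus an L2 penalty
(λ/2·Σw²) under RMSprop (decay 0.9, ε = 1e-7), batch size 1, with an
optional per-epoch learning-rate decay (desk preset: lr 1.5e-3 × 0.92^epoch
over 15 epochs — small batches make RMSprop oscillate late in training and
the decay stabilises the final epochs). The backend is a small reverse-mode
tape over numpy (conv via im2col, max-pool with argmax routing,
nearest-neighbour upsampling, concatenation, inverted dropout); gradients
are finite-difference-checked in the test suite, and pure-numpy execution
makes training bit-reproducible given the seed.

Numerical conventions: images resize bilinearly and masks strictly
nearest-neighbour (labels never blend); non-divisible tilings are
reflection-padded bottom/right and the padding stripped after stitching, so
extract→stitch is pixel-exact for every size/stride combination; per-pixel
argmax ties break toward the lowest label index; inputs must be divisible
by 2^depth, and a config whose pooling would collapse below 1×1 raises.

## Pipeline

Stages run in dependency order (simulate → segment → quantify → correlate →
signatures → ontology → interactions → survival); every intermediate is
persisted (TSV/GMT/JSON/indexed PNG) and a manifest records stage status,
parameters, derived seeds and versions, sufficient to re-run any stage in
isolation. All randomness descends from one master seed through stable
per-stage CRC32-hashed `SeedSequence` children. The segmentation stage can
be bypassed so ground-truth masks feed quantification — the first-class
path for testing the statistical stages, and the configuration under which
two full runs are byte-identical.

## Problem sizes

Default verification sizes were chosen so the whole suite runs in about a
minute of CPU: cohorts of 100 patients (200 for stratified recovery, 500
for the OLS generator check) on 64–96 px slides, 500 genes with 50 markers
per region, 50,000 null pairs for type-I calibration, 25 training tiles at
64 px, 10 reference seeds for cell-type calling and 50 for log-rank power.

## Known limitations

- Synthetic textures are linearly separable by colour; real H&E requires
  stain normalisation and larger receptive fields, and the desk-scale
  accuracy says nothing about accuracy on real atlases.
- The survival model is log-linear with Gaussian noise; no censoring is
  generated (though the analysis supports it) and no competing risks.
- Dropout is uniform; real FPKM zero patterns are expression-dependent.
- The concentric anatomy is a single-tumour idealisation; multifocal
  lesions, tissue folds and slide artefacts are absent.
- Identifier mapping is a static two-column table; no live annotation
  service is consulted.
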
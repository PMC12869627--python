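# Methods

## The labeling engine

Subtype labels are derived from bulk expression in five steps: (1) optional
counts→TPM conversion, `TPM_g = (count_g/len_g) / Σ_h(count_h/len_h) · 10⁶`;
(2) per-sample ssGSEA enrichment of the classical and basal-like halves of
the 50-gene Moffitt signature; (3) subtype score `s = ES_classical −
ES_basal` (positive = classical-leaning); (4) z-scoring of `s` across the
cohort; (5) thresholding at |z| > 1 into high-confidence calls, with the
closed band [−1, +1] labeled intermediate, optionally refined by GATA6
tertile.

**ssGSEA variant.** The enrichment score is the Barbie-style running sum:
genes are ranked within the sample (ascending ranks 1..G, ties averaged) and
walked in decreasing order; at each position the in-set cumulative
rank-weight fraction (weights `r^α`, default α = 0.25) minus the out-of-set
cumulative count fraction is accumulated. No range normalization is applied.
The name "ssGSEA" does not pin a single formula in the literature — the
exponent and normalization vary across implementations — so α is a config
knob and the score is documented as rank-based, hence invariant to gene
storage order and to any strictly increasing transform of expression.
Absolute scores shift slightly between variants; the downstream z-scored
thresholding is what matters for labels.

**z-scoring.** Population standard deviation (divisor N) everywhere, for
determinism; at cohort sizes of interest the N vs N−1 distinction cannot move
a call across the threshold unless it was numerically at the boundary
already. Zero-variance slices map to all-zero rather than NaN so downstream
sums stay finite. Two reference modes exist: `this_cohort` (default —
standardize on the cohort being labeled, the pooled-cohort behavior) and
`provided_reference` (frozen mean/SD), so a new cohort can be labeled without
re-pooling.

**GATA6 refinement.** GATA6 marks pancreatic epithelial differentiation:
high in classical, low or absent in basal-like tumors. Within the refinement
scope (default: intermediate samples only), the lowest GATA6 tertile becomes
basal-like, the highest classical, and the middle band ambiguous. Cutoffs
are cohort tertiles by default, or fixed TPM cutoffs (20/60) matching the
approximate tertile boundaries of large public PDAC cohorts. Whether refined
calls are promoted to high confidence is a switch, default off: the
z-threshold rule is the only path to high confidence unless the user opts in,
because promotion changes the training-set composition and the more
conservative reading keeps the |z| > 1 semantics intact. Whether tertiles
should be computed per cohort or on a pooled reference is likewise
configurable (`gata6_mode`), defaulting to the cohort at hand.

**Gene identifiers.** The engine works on symbols; ENSEMBL→symbol mapping is
the user's responsibility (a two-column table suffices). The bundled GMT
carries the signature's original published symbols (e.g. CTSL2, ATAD4);
users with modern annotations should map aliases before labeling. More than
half of either gene set missing is a hard error; any missing gene warns.

## The network

Inputs per slide: patch embeddings (dimension D_p) on a tile grid, and cell
records (embedding of dimension D_c, centroid, type) assigned to the patch
containing their centroid. Tiles are half-open squares of 256 patch-pixels
(512 base-frame pixels at the default ×40/×20 magnification ratio); partial
edge tiles are dropped and cells falling in the dropped remainder are
discarded with a logged count — foundation-model encoders expect fixed tile
sizes, and the half-open convention guarantees each centroid belongs to
exactly one tile.

**Spatially biased cell aggregation.** Per patch, tokens = [CLS] + cells.
Attention logits are scaled dot products plus an additive bias
`B_ij = −d(i,j)/γ` for cell pairs (0 for any pair involving CLS, which keeps
the summary token's view unbiased — the choice is ours; nothing in the
mechanism forces it). Distances are Euclidean in microns when the slide
carries an mpp, else in base-frame pixels; γ defaults to the patch extent in
the same unit so biases are O(1) against attention logits. γ → ∞ recovers
plain self-attention exactly. An empty patch passes the CLS token through
the value/output path deterministically.

**Fusion.** `f = W_f · vec(p ⊗ c) + b ∈ R^fused_dim` (default 768). The
outer product captures all pairwise patch×cell feature interactions; the
projection is learnable. Bilinearity means a zero cell vector with a
bias-free projection yields a zero fused vector.

**MIL pooling.** Gated attention (tanh ⊙ sigmoid gate, softmax-normalized
weights) over the fused patch vectors; a linear head on the attention-pooled
vector gives the slide logit, and sigmoid(logit) is the basal-like
probability. The "2D" variant (default) adds a fixed sinusoidal encoding of
the patch grid coordinates to each instance before scoring, recording our
interpretation of grid-aware MIL; the plain `gated` variant is permutation
invariant over patches and is what the patch-only baseline uses.

**Decision rule.** Positive class is basal-like. A tie at p = 0.5 is called
classical, deterministically. The decision margin is |p − 0.5| (range
[0, 0.5]); the alternative |2p − 1| is available behind `margin_def` since
published margin values do not pin the convention. Predictions with p ≤ 0.10
or p ≥ 0.90 are flagged high-confidence.

**Training.** BCE loss, AdamW (lr 5·10⁻⁵, weight decay 10⁻⁵), one slide per
optimization step (standard in MIL since bags vary in size), gradient-norm
clipping at 5, uniform 1/√fan-in init from a seeded generator. Stratified
k-fold CV (default 5); per fold, up to `max_epochs` epochs with early
stopping when validation AUC has not improved for `patience` epochs,
restoring the best-AUC checkpoint. The fold with the best validation AUC
supplies the model for zero-shot external evaluation. Folds are a
deterministic function of (labels, seed), so the baseline trained with the
same config sees identical splits.

The network is implemented on a ~250-line reverse-mode autodiff tape over
numpy (`pansubnet._autodiff`). Analytic gradients are pinned against central
finite differences in the test suite (relative tolerance 1e-4 on a toy bag).

**A caveat on reported fold metrics.** Because the reported per-fold metric
is the validation AUC of the checkpoint *selected* on validation AUC, it is
upward-biased, noticeably so for small validation folds (at 24 validation
slides the AUC's sampling SD is ≈0.12, and the maximum over epochs inherits
a positive bias of a few points even under the null). Label-permutation
controls on synthetic data therefore hover slightly above 0.5 rather than on
it; this is a property of the early-stopping protocol, not of the model.

## Synthetic generators

All generators are pure functions of (config, seed).

*Expression.* Log-normal background over 500 background genes plus the 50
signature genes and GATA6; per-gene baselines ~ N(0, 1) in log space,
within-class noise SD 1.0 (log space), global scale chosen so expected column
totals are 10⁶ before the exact TPM renormalization. A sample's continuum
position t ∈ [−1, +1] shifts classical-signature genes by `+t·effect·SD` and
basal genes by `−t·effect·SD` in log space; planted classical/basal samples
sit at t = ±1 and intermediates draw t ~ U(−0.5, 0.5), emulating a
transcriptional continuum with stable endpoints. GATA6 is log-normal around
a mode interpolated geometrically between 10 TPM (basal) and 100 TPM
(classical), giving the bimodal low/high structure the tertile rule expects.
Default cohort 100+100+50 with effect 2 SD: strong but not trivial planted
structure. What this does *not* emulate: gene–gene correlation, compositional
coupling beyond TPM closure, batch effects, tumor purity — so passing
recovery tests shows the pipeline's arithmetic and thresholds are right, not
that real cohorts will separate this cleanly.

*Slide bags.* Patch embeddings ~ N(m ± (patch_effect/2)·u, I) with a shared
non-zero baseline mean m and a fixed unit direction u (basal +, classical −).
The non-zero baseline mirrors real encoder features and matters structurally:
with zero-mean patch noise the outer-product fusion annihilates first-order
cell signal (E[p ⊗ c] = E[p] ⊗ E[c]). Cell embeddings are a 5-cluster
Gaussian mixture whose mixing weights tilt exponentially with the class in
proportion to cell_effect along a ramp over types; centroids are uniform
within the assigned patch. Default 120 slides, 6–12 patches each, 5–15 cells
per patch, both effects 1.0. These bags have no spatial autocorrelation of
cell types within patches, so the distance bias is exercised mechanically,
not selected for.

*Survival.* Exponential event times per group (defaults: medians ~16.6 vs
8.3 months, hazard ratio 2), independent uniform censoring at a configurable
rate, times in months.

## Evaluation choices

AUC is the Mann–Whitney pair statistic (ties half), computed via the ROC
integral and cross-checked against exhaustive pair counting in tests.
Survival defaults to an events-only analysis (subjects without a death event
are excluded before fitting), mirroring analyses that drop alive-but-censored
patients; standard right-censoring is available via `include_censored=True`
and is the statistically conventional choice — the events-only estimator
conditions on death and is not a consistent estimator of S(t). Median OS
confidence intervals follow the Brookmeyer–Crowley convention as implemented
in lifelines (log-log transformed survival CI, inverted at 0.5). The
Mann–Whitney margin test uses exact enumeration for groups ≤ 20 and the
normal approximation with tie correction above. The DDR composite score sums
per-gene population z-scores over BRCA1, BRCA2, PALB2, RAD51, ATM, CHEK1;
cohort scores sum to zero by construction. Over-representation is an
upper-tail hypergeometric test per term with Benjamini–Hochberg adjustment
across terms.

Attention masks min-max scale per-patch MIL weights to [0, 255] (constant
weights map to 0 by convention), paint one square block per patch, and
optionally alpha-blend over a thumbnail.

## Problem sizes used in tests and the acceptance script

End-to-end model experiments run at reduced dimensions chosen as this
package's desk-scale study conditions: D_p = 64, D_c = 32, fused_dim = 256,
120 slides, 5-fold CV, ≤12 epochs with patience 4. The separable cohort
(both effects 1.0) trains to ceiling within a few epochs; the cell-only
cohort uses patch_effect 0 and cell_effect 2. The labeling recovery cohort
is 100+100+50 samples at effect 2 SD. The log-rank type-I simulation uses
2,000 replicates at 50 subjects per arm. Full-scale settings (fused_dim 768,
100 epochs, patience 10) remain the config defaults.

## Known limitations

- Real WSIs, foundation-model encoders and GPU training are out of scope;
  the model consumes precomputed embeddings and the synthetic bags stand in
  for encoder outputs.
- The events-only survival default discards censoring information; use
  `include_censored=True` for inference about S(t).
- The GMT ships legacy gene symbols; alias resolution is left to the caller.
- Single-process CPU training; bags with thousands of patches will be slow.
- The "2D" MIL variant and the CLS-row bias convention are documented
  interpretations of underspecified mechanisms, behind flags.
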
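# pansubnet

Molecular subtyping of pancreatic ductal adenocarcinoma (PDAC) from routine
histology. PDAC splits into two transcriptomic subtypes with different
prognosis and treatment response — **basal-like** (aggressive) and
**classical** (better outcomes, GATA6-high) — but RNA sequencing is slow,
costly and often infeasible on small biopsies. This package implements, end
to end and testable on synthetic data:

1. **An RNA-seq labeling engine.** Per-sample ssGSEA enrichment of the
   50-gene Moffitt signature (25 classical + 25 basal-like marker genes),
   subtype score `s = ES_classical − ES_basal`, cohort z-scoring, and the
   high-confidence rule

   ```
   classical      if z > +1
   basal-like     if z < −1
   intermediate   if −1 ≤ z ≤ +1
   ```

   with optional GATA6-tertile refinement of the intermediate band
   (low tertile → basal-like, high → classical, middle → ambiguous).

2. **A dual-scale multiple-instance-learning network** that predicts the
   subtype from per-slide embeddings. Each slide is tiled into 256-px patches
   (at ×20; cells live at ×40 in the same base frame). Per patch, cell
   embeddings are aggregated by self-attention with a learnable CLS token in
   which the pairwise physical distance between cell centroids, scaled by γ,
   is *subtracted* from the attention logits — nearby cells form functional
   neighborhoods. The CLS output `c` is fused with the patch embedding `p`
   via an outer product, `f = W · vec(p ⊗ c) ∈ R^768`, and the bag of fused
   patch vectors is pooled with gated attention MIL:

   ```
   a_k = softmax_k( wᵀ (tanh(V h_k) ⊙ σ(U h_k)) ),   P(basal) = σ( w_cᵀ Σ_k a_k h_k )
   ```

   Training is binary cross-entropy with AdamW (lr 5·10⁻⁵, weight decay
   10⁻⁵), ≤100 epochs with early stopping on validation AUC, stratified
   5-fold cross-validation, and a patch-only gated AttMIL baseline on
   identical splits. The network runs on a small built-in reverse-mode
   autodiff over numpy — no deep-learning framework required.

3. **Evaluation and downstream analyses**: AUC/accuracy/balanced
   accuracy/sensitivity/specificity, decision-margin vs correctness
   (Mann–Whitney), Kaplan–Meier survival with log-rank tests and median OS
   95% CIs, a composite DNA-damage-repair (DDR) z-sum score, hypergeometric
   over-representation tests with Benjamini–Hochberg correction, and
   0–255 grayscale attention-mask rendering with slide overlays.

4. **Synthetic generators** for expression cohorts (planted subtype means,
   a transcriptional continuum of intermediates, bimodal GATA6), slide bags
   (class-conditional patch/cell embeddings with tunable effect sizes), and
   two-group exponential survival data — so every stage is exercised without
   any restricted data.

## Worked example

```bash
pansubnet simulate expr --n-classical 100 --n-basal 100 --n-intermediate 50 \
    --effect 2.0 --seed 0 --out expr.tsv --truth-out truth.csv
pansubnet label --expr expr.tsv --out labels.csv
```

prints

```
wrote 551x250 TPM matrix to expr.tsv
wrote 250 labels to labels.csv
```

`labels.csv` holds one row per sample: both enrichment scores, the subtype
score and its cohort z-score, the call, its confidence class and the GATA6
tertile. On this cohort (planted effect of 2 SD on the signature genes) 182
samples exceed |z| > 1 and every one of these high-confidence calls matches
the planted subtype (100% concordance); the samples generated on the
intermediate continuum fall inside the z band and are refined by their GATA6
tertile. In Python:

```python
from pansubnet import ExpressionSimConfig, simulate_expression_cohort, build_label_table
matrix, truth = simulate_expression_cohort(ExpressionSimConfig(seed=0))
labels, scores = build_label_table(matrix)
```

Training on synthetic slide bags:

```bash
pansubnet simulate bags --n-slides 120 --seed 0 --out-dir bags/
pansubnet crossval --bags bags/ --fused-dim 256 --max-epochs 12 --metrics-out cv.csv
# -> mean AUC 100.000 +/- 0.000 (best fold 0)
pansubnet attention-map --bag bags/slide_0000.h5 --out mask.png
```

The attention map renders each patch's MIL weight as a grayscale block
(255 = highest attention).

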
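# Methods

## Problem and model

The package predicts a binary gene-expression label — highly expressed
(HEG, +1) versus lowly expressed (LEG, −1), assigned by a per-cell-line
median split with ties going to LEG — from three promoter-centred feature
blocks, and exposes every attention weight the model computes as an
interpretation surface.  The three encoders and the fusion stage are
described in the README; this note records the assumptions, defaults, and
numerical choices behind them.

### Coordinate and strand conventions

All interval arithmetic is 0-based, half-open.  Bin *b* of the histone
window covers `[tss−2000+100b, tss−2000+100(b+1))`; a read is assigned to
the bin containing its 5′ position, and reads outside the window are
dropped.  Windows of minus-strand genes are reversed so bin 0 is always
the most upstream bin in transcriptional direction; CpG offsets are
sign-flipped the same way.  The CpG window is the *closed* interval
`[tss−2000, tss+2000]` ("within 2,000 bp" read as inclusive).  In BED
annotations the TSS is the start coordinate for `+` genes and the end for
`−` genes.  A window that runs past the chromosome start is zero-padded
with a warning rather than rejected.

### Feature construction

* Histone entries are `ln(count + 1)`: natural log with pseudocount 1 —
  monotone, zero-preserving, and exact on empty bins.  Coverage can be
  supplied as read positions or as bedGraph intervals whose value is the
  read count on the interval (apportioned to bins by overlap fraction);
  aligned 100-bp tiles reproduce per-read binning exactly.
* The TF catalog is a fixed, ordered 1016-name list shipped as a data
  file (`data/tf_catalog_synthetic.txt`, a synthetic stand-in name list);
  column index in every TF matrix equals catalog index.  Candidate TFs
  (motif occurrence within 200 bp of the TSS) are supplied externally as
  a table — motif scanning itself is out of scope.

### Architecture choices

The printed layer sizes (7×40 input, 100 kernels of 7×7 → 1×34 maps,
pool 3/3 with one zero of padding per side → 12, h^HM = 80, h^ME = 20,
TF 3×1016 → h^TF = 5, |h| = 105) are fixed by the design; the remaining
choices were genuinely open and are resolved as follows.

* The CNN treats the 7 marks as the full height of a 2-D kernel, so each
  kernel emits a single 1×34 row (the only reading consistent with the
  printed sizes).  Layer order: convolution → batch-norm → ReLU →
  max-pool.  Pool padding is symmetric, one zero per side.
* Both LSTM encoders use standard additive soft attention
  (`score_t = vᵀ tanh(W s_t + b)`, softmax over steps, context = weighted
  sum); the emitted latent is the attended context, not the final hidden
  state — otherwise the attention would be dead weight.  Hidden sizes (40
  and 10 per direction) are forced by the printed output lengths.
* The dynamic (variable-length) bidirectional LSTM runs its reverse
  direction on per-sample reversed inputs with trailing padding and
  re-aligns the outputs, so padded batches are bit-equivalent to
  one-by-one encoding (tested).  An empty CpG track maps to the zero
  vector — distinguishable from every real methylation pattern.
* The TF self-attention is single-head scaled dot-product over candidate
  positions only: masked logits are −∞ before the softmax, so the latent
  is provably invariant to the content of masked columns; an all-masked
  gene maps to the zero vector.  Query/key/value width is 8.
* The fusion map A is one affine layer (R^105 → R^(k·105)); the softmax
  is taken per head across all 105 coordinates, not per block, so heads
  can trade mass between omics — which is exactly what the cross-cell-line
  comparison interprets.  The attention count defaults to **k = 4** (the
  small-k regime of the multi-attention block this stage follows).
* Per-omics importance is mean-per-dimension attention mass (block mass ÷
  block width, normalized to sum to 1) so the 5-dim TF block is not
  penalized for being narrow.

### Training

Binary cross-entropy on `sigmoid(score)` with labels mapped {+1→1, −1→0};
Adam (lr 3·10⁻³, β = 0.9/0.999), batch size 128, at most 25 epochs with
early stopping on validation AUC (patience 5; the best-validation
parameter state is restored).  The TF encoder divides its input triples
by a fixed scale (5.0) so the self-attention logits start in the soft,
trainable range; at lower learning rates or unscaled inputs the ME and
TF branches plateau near chance.  A non-finite loss aborts with a
diagnostic.  Omics subsets omit the excluded branches from the network
entirely (no parameters), rather than zeroing inputs.  All randomness —
initialization, validation split, batch order — derives from one integer
seed; two runs with the same seed produce bit-identical reports.  The
networks run on the package's own NumPy reverse-mode autodiff core
(float64 throughout); every layer's gradient is finite-difference tested.

### Evaluation protocol

Genes are split into four near-equal random folds (by gene, not
chromosome-stratified); rotation r uses fold r as test, fold r+1 as
validation, the rest as training, and reported cross-validation metrics
are means over the four rotations.  Metrics: AUC, AUPR (HEG positive),
and rank concordance, implemented as the Spearman rank correlation
between the model score and the true expression values (a concordance
index would be an equally defensible reading; Spearman is used
throughout and reported ×100 when printed as a percentage).

### Cross-cell-line analyses

The block-weight table divides each omics column by its mean over the
provided cell lines (column means exactly 1 after normalization);
importances are computed over each cell line's test genes.  The
compatibility matrix holds AUC(train i, test j), normalized by its
column's diagonal AUC(train j, test j); rows of the normalized matrix are
clustered with average-linkage hierarchical clustering on Euclidean
distances (the metric is fixed, the linkage was open and average linkage
chosen), exported as Newick.

## Synthetic data

The generator emulates the qualitative structure of promoter epigenomics
rather than read-level realism (no FASTQ/SAM): one artificial chromosome,
genes every 10 kb, TSS on the bin grid.

* **Histone signal**: Poisson background (2 reads/bin) plus, for
  informative HEG, a Gaussian bump (sd 4 bins, default amplitude 40
  reads/bin) on the activation marks H3K27ac/H3K4me3/H3K9ac, half that on
  H3K4me1, and a flat 20% elevation of gene-body H3K36me3.  *HM-ambiguous*
  genes draw their profile independently of the label — half look fully
  activated, half silent — so histone marks alone cannot separate them
  (mirroring expressed genes with weak activation marks and silent genes
  with an open-chromatin appearance).
* **Methylation**: CpG count ~ Poisson(16) per window; informative betas
  are truncated Gaussians around 0.1 (HEG) or 0.8 (LEG) with sd 0.15
  (all four values configurable); uninformative betas centre on 0.5.
* **TF features**: each cell line has 12 activator TFs with elevated
  expression; TF-informative HEG recruit each activator with probability
  0.8 (LEG: 0.05) on top of ~4 random background candidates.
* **Cell-line individuality**: seeded nuisance jitter (±30% histone
  assay depth, ±20% methylation noise and CpG density) makes
  same-configuration lines similar but not identical.  For cross-line
  benchmarks, `primary_informative_fraction` restricts the ME/TF signal
  to a subset of genes and each line can carry a weak line-specific
  *histone side-channel* (TSS-bump bias, repressive-mark level,
  enhancer-mark level, or gene-body level, each worth roughly AUC 0.75
  alone) that resolves part of the remainder — own-line models exploit
  it, transferred models cannot, which is what gives the compatibility
  matrix its dominant diagonal while same-regime lines still cluster.
* **Expression**: log-normal, exp(N(2, 0.6)) for HEG and exp(N(−2, 0.6))
  for LEG, so the median split of the emitted values almost always
  recovers the generating label (per-gene Bernoulli(heg_fraction) class
  draws make a small mismatch near the median possible — a realistic
  trace of label noise).
* **Regimes** (`hm`, `me`, `tf`, `mixed`) choose which blocks carry the
  label signal; benchmark cell lines sharing a regime share all generator
  parameters except the per-line seed, with activator TF sets tied per
  regime, so same-regime transfer exceeds cross-regime transfer.

Generation is byte-deterministic given the seed, and the emitted files
round-trip through the ingest module record-for-record (tested).  What
passing tests on these data do **not** show: robustness to mappability or
GC artefacts, batch effects, correlated marks, chromosome-scale
structure, or realistic class imbalance — the generator makes separable
or controllably ambiguous problems, not hard ones.

## Problem sizes used by the test suite

The end-to-end checks run at desk scale, chosen as the smallest sizes at
which the stochastic properties are stable: a 2,000-gene cell line for
full-model recovery and label-permutation nulls; 800-gene cell lines
(30% HM-ambiguous) across three seeds for the omics-ablation comparison;
four 500-gene cell lines (two HM-driven, two ME-driven) per seed for the
block-weight table; and four 800-gene cell lines (two ME-driven, two
TF-driven, with side-channels and half-coverage primaries) per seed for
the transfer matrix.

## Known limitations

* Real-data preprocessing upstream of the documented file formats (read
  alignment, peak calling, motif scanning) is out of scope.
* Whether raw or depth-normalized counts enter the log transform is an
  open question of the design; the implementation takes the counts it is
  given.
* The float64 NumPy substrate is single-threaded and CPU-bound; the
  defaults train a 2,000-gene cell line in well under a minute, but the
  implementation is not meant for genome-scale sweeps.
* AUPR is reported for completeness but is sensitive to class balance;
  with the default median split classes are balanced by construction.
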
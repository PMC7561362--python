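# epifusion

Attention-based multi-omics prediction of gene expression level.

`epifusion` asks a classic question of regulatory genomics — can a gene's
expression level be read off the epigenetic state of its promoter? — and
answers it with an end-to-end attention model over three feature blocks
built around each gene's transcription start site (TSS):

* **Histone marks** (`hm`): seven core ChIP-seq marks (H3K4me1, H3K4me3,
  H3K9me3, H3K27me3, H3K36me3, H3K27ac, H3K9ac) binned at 100 bp over the
  4,000 bp window centred on the TSS, as a 7 × 40 matrix of log read
  counts ln(c + 1).
* **DNA methylation** (`me`): the ordered CpG beta values within ±2,000 bp
  of the TSS — a variable-length track.
* **Transcription factors** (`tf`): a 3 × 1016 matrix (TF expression,
  binding-site count, binding score over a fixed TF catalog) in which
  every column that is not a candidate binding TF for the gene is masked
  to zero.

Genes are labelled **HEG** (+1, highly expressed) or **LEG** (−1) by a
per-cell-line median split of their expression values.

## Model

Each block has its own encoder into a shared regulatory latent space:

* `hm` → CNN (100 full-height 7 × 7 kernels → 1 × 34 maps; batch-norm,
  ReLU; max-pool size 3 / stride 3 with one zero of padding per side → 12
  positions) → bidirectional LSTM (40 units/direction) with additive
  attention → **h^HM ∈ R^80**;
* `me` → dynamic bidirectional LSTM (10 units/direction) over the CpG
  track, additive attention over the CpGs → **h^ME ∈ R^20** (an empty
  track maps to the zero vector);
* `tf` → single-head scaled dot-product self-attention over the candidate
  TF positions, masked mean-pooling, linear map → **h^TF ∈ R^5**.

The fusion stage concatenates h = [h^HM; h^ME; h^TF] ∈ R^105, produces k
attention rows a_1…a_k = softmax(reshape(A h)) over the joint vector, and
scores the elementwise-attended copies h̃_i = h ⊙ a_i with a final affine
layer; the gene is called HEG iff the score is positive.  The attention
mass a head places on each block's coordinate range (divided by the block
width) is the model's per-omics importance — the interpretation surface
used to compare regulatory programmes across cell lines.

Everything runs on a small NumPy reverse-mode autodiff core shipped with
the package (`epifusion.autograd`, `epifusion.nn`); training is Adam on
binary cross-entropy with early stopping on validation AUC.

## Worked example

```python
import numpy as np
from epifusion import (MultiOmicsAttentionClassifier, SimConfig,
                       simulate_dataset, make_folds, evaluate)

ds, truth = simulate_dataset(SimConfig(seed=1, n_genes=2000, regime="mixed"))
fold = make_folds(ds.gene_ids, seed=1)[0]

clf = MultiOmicsAttentionClassifier(random_state=1)
clf.fit(ds.subset_by_gene_id(fold.train),
        validation=(ds.subset_by_gene_id(fold.validation),
                    ds.subset_by_gene_id(fold.validation).labels))

test = ds.subset_by_gene_id(fold.test)
rep = evaluate(clf.decision_function(test), test.labels, test.expressions)
print(f"AUC {rep.auc:.3f}  AUPR {rep.aupr:.3f}  "
      f"rank concordance {100 * rep.rank_concordance:.1f}%")
print({k: round(v, 3) for k, v in clf.omics_importance(test).items()})
```

prints (2,000 synthetic genes, all three omics informative):

```
AUC 1.000  AUPR 1.000  rank concordance 75.1%
{'hm': 0.369, 'me': 0.26, 'tf': 0.371}
```

AUC/AUPR of 1.0 say the held-out fold is ranked perfectly; the rank
concordance of ~75% reflects that a binary-trained score orders the
continuous expression values only up to the HEG/LEG split.  The
importances show which blocks this particular fit leans on — here all
three blocks carry clean signal and the attention spreads across them.
On a methylation-driven cell line the `me` importance dominates — see
`epifusion.interpretation.collect_block_weights` for the cross-cell-line
version of that comparison and `compatibility_test` for the
train-on-one/test-on-another transfer matrix with clustering.

The same pipeline is scriptable from a shell:

```sh
epifusion simulate --n-genes 500 --seed 1 --out data/sim
epifusion train --data data/sim --omics hm,me,tf --out runs/full
# one subdirectory per cell line, then the cross-cell-line analyses:
epifusion simulate --regime hm --seed 1 --out data/bench/lineA
epifusion simulate --regime me --seed 2 --out data/bench/lineB
epifusion crosscell --benchmark data/bench --out runs/transfer
```

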
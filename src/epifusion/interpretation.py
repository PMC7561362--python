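"""Cross-cell-line interpretation of fitted models.

Two analyses:

* **Block-weight table** — per cell line, the per-omics importance of the
  fusion attention (mean per-dimension attention mass on each omics'
  coordinate range, over that cell line's test genes), then each omics
  column divided by its mean across cell lines, so a value above 1 marks a
  cell line that leans on that block more than average.
* **Compatibility matrix** — AUC of the model trained on cell line i and
  evaluated on cell line j, each column j divided by its own-model AUC
  (train j, test j), so normalized diagonals equal 1.  Rows of the
  normalized matrix are clustered with average-linkage hierarchical
  clustering on Euclidean distances; the dendrogram is exportable as
  Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode
from sklearn.metrics import roc_auc_score

from .estimator import MultiOmicsAttentionClassifier
from .ingest import MultiOmicsDataset

OMICS_COLUMNS = ("HM", "ME", "TF")


@dataclass
class CompatibilityMatrix:
    cell_lines: list[str]
    auc: pd.DataFrame  # raw AUC, rows = training line, cols = test line
    normalized: pd.DataFrame  # column j divided by auc[j, j]
    linkage: np.ndarray  # average-linkage merge tree over normalized rows
    newick: str

    def to_tsv(self, path) -> None:
        self.normalized.to_csv(path, sep="\t")


def _check_architectures(models: dict[str, MultiOmicsAttentionClassifier]) -> None:
    sigs = {
        name: (tuple(m.omics), m.k_attention, m.latent_dim_)
        for name, m in models.items()
    }
    if len(set(sigs.values())) > 1:
        raise ValueError(f"models differ in architecture: {sigs}")


def collect_block_weights(models: dict[str, MultiOmicsAttentionClassifier],
                          datasets: dict[str, MultiOmicsDataset]) -> pd.DataFrame:
    """Normalized per-omics importance table (rows = cell lines).

    ``datasets[name]`` holds the genes (typically the test split) whose
    fusion attention is averaged for cell line ``name``.  Each omics column
    is divided by its mean over cell lines, so column means equal 1.
    """
    missing = set(models) ^ set(datasets)
    if missing:
        raise ValueError(f"models and datasets disagree on cell lines: {missing}")
    _check_architectures(models)
    rows = {}
    for name, model in models.items():
        imp = model.omics_importance(datasets[name])
        rows[name] = {omics.upper(): imp.get(omics.lower(), np.nan)
                      for omics in OMICS_COLUMNS}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[[c for c in OMICS_COLUMNS if table[c].notna().any()]]
    return table / table.mean(axis=0)


def compatibility_test(models: dict[str, MultiOmicsAttentionClassifier],
                       datasets: dict[str, MultiOmicsDataset]) -> CompatibilityMatrix:
    """Train-on-one / test-on-another AUC matrix with clustering.

    Entry (i, j) is the AUC of model i on dataset j; column j is then
    divided by its diagonal (own-model) AUC.  Rows of the normalized
    matrix are clustered (average linkage, Euclidean).
    """
    missing = set(models) ^ set(datasets)
    if missing:
        raise ValueError(f"missing model/dataset pairs: {missing}")
    if len(models) < 2:
        raise ValueError("compatibility test needs at least 2 cell lines")
    _check_architectures(models)
    names = list(models)
    auc = np.zeros((len(names), len(names)))
    for i, train_name in enumerate(names):
        for j, test_name in enumerate(names):
            ds = datasets[test_name]
            scores = models[train_name].decision_function(ds)
            auc[i, j] = roc_auc_score((ds.labels + 1) // 2, scores)
    auc_df = pd.DataFrame(auc, index=names, columns=names)
    normalized = auc_df / np.diag(auc)[None, :]
    Z = linkage(pdist(normalized.to_numpy(), metric="euclidean"), method="average")
    tree = TreeNode.from_linkage_matrix(Z, names)
    newick = str(tree).strip()
    return CompatibilityMatrix(
        cell_lines=names, auc=auc_df, normalized=normalized, linkage=Z, newick=newick,
    )
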
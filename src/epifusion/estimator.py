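"""Scikit-learn style estimator for the multi-omics attention classifier.

:class:`MultiOmicsAttentionClassifier` composes the omics encoders and the
multi-attention fusion block into one end-to-end binary classifier of gene
expression level (+1 = highly expressed, -1 = lowly expressed).  ``X`` is a
:class:`~epifusion.ingest.MultiOmicsDataset` (or a list of
:class:`~epifusion.ingest.OmicsExample`); ``y`` defaults to the dataset's
own HEG/LEG labels.  Omics branches excluded via ``omics`` are omitted from
the network entirely — their parameters do not exist, rather than being
zeroed.

Training minimizes binary cross-entropy on ``sigmoid(score)`` with labels
mapped {+1 -> 1, -1 -> 0}, using the Adam optimizer with early stopping on
validation AUC.  All randomness (initialization, validation split, batch
order) flows from ``random_state``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import nn
from .autograd import Tensor, concat
from .encoders import EncoderConfig, HistoneEncoder, MethylationEncoder, TFEncoder
from .fusion import MultiAttentionBlock, omics_block_importance
from .ingest import MultiOmicsDataset

OMICS_ORDER = ("hm", "me", "tf")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class AttentionBundle:
    """Every attention surface the model computes for one gene.

    Fields are None for omics branches the model was built without.
    """

    bin_attention: np.ndarray | None  # (12,) pooled histone positions
    cpg_attention: np.ndarray | None  # (n_cpgs,)
    tf_attention: np.ndarray | None  # (c, c) over the gene's candidate TFs
    block_attention: np.ndarray  # (k, latent_dim) fusion heads


def _as_dataset(X) -> MultiOmicsDataset:
    if isinstance(X, MultiOmicsDataset):
        return X
    return MultiOmicsDataset.from_examples(list(X))


class MultiOmicsAttentionClassifier(BaseEstimator, ClassifierMixin):
    """Attention-based multi-omics HEG/LEG classifier.

    Parameters
    ----------
    omics : tuple of {"hm", "me", "tf"}
        Feature blocks to include (histone marks, CpG methylation,
        transcription factors).  Branch order in the concatenated latent
        vector is always hm, me, tf.
    k_attention : int
        Number of fusion attention heads.
    learning_rate, batch_size, max_epochs, patience, validation_fraction :
        Optimization settings; early stopping monitors validation AUC.
    random_state : int
        Seeds initialization, the validation split and batch shuffling.
    """

    def __init__(self, omics=("hm", "me", "tf"), k_attention: int = 4,
                 conv_kernels: int = 100, hm_lstm_hidden: int = 40,
                 me_lstm_hidden: int = 10, tf_latent: int = 5,
                 tf_qkv_dim: int = 8, attn_hidden: int = 32,
                 learning_rate: float = 3e-3, batch_size: int = 128,
                 max_epochs: int = 25, patience: int = 5,
                 validation_fraction: float = 0.15,
                 random_state: int = 0, verbose: int = 0):
        self.omics = omics
        self.k_attention = k_attention
        self.conv_kernels = conv_kernels
        self.hm_lstm_hidden = hm_lstm_hidden
        self.me_lstm_hidden = me_lstm_hidden
        self.tf_latent = tf_latent
        self.tf_qkv_dim = tf_qkv_dim
        self.attn_hidden = attn_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- construction ------------------------------------------------------
    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            conv_kernels=self.conv_kernels,
            hm_lstm_hidden=self.hm_lstm_hidden,
            me_lstm_hidden=self.me_lstm_hidden,
            tf_latent=self.tf_latent,
            tf_qkv_dim=self.tf_qkv_dim,
            attn_hidden=self.attn_hidden,
            seed=self.random_state,
        )

    def _build(self) -> None:
        omics = tuple(self.omics)
        if not omics or any(o not in OMICS_ORDER for o in omics):
            raise ValueError(f"omics must be a nonempty subset of {OMICS_ORDER}")
        if self.k_attention < 1:
            raise ValueError("k_attention must be >= 1")
        cfg = self._encoder_config()
        rng = np.random.default_rng(self.random_state)
        self.encoders_ = {}
        sizes = {}
        if "hm" in omics:
            self.encoders_["hm"] = HistoneEncoder(cfg, rng)
            sizes["hm"] = cfg.hm_latent
        if "me" in omics:
            self.encoders_["me"] = MethylationEncoder(cfg, rng)
            sizes["me"] = cfg.me_latent
        if "tf" in omics:
            self.encoders_["tf"] = TFEncoder(cfg, rng)
            sizes["tf"] = cfg.tf_latent
        self.block_sizes_ = sizes
        self.latent_dim_ = sum(sizes.values())
        self.fusion_ = MultiAttentionBlock(self.latent_dim_, self.k_attention, rng)
        self.config_ = cfg

    def _modules(self) -> list[nn.Module]:
        return list(self.encoders_.values()) + [self.fusion_]

    def _parameters(self) -> list[nn.Parameter]:
        params = []
        for m in self._modules():
            params.extend(m.parameters())
        return params

    @property
    def n_parameters_(self) -> int:
        return int(sum(p.data.size for p in self._parameters()))

    def _set_training(self, mode: bool) -> None:
        for m in self._modules():
            m.train(mode)

    # -- forward -----------------------------------------------------------
    def _tf_compact(self, ds: MultiOmicsDataset, idx: np.ndarray):
        counts = [len(ds.tf_idx[i]) for i in idx]
        C = max(1, max(counts, default=1))
        B = len(idx)
        vals = np.zeros((B, C, 3))
        mask = np.zeros((B, C), dtype=bool)
        for row, i in enumerate(idx):
            c = len(ds.tf_idx[i])
            if c:
                vals[row, :c, :] = ds.tf_vals[i].T
                mask[row, :c] = True
        return vals, mask

    def _forward(self, ds: MultiOmicsDataset, idx: np.ndarray,
                 collect_attention: bool = False):
        parts = []
        attn: dict = {}
        if "hm" in self.encoders_:
            h, w = self.encoders_["hm"](Tensor(ds.hm[idx]))
            parts.append(h)
            if collect_attention:
                attn["bin_attention"] = w.data.copy()
        if "me" in self.encoders_:
            betas = [ds.me_betas[i] for i in idx]
            h, w = self.encoders_["me"](betas)
            parts.append(h)
            if collect_attention:
                attn["cpg_attention"] = [
                    w.data[r, : len(b)].copy() for r, b in enumerate(betas)
                ]
        if "tf" in self.encoders_:
            vals, mask = self._tf_compact(ds, idx)
            h, w = self.encoders_["tf"](vals, mask)
            parts.append(h)
            if collect_attention:
                attn["tf_attention"] = [
                    w.data[r][: c, : c].copy()
                    for r, c in enumerate(mask.sum(axis=1))
                ]
        h = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
        scores, a = self.fusion_(h)
        if collect_attention:
            attn["block_attention"] = a.data.copy()
        return scores, attn

    # -- fit ---------------------------------------------------------------
    def fit(self, X, y=None, validation=None):
        """Fit on a multi-omics dataset.

        ``validation`` may be ``(X_val, y_val)``; otherwise
        ``validation_fraction`` of the training genes is held out.
        Keeps the parameter state with the best validation AUC.
        """
        ds = _as_dataset(X)
        y = np.asarray(ds.labels if y is None else y)
        if set(np.unique(y)) - {-1, 1}:
            raise ValueError("labels must be in {+1, -1}")
        self._build()
        rng = np.random.default_rng(self.random_state + 1)

        n = len(ds)
        if validation is not None:
            ds_val = _as_dataset(validation[0])
            y_val = np.asarray(validation[1])
            train_idx = np.arange(n)
        else:
            perm = rng.permutation(n)
            n_val = max(1, int(round(self.validation_fraction * n)))
            val_idx = perm[:n_val]
            train_idx = perm[n_val:]
            ds_val = ds.subset(val_idx)
            y_val = y[val_idx]

        y01 = (y + 1) // 2
        opt = nn.Adam(self._parameters(), lr=self.learning_rate)
        best_metric = -np.inf
        best_state = None
        best_epoch = -1
        history = []
        stale = 0
        for epoch in range(self.max_epochs):
            self._set_training(True)
            order = rng.permutation(train_idx)
            losses = []
            for lo in range(0, len(order), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                if len(batch) < 2:
                    continue  # batch-norm needs more than one sample
                scores, _ = self._forward(ds, batch)
                loss = nn.bce_with_logits(scores, y01[batch])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"divergent training loss ({loss.data}) at epoch {epoch}; "
                        "lower the learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_scores = self._scores(ds_val)
            if len(np.unique(y_val)) == 2:
                val_metric = roc_auc_score((y_val + 1) // 2, val_scores)
            else:  # degenerate split: fall back to negative loss
                val_metric = -float(np.mean(losses)) if losses else 0.0
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)) if losses else np.nan,
                 "val_auc": float(val_metric)}
            )
            if self.verbose:
                print(f"epoch {epoch}: loss={history[-1]['train_loss']:.4f} "
                      f"val_auc={val_metric:.4f}")
            if val_metric > best_metric:
                best_metric = val_metric
                best_state = [p.data.copy() for p in self._parameters()]
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale > self.patience:
                    break
        if best_state is not None:
            for p, a in zip(self._parameters(), best_state):
                p.data = a
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_auc_ = float(best_metric)
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = self.latent_dim_
        return self

    # -- inference -----------------------------------------------------------
    def _scores(self, ds: MultiOmicsDataset, chunk: int = 512) -> np.ndarray:
        self._set_training(False)
        out = []
        for lo in range(0, len(ds), chunk):
            idx = np.arange(lo, min(lo + chunk, len(ds)))
            scores, _ = self._forward(ds, idx)
            out.append(scores.data)
        return np.concatenate(out) if out else np.empty(0)

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self._scores(_as_dataset(X))

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([1 - p, p])

    def attention(self, X) -> dict:
        """All attention surfaces for the genes of ``X``.

        Returns a dict with (depending on ``omics``) ``bin_attention``
        (n, 12), ``cpg_attention`` (list of per-gene arrays),
        ``tf_attention`` (list of per-gene candidate-square matrices) and
        ``block_attention`` (n, k, latent_dim).
        """
        self._check_fitted()
        ds = _as_dataset(X)
        self._set_training(False)
        collected: dict = {}
        ragged: set = set()  # per-gene lists (variable shapes) stay lists
        for lo in range(0, len(ds), 512):
            idx = np.arange(lo, min(lo + 512, len(ds)))
            _, attn = self._forward(ds, idx, collect_attention=True)
            for key, val in attn.items():
                if isinstance(val, list):
                    ragged.add(key)
                    collected.setdefault(key, []).extend(val)
                else:
                    collected.setdefault(key, []).append(val)
        return {
            k: (v if k in ragged else np.concatenate(v))
            for k, v in collected.items()
        }

    def attention_bundles(self, X) -> list[AttentionBundle]:
        """Per-gene :class:`AttentionBundle` objects for the genes of ``X``."""
        attn = self.attention(X)
        n = len(attn["block_attention"])
        bundles = []
        for i in range(n):
            bundles.append(
                AttentionBundle(
                    bin_attention=attn.get("bin_attention", [None] * n)[i],
                    cpg_attention=attn.get("cpg_attention", [None] * n)[i],
                    tf_attention=attn.get("tf_attention", [None] * n)[i],
                    block_attention=attn["block_attention"][i],
                )
            )
        return bundles

    def omics_importance(self, X) -> dict[str, float]:
        """Normalized per-omics importance from the fusion attention weights."""
        attn = self.attention(X)
        return omics_block_importance(attn["block_attention"], self.block_sizes_)

    def _check_fitted(self):
        if not hasattr(self, "fusion_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: parameters + estimator config (versioned)."""
        self._check_fitted()
        meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "params": self.get_params()}
        arrays = {f"p{i}": p.data for i, p in enumerate(self._parameters())}
        running = {}
        for name, enc in list(self.encoders_.items()):
            if hasattr(enc, "bn"):
                running[f"{name}_bn_mean"] = enc.bn.running_mean
                running[f"{name}_bn_var"] = enc.bn.running_var
        np.savez(path, meta=json.dumps(meta), **arrays, **running)

    @classmethod
    def load(cls, path) -> "MultiOmicsAttentionClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            params = meta["params"]
            params["omics"] = tuple(params["omics"])
            est = cls(**params)
            est._build()
            est.load_state(z)
        est.classes_ = np.array([-1, 1])
        est.history_ = []
        est.best_epoch_ = -1
        est.best_val_auc_ = float("nan")
        return est

    def load_state(self, z) -> None:
        for i, p in enumerate(self._parameters()):
            p.data = z[f"p{i}"].astype(np.float64)
        for name, enc in self.encoders_.items():
            if hasattr(enc, "bn") and f"{name}_bn_mean" in z:
                enc.bn.running_mean = z[f"{name}_bn_mean"].astype(np.float64)
                enc.bn.running_var = z[f"{name}_bn_var"].astype(np.float64)
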
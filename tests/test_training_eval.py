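"""Fold protocol, metrics against brute-force oracles, and training contracts."""

import numpy as np
import pytest

from epifusion.synthetic_data import SimConfig, simulate_dataset
from epifusion.training_eval import (
    TrainConfig,
    cross_validate,
    evaluate,
    make_folds,
    train_model,
)


class TestFolds:
    def test_exact_division(self):
        splits = make_folds([f"g{i}" for i in range(8)], seed=0)
        sizes = sorted(len(s.test) for s in splits)
        assert sizes == [2, 2, 2, 2]

    def test_near_equal_sizes_for_10_genes(self):
        splits = make_folds([f"g{i}" for i in range(10)], seed=1)
        sizes = sorted(len(s.test) for s in splits)
        assert sizes == [2, 2, 3, 3]  # counting oracle: 10 = 3+3+2+2

    def test_every_gene_tests_exactly_once_and_roles_partition(self):
        ids = [f"g{i}" for i in range(23)]
        splits = make_folds(ids, seed=3)
        seen = [g for s in splits for g in s.test]
        assert sorted(seen) == sorted(ids)
        for s in splits:
            assert sorted(s.all_ids()) == sorted(ids)
            assert not (set(s.test) & set(s.validation))
            assert not (set(s.test) & set(s.train))

    def test_deterministic_given_seed(self):
        ids = [f"g{i}" for i in range(17)]
        assert make_folds(ids, seed=9) == make_folds(ids, seed=9)
        assert make_folds(ids, seed=9) != make_folds(ids, seed=10)

    def test_fewer_genes_than_folds_raises(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], n_folds=4)


def brute_force_auc(scores, labels):
    """Concordant HEG/LEG pairs over all pairs, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_spearman(x, y):
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ranks for ties
        for val in np.unique(v):
            m = v == val
            r[m] = r[m].mean()
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestEvaluate:
    def test_perfect_ranking_gives_auc_one(self):
        rep = evaluate([1, 2, 3, 4], [-1, -1, 1, 1], [0.1, 0.2, 5.0, 9.0])
        assert rep.auc == 1.0
        assert rep.aupr == 1.0

    def test_anti_perfect_ranking_gives_auc_zero(self):
        rep = evaluate([4, 3, 2, 1], [-1, -1, 1, 1], [0.1, 0.2, 5.0, 9.0])
        assert rep.auc == 0.0

    def test_six_point_toy_matches_pairwise_and_rank_oracles(self):
        scores = [0.3, 0.1, 0.4, 0.4, 0.9, 0.2]
        labels = [-1, -1, 1, -1, 1, 1]
        exprs = [0.5, 0.1, 3.0, 0.4, 9.0, 2.0]
        rep = evaluate(scores, labels, exprs)
        assert rep.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert rep.rank_concordance == pytest.approx(
            brute_force_spearman(scores, exprs), abs=1e-12
        )

    def test_auc_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) > 0.5, 1, -1)
        labels[:2] = [1, -1]
        exprs = rng.random(50)
        a = evaluate(scores, labels, exprs).auc
        b = evaluate(np.exp(3 * scores) + 7, labels, exprs).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError, match="single-class"):
            evaluate([1, 2], [1, 1], [0.5, 0.6])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            evaluate([1, 2], [1, -1, 1], [0.5, 0.6, 0.7])


@pytest.fixture(scope="module")
def tiny_ds():
    ds, _ = simulate_dataset(SimConfig(seed=21, n_genes=80, regime="hm"))
    return ds


class TestTraining:
    def test_same_seed_reproduces_metrics_bit_identically(self, tiny_ds):
        cfg = TrainConfig(epochs=2, seed=5, batch_size=32)
        folds = make_folds(tiny_ds.gene_ids, seed=5)
        est1, log1 = train_model(tiny_ds, folds[0], cfg)
        est2, log2 = train_model(tiny_ds, folds[0], cfg)
        assert log1 == log2
        s1 = est1.decision_function(tiny_ds)
        s2 = est2.decision_function(tiny_ds)
        assert np.array_equal(s1, s2)

    def test_loss_descends_on_separable_data(self):
        ds, _ = simulate_dataset(SimConfig(seed=22, n_genes=120, regime="hm"))
        cfg = TrainConfig(epochs=6, seed=1, batch_size=32, omics_subset=("hm",))
        _, log = train_model(ds, make_folds(ds.gene_ids, seed=1)[0], cfg)
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_omics_subset_omits_other_branches(self, tiny_ds):
        from epifusion.estimator import MultiOmicsAttentionClassifier

        full = MultiOmicsAttentionClassifier()
        full._build()
        hm_only = MultiOmicsAttentionClassifier(omics=("hm",))
        hm_only._build()
        assert set(hm_only.encoders_) == {"hm"}
        assert hm_only.n_parameters_ < full.n_parameters_
        me_tf = sum(
            p.data.size for name in ("me", "tf") for p in full.encoders_[name].parameters()
        )
        # difference = absent encoder branches + the narrower fusion block
        fusion_diff = full.fusion_.attn_map.weight.data.size - hm_only.fusion_.attn_map.weight.data.size
        assert full.n_parameters_ - hm_only.n_parameters_ > me_tf

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergent_loss_aborts_with_diagnostic(self, tiny_ds):
        # a step size near the float ceiling overflows the parameters,
        # so the next forward pass produces a non-finite loss
        cfg = TrainConfig(epochs=3, seed=0, learning_rate=1e200, batch_size=32)
        with pytest.raises(RuntimeError, match="divergent"):
            train_model(tiny_ds, make_folds(tiny_ds.gene_ids, seed=0)[0], cfg)


def test_cross_validate_reports_mean_over_rotations(tiny_ds):
    cfg = TrainConfig(epochs=1, seed=2, batch_size=32, omics_subset=("me",))
    report = cross_validate(tiny_ds, cfg)
    assert len(report) == 5  # 4 rotations + mean
    rotations = report[report["fold"] != "mean"]
    mean_row = report[report["fold"] == "mean"].iloc[0]
    assert mean_row["auc"] == pytest.approx(rotations["auc"].mean())
    assert (report["omics_subset"] == "ME").all()
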
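"""Composite losses, fold splitting, and the training loop."""

import numpy as np
import pytest

from npfp import (
    FeaturizedDataset,
    ModelSpec,
    OptimizerConfig,
    composite_loss,
    cross_validate,
    make_folds,
    one_cycle_lr,
    train_fold,
)
from npfp.errors import ShapeError
from npfp.training import _bce_with_logits


def spec_for(arch, epochs=3, **kw):
    return ModelSpec(arch=arch, seed=0,
                     optimizer=OptimizerConfig(epochs=epochs, batch_size=64),
                     **kw)


class TestCompositeLoss:
    def test_perfect_predictions_give_zero(self):
        big = 50.0  # saturated logits: BCE ~ 0 to double precision
        out = {"np_logit": np.array([big, -big])}
        tgt = {"np": np.array([1.0, 0.0])}
        assert composite_loss(out, tgt, spec_for("baseline")) == \
            pytest.approx(0.0, abs=1e-12)
        out_aux = {"np_logit": np.array([big, -big]),
                   "aux": np.ones((2, 48))}
        tgt_aux = {"np": np.array([1.0, 0.0]), "aux": np.ones((2, 48))}
        assert composite_loss(out_aux, tgt_aux, spec_for("aux")) == \
            pytest.approx(0.0, abs=1e-12)

    def test_bce_at_half_probability_is_ln2(self):
        out = {"np_logit": np.array([0.0]),
               "recon_logit": np.full((1, 2048), 50.0)}
        tgt = {"np": np.array([1.0]), "recon": np.ones((1, 2048))}
        loss = composite_loss(out, tgt, spec_for("ae"))
        assert loss == pytest.approx(np.log(2), abs=1e-10)

    def test_aux_loss_is_weighted_sum_of_task_losses(self):
        """The composite equals (1 BCE + sum of 48 RMSEs) / 49, computed
        independently task by task."""
        rng = np.random.default_rng(0)
        n, k = 32, 48
        out = {"np_logit": rng.normal(size=n), "aux": rng.normal(size=(n, k))}
        tgt = {"np": rng.integers(0, 2, n).astype(float),
               "aux": rng.normal(size=(n, k))}
        spec = spec_for("aux")
        bce = _bce_with_logits(out["np_logit"], tgt["np"])
        rmses = [np.sqrt(np.mean((out["aux"][:, j] - tgt["aux"][:, j]) ** 2))
                 for j in range(k)]
        expected = (bce + sum(rmses)) / (1 + k)
        assert composite_loss(out, tgt, spec) == pytest.approx(
            expected, abs=1e-12)

    def test_aux_descriptor_share_scales_linearly(self):
        """Doubling only the descriptor errors moves the loss by exactly
        the descriptor term's share (RMSE is positively homogeneous)."""
        rng = np.random.default_rng(1)
        n, k = 16, 4
        z = rng.normal(size=n)
        t = rng.integers(0, 2, n).astype(float)
        resid = rng.normal(size=(n, k))
        y = rng.normal(size=(n, k))
        spec = spec_for("aux", n_aux=k)
        l1 = composite_loss({"np_logit": z, "aux": y + resid},
                            {"np": t, "aux": y}, spec)
        l2 = composite_loss({"np_logit": z, "aux": y + 2 * resid},
                            {"np": t, "aux": y}, spec)
        bce_share = _bce_with_logits(z, t) / (1 + k)
        assert l2 - bce_share == pytest.approx(2 * (l1 - bce_share), rel=1e-12)

    def test_ae_loss_is_bce_plus_weighted_reconstruction(self):
        rng = np.random.default_rng(2)
        n, d = 8, 32
        out = {"np_logit": rng.normal(size=n),
               "recon_logit": rng.normal(size=(n, d))}
        tgt = {"np": rng.integers(0, 2, n).astype(float),
               "recon": rng.integers(0, 2, (n, d)).astype(float)}
        spec = spec_for("ae", input_dim=d)
        expected = _bce_with_logits(out["np_logit"], tgt["np"]) + \
            100.0 * _bce_with_logits(out["recon_logit"], tgt["recon"])
        assert composite_loss(out, tgt, spec) == pytest.approx(
            expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            composite_loss({"np_logit": np.zeros(3)}, {"np": np.zeros(4)},
                           spec_for("baseline"))


class TestFolds:
    def test_fold_sizes_within_one(self, small_records):
        split = make_folds(small_records, k=5, seed=0)
        sizes = [len(split.fold_ids(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_identical(self, small_records):
        a = make_folds(small_records, k=5, seed=11)
        b = make_folds(small_records, k=5, seed=11)
        assert a.assignments == b.assignments

    def test_partition_covers_all_ids(self, small_records):
        split = make_folds(small_records, k=5, seed=0)
        union = set()
        for f in range(5):
            ids = split.fold_ids(f)
            assert union.isdisjoint(ids)
            union |= ids
        assert union == {r.id for r in small_records}

    def test_n10_k5_gives_folds_of_two(self, small_records):
        split = make_folds(small_records[:10], k=5, seed=0)
        assert all(len(split.fold_ids(f)) == 2 for f in range(5))


class TestTrainFold:
    def test_zero_epochs_returns_untrained_model(self, small_featurized,
                                                 small_split):
        m = train_fold(small_featurized, small_split, 0,
                       spec_for("baseline", epochs=0))
        assert m.train_metrics["epoch_losses"] == []
        assert 0.1 < m.train_metrics["val_auc"] < 0.9

    def test_same_seed_reproduces_metrics_exactly(self, small_featurized,
                                                  small_split):
        spec = spec_for("baseline", epochs=3)
        a = train_fold(small_featurized, small_split, 0, spec)
        b = train_fold(small_featurized, small_split, 0, spec)
        assert a.train_metrics["val_auc"] == b.train_metrics["val_auc"]
        assert a.train_metrics["epoch_losses"] == \
            b.train_metrics["epoch_losses"]

    def test_separable_fixture_reaches_high_auc(self, trained_models):
        for arch, model in trained_models.items():
            assert model.train_metrics["val_auc"] >= 0.95, arch

    def test_aux_standardizer_fitted_on_training_fold_only(
            self, small_featurized, small_split):
        m = train_fold(small_featurized, small_split, 0,
                       spec_for("aux", epochs=1))
        val_ids = small_split.fold_ids(0)
        train_mask = np.array([rid not in val_ids
                               for rid in small_featurized.ids])
        D_tr = small_featurized.descriptors[train_mask]
        assert np.allclose(m.scaler_mean, D_tr.mean(axis=0))


class TestCrossValidate:
    def test_five_models_and_summary_stats(self, small_featurized):
        models, summary = cross_validate(small_featurized,
                                         spec_for("baseline", epochs=2), k=5)
        assert len(models) == 5
        aucs = [m.train_metrics["val_auc"] for m in models]
        assert summary["val_auc"]["mean"] == pytest.approx(np.mean(aucs))
        assert summary["val_auc"]["sd"] == pytest.approx(np.std(aucs))
        assert summary["val_auc"]["n_folds"] == 5


def test_one_cycle_schedule_shape():
    total, lr_max = 100, 1e-3
    lrs = [one_cycle_lr(s, total, lr_max) for s in range(total)]
    peak = int(np.argmax(lrs))
    assert lrs[peak] == pytest.approx(lr_max)
    assert 20 <= peak <= 40  # peak near pct_start = 0.3
    assert lrs[0] < lr_max / 10
    assert lrs[-1] < lr_max / 100
    # rises monotonically before the peak, falls after
    assert all(a <= b + 1e-15 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))
    assert all(a >= b - 1e-15 for a, b in zip(lrs[peak:], lrs[peak + 1:]))
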
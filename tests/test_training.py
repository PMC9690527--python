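import numpy as np
import pytest

from omsas.acrnet import build_acrnet, tiny_config
from omsas.preprocess import PreprocessConfig, preprocess_sample
from omsas.synthetic_data import easy_params, generate_phantom
from omsas.training import (SplitSpec, TrainConfig, TverskyParams,
                            evaluate_dsc, kfold_patients, split_patients,
                            train, tversky_index, tversky_loss,
                            tversky_loss_grad)

P = TverskyParams()


class TestTversky:
    def test_perfect_prediction(self):
        q = np.array([1.0, 0.0, 1.0, 1.0])
        assert tversky_index(q, q, P) == pytest.approx(1.0, abs=1e-7)
        assert tversky_loss(q, q, P) == pytest.approx(0.0, abs=1e-7)

    def test_disjoint_prediction_is_zero(self):
        pred = np.ones(6)
        truth = np.zeros(6)
        assert tversky_index(pred, truth, P) == 0.0
        assert tversky_loss(pred, truth, P) == 1.0

    def test_four_pixel_worked_example(self):
        # TP=1, FP=1, FN=1: T = 1 / (1 + 0.25*1 + 0.75*1) = 0.5
        pred = np.array([1.0, 1.0, 0.0, 0.0])
        truth = np.array([1.0, 0.0, 1.0, 0.0])
        assert tversky_index(pred, truth, P) == pytest.approx(0.5, abs=1e-7)

    def test_alpha_beta_half_is_dice(self):
        """alpha = beta = 0.5 reduces the index to the Dice coefficient,
        exactly, on random binary pairs."""
        rng = np.random.default_rng(0)
        half = TverskyParams(alpha=0.5, beta=0.5, epsilon=1e-30)
        for _ in range(200):
            pred = (rng.random(50) > 0.5).astype(float)
            truth = (rng.random(50) > 0.5).astype(float)
            tp = float((pred * truth).sum())
            fp = float((pred * (1 - truth)).sum())
            fn = float((truth * (1 - pred)).sum())
            if 2 * tp + fp + fn == 0:
                continue
            dice = 2 * tp / (2 * tp + fp + fn)
            assert abs(tversky_index(pred, truth, half) - dice) < 1e-12

    def test_bounded_and_monotone_under_errors(self):
        rng = np.random.default_rng(1)
        pred = (rng.random(30) > 0.5).astype(float)
        truth = pred.copy()
        t0 = tversky_index(pred, truth, P)
        assert 0.0 <= t0 <= 1.0
        # adding a false positive can only lower the index
        fp_pred = pred.copy()
        fp_pred[np.flatnonzero(truth == 0)[0]] = 1.0
        assert tversky_index(fp_pred, truth, P) <= t0
        # adding a false negative can only lower the index
        fn_pred = pred.copy()
        fn_pred[np.flatnonzero(truth == 1)[0]] = 0.0
        assert tversky_index(fn_pred, truth, P) <= t0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            tversky_index(np.zeros(3), np.zeros(4), P)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        pred = rng.uniform(0.05, 0.95, 20)
        truth = (rng.random(20) > 0.6).astype(float)
        loss, grad = tversky_loss_grad(pred, truth, P)
        eps = 1e-7
        for i in range(20):
            pp, pm = pred.copy(), pred.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (tversky_loss(pp, truth, P) - tversky_loss(pm, truth, P)) / (2 * eps)
            assert abs(num - grad[i]) < 1e-6


class TestSplits:
    def test_210_patients_give_147_63(self):
        ids = [f"P{i}" for i in range(210)]
        for seed in (0, 1, 99):
            train_ids, test_ids = split_patients(ids, SplitSpec(seed=seed))
            assert len(train_ids) == 147 and len(test_ids) == 63

    def test_10_patients_give_7_3(self):
        train_ids, test_ids = split_patients([f"P{i}" for i in range(10)],
                                             SplitSpec(seed=5))
        assert len(train_ids) == 7 and len(test_ids) == 3

    def test_partition_property(self):
        ids = [f"P{i}" for i in range(37)]
        for seed in range(5):
            tr, te = split_patients(ids, SplitSpec(seed=seed))
            assert set(tr) | set(te) == set(ids)
            assert set(tr) & set(te) == set()

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_patients(["only"], SplitSpec())

    def test_kfold_147_ids_balanced(self):
        folds = kfold_patients([f"P{i}" for i in range(147)],
                               SplitSpec(k_folds=10, seed=3))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [14, 14, 14, 15, 15, 15, 15, 15, 15, 15]
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(f"P{i}" for i in range(147))

    def test_leave_one_out(self):
        folds = kfold_patients(list("abcde"), SplitSpec(k_folds=5, seed=0))
        assert all(len(f) == 1 for f in folds)

    def test_kfold_seeded_determinism(self):
        ids = [f"P{i}" for i in range(23)]
        a = kfold_patients(ids, SplitSpec(k_folds=4, seed=8))
        b = kfold_patients(ids, SplitSpec(k_folds=4, seed=8))
        assert a == b


@pytest.fixture(scope="module")
def tiny_training_set():
    params = easy_params(seed=13)
    cfg = PreprocessConfig(target_size=(32, 32))
    imgs, masks = [], []
    for i in range(8):
        slc, mask, _ = generate_phantom(params, i)
        ps, pm = preprocess_sample(slc, mask, cfg)
        imgs.append(ps.pixels)
        masks.append(pm.pixels)
    return np.stack(imgs), np.stack(masks)


def micro_model(seed=13):
    from omsas.acrnet import ACRNetConfig
    return build_acrnet(ACRNetConfig(input_size=(32, 32),
                                     stage_widths=(8, 16),
                                     units_per_stage=1, condenser_ratio=2,
                                     seed=seed))


class TestTrainLoop:
    def test_overfit_probe_loss_falls(self, tiny_training_set):
        """A micro network memorises 8 easy phantoms: the Tversky loss
        drops below 0.1 within a couple hundred steps."""
        imgs, masks = tiny_training_set
        model = micro_model()
        tcfg = TrainConfig(learning_rate=3e-3, epochs=30, batch_size=2,
                           seed=13)
        log = train(model, imgs, masks, tcfg=tcfg)
        assert log[-1]["loss"] < 0.1
        assert log[-1]["loss"] < log[0]["loss"]

    def test_epoch0_deterministic(self, tiny_training_set):
        imgs, masks = tiny_training_set
        tcfg = TrainConfig(learning_rate=1e-4, epochs=1, batch_size=2, seed=4)
        log1 = train(micro_model(seed=4), imgs, masks, tcfg=tcfg)
        log2 = train(micro_model(seed=4), imgs, masks, tcfg=tcfg)
        assert log1[0]["loss"] == log2[0]["loss"]

    def test_checkpoint_round_trip_preserves_val_dsc(self, tiny_training_set,
                                                     tmp_path):
        from omsas.acrnet import ACRNet
        imgs, masks = tiny_training_set
        model = micro_model(seed=6)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=2, seed=6,
                           checkpoint_dir=str(tmp_path),
                           log_path=str(tmp_path / "log.csv"))
        log = train(model, imgs[:6], masks[:6], imgs[6:], masks[6:], tcfg=tcfg)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "log.csv").exists()
        restored = ACRNet.load(tmp_path / "best.npz")
        dsc_restored = evaluate_dsc(restored, imgs[6:], masks[6:])
        dsc_best = max(r["val_dsc"] for r in log)
        assert dsc_restored == pytest.approx(dsc_best, abs=1e-12)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(micro_model(), np.empty((0, 32, 32)), np.empty((0, 32, 32)))
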
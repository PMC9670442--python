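"""Patient-wise splitting, loss functions, and the training loop."""

import numpy as np
import pandas as pd
import pytest

import cardiov.ordinal as ordinal
from cardiov.model import CardioVNet, ModelConfig
from cardiov.nn import Tensor
from cardiov.training import (
    SplitSpec,
    TrainConfig,
    bce_with_logits,
    build_ablation_head,
    head_predictions,
    mse_loss,
    softmax_cross_entropy,
    split_patients,
    train,
)

SMOKE_CONFIG = ModelConfig(stage_channels=(8,), stage_blocks=(1,), groups=4,
                           se_reduction=4, kernel_size=8, dropout_rate=0.1)


def metadata_frame(patient_of_record):
    return pd.DataFrame({"patient_id": patient_of_record})


class TestSplitPatients:
    def test_ten_singleton_patients_split_8_1_1(self):
        md = metadata_frame([f"p{i}" for i in range(10)])
        tr, va, te = split_patients(md, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_multi_record_patient_stays_together(self):
        md = metadata_frame([f"p{i}" for i in range(9)] + ["p0"] * 4)
        p0_records = set(md.index[md["patient_id"] == "p0"])
        for seed in range(10):
            splits = split_patients(md, SplitSpec(seed=seed))
            homes = [set(s) & p0_records for s in splits]
            non_empty = [h for h in homes if h]
            assert len(non_empty) == 1 and non_empty[0] == p0_records

    def test_partition_and_disjointness_across_seeds(self, small_dataset):
        _, _, md = small_dataset
        for seed in range(50):
            tr, va, te = split_patients(md, SplitSpec(seed=seed))
            ids = tr + va + te
            assert sorted(ids) == sorted(md.index)
            p = md["patient_id"]
            assert not (set(p[tr]) & set(p[va]))
            assert not (set(p[tr]) & set(p[te]))
            assert not (set(p[va]) & set(p[te]))

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_patients(metadata_frame(["a", "b"]))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.5, 0.0))


class TestLosses:
    def test_bce_with_logits_matches_probability_form(self, rng):
        for _ in range(100):
            z = rng.normal(scale=3, size=(4, 3))
            y = ordinal.encode_cumulative(rng.integers(0, 4, 4))
            stable = float(bce_with_logits(Tensor(z), y).data)
            direct = ordinal.ordinal_loss(ordinal.cumulative_probs(z), y)
            assert stable == pytest.approx(direct, abs=1e-9)

    def test_softmax_ce_matches_manual_logsumexp(self, rng):
        z = rng.normal(size=(5, 4))
        labels = rng.integers(0, 4, 5)
        expected = np.mean([
            np.log(np.exp(z[i]).sum()) - z[i, labels[i]] for i in range(5)])
        assert float(softmax_cross_entropy(Tensor(z), labels).data) == \
            pytest.approx(expected)

    def test_mse_loss(self):
        out = Tensor(np.array([[0.5], [2.0]]))
        assert float(mse_loss(out, np.array([0.0, 3.0])).data) == \
            pytest.approx((0.25 + 1.0) / 2)


@pytest.fixture(scope="module")
def smoke_data():
    from cardiov.synthetic import generate_dataset

    signals, labels, _ = generate_dataset(12, seed=77)  # 48 records
    return (signals[:36], labels[:36]), (signals[36:], labels[36:])


class TestTrainLoop:
    def test_two_phase_history_and_learning(self, smoke_data):
        train_set, val_set = smoke_data
        net = CardioVNet(SMOKE_CONFIG, seed=0)
        cfg = TrainConfig(batch_size=12, learning_rate=3e-3, seed=0,
                          head="ordinal", phase1_epochs=2, phase2_epochs=2)
        hist = train(net, train_set, val_set, cfg)
        assert hist.phase == [1, 1, 2, 2]
        assert len(hist.train_loss) == 4
        # phase-2 objective decreases over its epochs
        assert hist.train_loss[3] < hist.train_loss[2]
        # phase-1 objective decreases too
        assert hist.train_loss[1] < hist.train_loss[0]

    def test_same_seed_reproduces_epoch1_loss(self, smoke_data):
        train_set, val_set = smoke_data
        losses = []
        for _ in range(2):
            net = CardioVNet(SMOKE_CONFIG, seed=5)
            cfg = TrainConfig(batch_size=12, learning_rate=1e-3, seed=5,
                              head="classification", phase1_epochs=1,
                              phase2_epochs=0)
            hist = train(net, train_set, val_set, cfg)
            losses.append(hist.train_loss[0])
        assert losses[0] == losses[1]

    def test_empty_training_split_rejected(self, smoke_data):
        _, val_set = smoke_data
        net = CardioVNet(SMOKE_CONFIG, seed=0)
        with pytest.raises(ValueError):
            train(net, (val_set[0][:0], val_set[1][:0]), val_set,
                  TrainConfig())


class TestAblationHeads:
    def test_classification_probs_sum_to_one(self, smoke_data):
        net = build_ablation_head(CardioVNet(SMOKE_CONFIG, seed=1),
                                  "classification", seed=1)
        x = smoke_data[0][0][:3]
        pred, probs = head_predictions(net, x)
        assert probs.shape == (3, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert ((pred >= 0) & (pred <= 3)).all()

    def test_regression_outputs_scalar_without_probs(self, smoke_data):
        net = build_ablation_head(CardioVNet(SMOKE_CONFIG, seed=1),
                                  "regression", seed=1)
        x = smoke_data[0][0][:3]
        pred, probs = head_predictions(net, x)
        assert probs is None
        assert pred.shape == (3,)
        assert pred.dtype.kind == "f"  # raw continuous output, no rounding

    def test_unknown_head_rejected(self):
        with pytest.raises(ValueError):
            build_ablation_head(CardioVNet(SMOKE_CONFIG, seed=0), "svm")
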
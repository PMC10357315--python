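import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpipe.features import extract_features
from gaitpipe.frame_classifiers import (
    BiLSTMHyperparams,
    BiLSTMNet,
    SVMHyperparams,
    WindowConfig,
    apply_standardization,
    fit_standardization,
    kfold_plan,
    make_windows,
    predict_labels,
    run_cv,
    train_bilstm,
    train_svm,
)
from gaitpipe.skeleton_io import FrameLabel
from gaitpipe.synthetic_gait import GaitSimConfig, simulate_cohort


def _frame_accuracy(pred, truth):
    return np.mean([p == t for p, t in zip(pred, truth)])


@pytest.fixture(scope="module")
def clean_pairs():
    """Feature/label pairs for 8 short noise-free walks."""
    cohort = simulate_cohort(GaitSimConfig(n_passes=4), 8, seed=11)
    return [(extract_features(seq).values, truth.labels) for seq, truth in cohort]


class TestMakeWindows:
    def test_partition_with_padded_tail(self):
        x = np.arange(12 * 3, dtype=float).reshape(12, 3)
        batch = make_windows(x, cfg=WindowConfig(seq_len=5))
        assert batch.n_windows == 3
        assert batch.mask[2].tolist() == [True, True, False, False, False]
        assert (batch.X[2, 2:] == 0).all()

    def test_exact_fit_no_padding(self):
        x = np.ones((5, 4))
        batch = make_windows(x, cfg=WindowConfig(seq_len=5))
        assert batch.n_windows == 1 and batch.mask.all()

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(1, 50), L=st.integers(1, 8))
    def test_round_trip_lossless(self, n, L):
        rng = np.random.default_rng(n * 100 + L)
        x = rng.normal(size=(n, 6))
        batch = make_windows(x, cfg=WindowConfig(seq_len=L))
        np.testing.assert_array_equal(batch.valid_rows(), x)

    def test_labels_padded_with_ignore_marker(self):
        labels = [FrameLabel.S] * 7
        batch = make_windows(np.zeros((7, 2)), labels, WindowConfig(seq_len=5))
        assert batch.y[1].tolist() == [0, 0, -1, -1, -1]


class TestStandardization:
    def test_train_columns_zero_mean_unit_variance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5.0, 3.0, size=(500, 8))
        std = fit_standardization(x)
        z = apply_standardization(std, x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_floored_to_zeros(self):
        x = np.column_stack([np.full(50, 3.0), np.random.default_rng(0).normal(size=50)])
        z = apply_standardization(fit_standardization(x), x)
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_test_data_uses_train_statistics(self):
        train = np.zeros((10, 1))
        train[:, 0] = np.arange(10)
        std = fit_standardization(train)
        shifted = apply_standardization(std, train + 100.0)
        assert shifted.mean() > 10  # not re-centered on its own mean


class TestSVM:
    def test_separable_clusters_high_accuracy(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 0.1, (100, 4)), rng.normal(3, 0.1, (100, 4))])
        y = [FrameLabel.L] * 100 + [FrameLabel.R] * 100
        model = train_svm(x, y)
        pred = predict_labels(model, x)
        assert _frame_accuracy(pred, y) >= 0.99

    def test_prediction_length_matches_input(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(60, 3))
        y = [FrameLabel.L if v > 0 else FrameLabel.R for v in x[:, 0]]
        model = train_svm(x, y)
        assert len(predict_labels(model, rng.normal(size=(17, 3)))) == 17

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_svm(np.zeros((10, 2)), [FrameLabel.S] * 10)

    def test_predict_before_fit_errors(self):
        from gaitpipe.frame_classifiers import SVMModel

        with pytest.raises(RuntimeError, match="unfitted"):
            SVMModel().predict_codes(np.zeros((3, 2)))


class TestBiLSTM:
    def test_gradients_match_numerical(self):
        net = BiLSTMNet(input_size=3, hidden=4, n_classes=3, seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 5, 3))
        y = rng.integers(0, 3, size=(2, 5))
        _, grads = net.loss_and_grads(x, y)
        eps = 1e-6
        for p, g in zip(net.params(), grads):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = net.loss_and_grads(x, y)
                flat[idx] = orig - eps
                lm, _ = net.loss_and_grads(x, y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_learns_simulated_gait(self, clean_pairs):
        train, test = clean_pairs[:6], clean_pairs[6:]
        model = train_bilstm(train, BiLSTMHyperparams(epochs=30, seed=0))
        for feats, labels in test:
            assert _frame_accuracy(predict_labels(model, feats), labels) >= 0.95

    def test_seeded_training_deterministic(self, clean_pairs):
        train = clean_pairs[:3]
        hp = BiLSTMHyperparams(epochs=3, seed=42)
        m1 = train_bilstm(train, hp)
        m2 = train_bilstm(train, hp)
        feats = clean_pairs[3][0]
        assert predict_labels(m1, feats) == predict_labels(m2, feats)

    def test_pad_value_never_reaches_network(self, clean_pairs):
        """Short tail windows are processed truncated, so the pad scalar
        cannot influence predictions on real frames."""
        train = clean_pairs[:3]
        hp = BiLSTMHyperparams(epochs=3, seed=0)
        m_a = train_bilstm(train, hp, WindowConfig(seq_len=5, pad_value=0.0))
        m_b = train_bilstm(train, hp, WindowConfig(seq_len=5, pad_value=1e6))
        feats = clean_pairs[3][0][:23]  # force a short tail window
        m_b.window_config = WindowConfig(seq_len=5, pad_value=1e6)
        assert predict_labels(m_a, feats) == predict_labels(m_b, feats)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_bilstm([(np.zeros((10, 3)), [FrameLabel.D] * 10)])


class TestCrossValidation:
    def test_fold_sizes_and_partition(self):
        plan = kfold_plan(list(range(40)), k=10, seed=0)
        folds = [plan.fold_ids(f) for f in range(10)]
        assert all(len(f) == 4 for f in folds)
        ids = sorted(i for f in folds for i in f)
        assert ids == list(range(40))

    def test_same_seed_same_assignment(self):
        a = kfold_plan(list(range(25)), k=5, seed=3).assignment
        b = kfold_plan(list(range(25)), k=5, seed=3).assignment
        assert a == b

    def test_k_larger_than_sequences_rejected(self):
        with pytest.raises(ValueError):
            kfold_plan([1, 2, 3], k=10)

    def test_run_cv_predicts_each_walk_once(self, clean_pairs):
        dataset = {i: p for i, p in enumerate(clean_pairs)}
        plan = kfold_plan(list(dataset), k=4, seed=0)
        reports, predictions = run_cv(dataset, "svm_rbf", plan)
        assert len(reports) == 4
        assert sorted(predictions) == sorted(dataset)
        for i, (feats, labels) in dataset.items():
            assert len(predictions[i]) == len(labels)

    def test_classifier_ordering_on_shared_folds(self, clean_pairs):
        """On clean data both classifiers are accurate and the sequence
        model's event localization is at least as good as the SVM's."""
        from gaitpipe.evaluation import segmentation_accuracy
        from gaitpipe.semantics_gpm import FOOT_EVENTS, extract_semantics

        dataset = {i: p for i, p in enumerate(clean_pairs)}
        plan = kfold_plan(list(dataset), k=4, seed=1)
        seg_acc = {}
        for kind in ("svm_rbf", "bilstm"):
            reports, predictions = run_cv(
                dataset, kind, plan, bilstm_hp=BiLSTMHyperparams(epochs=20, seed=0)
            )
            accs = [
                _frame_accuracy(predictions[i], dataset[i][1]) for i in dataset
            ]
            assert np.mean(accs) > 0.90, kind
            matched = total = 0
            for i in dataset:
                true_ev = [e for e in extract_semantics(dataset[i][1]) if e.type in FOOT_EVENTS]
                pred_ev = [e for e in extract_semantics(predictions[i]) if e.type in FOOT_EVENTS]
                s = segmentation_accuracy(true_ev, pred_ev, t=2)
                matched += s.matched
                total += s.K
            seg_acc[kind] = matched / total
        assert seg_acc["bilstm"] >= seg_acc["svm_rbf"]
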
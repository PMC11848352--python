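"""Atlas-feature extraction and the MLP ensemble / CV harness."""

import numpy as np
import pytest

from pseudopet.classifier import (
    BranchConfig,
    cross_validate,
    predict_ensemble,
    train_branch,
)
from pseudopet.features import extract_features, pair_feature_table
from pseudopet.phantoms import CLASSES, PhantomConfig, generate_dataset


class TestExtractFeatures:
    def _toy(self):
        atlas = np.array([[1, 1, 1, 2, 2]])
        volume = np.array([[0.0, 3.0, 5.0, 2.0, 0.0]])
        seg = np.ones_like(atlas)
        return volume, atlas, seg

    def test_hand_enumeration_counts_and_sums(self):
        volume, atlas, seg = self._toy()
        counts = extract_features(volume, atlas, seg, "count_nonzero")
        sums = extract_features(volume, atlas, seg, "sum")
        np.testing.assert_array_equal(counts.values, [2, 1])
        np.testing.assert_array_equal(sums.values, [8.0, 2.0])
        assert counts.regions == (1, 2)

    def test_all_zero_volume_count_is_zero_vector(self):
        _, atlas, seg = self._toy()
        fv = extract_features(np.zeros_like(atlas, float), atlas, seg,
                              "count_nonzero")
        np.testing.assert_array_equal(fv.values, [0, 0])

    def test_segment_mask_restricts(self):
        volume, atlas, seg = self._toy()
        seg = np.array([[1, 1, 0, 0, 1]])
        fv = extract_features(volume, atlas, seg, "sum")
        np.testing.assert_array_equal(fv.values, [3.0, 0.0])

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        atlas = rng.integers(0, 4, (6, 6))
        volume = rng.uniform(0, 2, (6, 6))
        seg = np.ones_like(atlas)
        base = extract_features(volume, atlas, seg, "sum")
        # swap labels 1 <-> 3
        swapped = atlas.copy()
        swapped[atlas == 1] = 3
        swapped[atlas == 3] = 1
        perm = extract_features(volume, swapped, seg, "sum")
        assert base.values[base.regions.index(1)] == pytest.approx(
            perm.values[perm.regions.index(3)]
        )

    def test_absent_region_warns_and_zeroes(self):
        volume, atlas, seg = self._toy()
        with pytest.warns(UserWarning, match="absent"):
            fv = extract_features(volume, atlas, seg, "sum", regions=(1, 2, 9))
        assert fv.values[-1] == 0.0

    def test_bad_mode_rejected(self):
        volume, atlas, seg = self._toy()
        with pytest.raises(ValueError, match="mode"):
            extract_features(volume, atlas, seg, "median")

    def test_pure_function(self):
        volume, atlas, seg = self._toy()
        a = extract_features(volume, atlas, seg, "sum")
        b = extract_features(volume, atlas, seg, "sum")
        np.testing.assert_array_equal(a.values, b.values)


class TestBranches:
    def _separable(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(0, 0.3, (n // 2, 4))
        X1 = rng.normal(4, 0.3, (n // 2, 4))
        X = np.vstack([X0, X1])
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        return X, y

    def test_separable_toy_reaches_full_training_accuracy(self):
        X, y = self._separable()
        clf = train_branch(X, y, BranchConfig(seed=0, max_iter=600))
        assert (clf.predict(X) == y).mean() == 1.0

    def test_probabilities_sum_to_one(self):
        X, y = self._separable()
        clf = train_branch(X, y, BranchConfig(seed=0))
        p = clf.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_same_seed_identical_parameters(self):
        X, y = self._separable()
        a = train_branch(X, y, BranchConfig(seed=5))
        b = train_branch(X, y, BranchConfig(seed=5))
        for wa, wb in zip(a["mlp"].coefs_, b["mlp"].coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_single_class_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="2 classes"):
            train_branch(X, ["A"] * 5, BranchConfig())


class _StubBranch:
    def __init__(self, probs, classes=("A", "B", "C")):
        self._p = np.asarray(probs, float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._p[None, :]


class _StubFeature:
    values = np.zeros(3)


class TestPredictEnsemble:
    def test_single_branch_passthrough(self):
        pred = predict_ensemble(
            {("m", "GM"): _StubBranch([0.7, 0.2, 0.1])},
            {("m", "GM"): _StubFeature()},
        )
        np.testing.assert_allclose(pred.probs, [0.7, 0.2, 0.1])
        assert pred.predicted_class == "A"

    def test_two_branch_arithmetic_mean(self):
        pred = predict_ensemble(
            {
                ("m", "GM"): _StubBranch([0.8, 0.1, 0.1]),
                ("m", "WM"): _StubBranch([0.2, 0.5, 0.3]),
            },
            {("m", "GM"): _StubFeature(), ("m", "WM"): _StubFeature()},
        )
        np.testing.assert_allclose(pred.probs, [0.5, 0.3, 0.2])

    def test_six_branches_equal_mean_of_modality_means(self):
        rng = np.random.default_rng(0)
        branches, feats = {}, {}
        per_mod = {}
        for mod in ("structural", "functional"):
            ps = []
            for seg in ("GM", "WM", "CSF"):
                p = rng.dirichlet(np.ones(3))
                branches[(mod, seg)] = _StubBranch(p)
                feats[(mod, seg)] = _StubFeature()
                ps.append(p)
            per_mod[mod] = np.mean(ps, axis=0)
        pred = predict_ensemble(branches, feats)
        expected = np.mean(list(per_mod.values()), axis=0)
        np.testing.assert_allclose(pred.probs, expected, atol=1e-12)

    def test_missing_branch_features_listed(self):
        branches = {("m", "GM"): _StubBranch([1, 0, 0]), ("m", "WM"): _StubBranch([1, 0, 0])}
        with pytest.raises(ValueError, match="WM"):
            predict_ensemble(branches, {("m", "GM"): _StubFeature()})

    def test_empty_branches_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict_ensemble({}, {})


class TestPrecisionRecallClosedForm:
    def test_printed_confusion_matrix(self):
        from sklearn.metrics import precision_recall_fscore_support

        # TP=8, FP=2, FN=2, TN=8
        truth = ["P"] * 10 + ["N"] * 10
        pred = ["P"] * 8 + ["N"] * 2 + ["P"] * 2 + ["N"] * 8
        p, r, f, _ = precision_recall_fscore_support(
            truth, pred, labels=["P"], zero_division=0
        )
        assert p[0] == pytest.approx(0.8)
        assert r[0] == pytest.approx(0.8)
        assert f[0] == pytest.approx(0.8)


@pytest.fixture(scope="module")
def phantom_cohort():
    cfg = PhantomConfig(image_shape=(24, 24), n_subjects=24, seed=3)
    return generate_dataset(cfg)


class TestCrossValidate:
    def test_every_subject_tested_exactly_once(self, phantom_cohort):
        result = cross_validate(
            phantom_cohort, k=3, tasks={"NC/MCI/AD": CLASSES},
            views=[("functional",)], seed=0,
            branch_config=BranchConfig(max_iter=100),
        )
        row = result.table.iloc[0]
        assert row["accuracy"] >= 0.0
        # 24 subjects, 3 folds of 8: accuracy over exactly 24 predictions
        assert ("NC/MCI/AD", ("functional",)) in result.accuracies

    def test_fold_sizes_partition_subjects(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.array([CLASSES[i % 3] for i in range(30)])
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, test_idx in skf.split(np.zeros(30), labels):
            assert len(test_idx) == 6
            seen.extend(test_idx)
        assert sorted(seen) == list(range(30))

    def test_class_smaller_than_k_rejected(self, phantom_cohort):
        with pytest.raises(ValueError, match="fewer than k"):
            cross_validate(
                phantom_cohort, k=10, tasks={"NC/MCI/AD": CLASSES},
                views=[("structural",)], seed=0,
            )

    def test_synth_view_without_synthesizer_rejected(self, phantom_cohort):
        with pytest.raises(ValueError, match="fold_synthesizer"):
            cross_validate(
                phantom_cohort, k=3,
                views=[("structural", "functional_synth_two_way")], seed=0,
            )

    def test_k_below_two_rejected(self, phantom_cohort):
        with pytest.raises(ValueError, match="k"):
            cross_validate(phantom_cohort, k=1)
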
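"""Evaluation metrics against brute-force confusion-count oracles."""

import numpy as np
import pytest

from retseg.metrics import auc_pr, auc_roc, dice_score, evaluate, mae, sensitivity


def oracle_dice(pred, gt):
    tp = int(np.sum((pred == 1) & (gt == 1)))
    denom = int(pred.sum() + gt.sum())
    return 1.0 if denom == 0 else 2.0 * tp / denom


def oracle_sensitivity(pred, gt):
    tp = int(np.sum((pred == 1) & (gt == 1)))
    return tp / int(gt.sum())


def oracle_auc_roc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestDiceScore:
    def test_identical_nonempty_masks(self, rng):
        m = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.eye(3, dtype=np.uint8)
        assert dice_score(a, 1 - a) == 0.0

    def test_counted_example(self):
        pred = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        gt = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        assert dice_score(pred, gt) == pytest.approx(2.0 / 3.0)

    def test_symmetry(self, rng):
        a = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        b = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        assert dice_score(a, b) == dice_score(b, a)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            dice_score(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestMae:
    def test_identity(self):
        g = np.array([[0, 1], [1, 0]], dtype=float)
        assert mae(g, g) == 0.0

    def test_constant_half(self):
        g = np.array([[0, 1], [1, 1]], dtype=float)
        assert mae(np.full((2, 2), 0.5), g) == 0.5

    def test_hand_computed(self):
        s = np.array([[0.1, 0.9], [0.0, 1.0]])
        g = np.array([[0, 1], [1, 1]], dtype=float)
        assert mae(s, g) == pytest.approx(0.3)

    def test_permutation_invariance(self, rng):
        s = rng.random(16)
        g = (rng.random(16) > 0.5).astype(float)
        perm = rng.permutation(16)
        assert mae(s, g) == pytest.approx(mae(s[perm], g[perm]))


class TestSensitivity:
    def test_superset_prediction(self):
        gt = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        assert sensitivity(np.ones((2, 2), dtype=np.uint8), gt) == 1.0

    def test_disjoint_prediction(self):
        gt = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        pred = np.array([[0, 1], [0, 0]], dtype=np.uint8)
        assert sensitivity(pred, gt) == 0.0

    def test_counted_example(self):
        gt = np.array([1, 1, 1, 1, 0, 0], dtype=np.uint8)
        pred = np.array([1, 1, 1, 0, 1, 0], dtype=np.uint8)
        assert sensitivity(pred, gt) == 0.75

    def test_asymmetry_witness(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([1, 0, 0, 0], dtype=np.uint8)
        assert sensitivity(a, b) != sensitivity(b, a)

    def test_empty_ground_truth_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sensitivity(np.ones((2, 2), dtype=np.uint8), np.zeros((2, 2), dtype=np.uint8))


class TestAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc_roc(scores, labels) == 1.0
        assert auc_pr(scores, labels) == 1.0

    def test_uninformative_scores(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        assert auc_roc(scores, labels) == 0.5

    def test_six_pixel_worked_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        labels = np.array([1, 1, 0, 1, 0, 0])
        assert auc_roc(scores, labels) == pytest.approx(8.0 / 9.0)

    def test_matches_pairwise_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            scores = rng.random(50)
            labels = (rng.random(50) > 0.6).astype(int)
            if labels.min() == labels.max():
                continue
            assert auc_roc(scores, labels) == pytest.approx(
                oracle_auc_roc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auc_roc(np.array([0.1, 0.9]), np.array([1, 1]))


class _OracleModel:
    """Predicts the ground truth of one lesion exactly; flat noise elsewhere."""

    def __init__(self, masks):
        self.masks = masks

    def predict_proba(self, images):
        n, _, h, w = images.shape
        return {
            name: m.reshape(n, 1, h, w).astype(float) for name, m in self.masks.items()
        }


class TestEvaluate:
    def test_oracle_model_scores_perfectly(self, rng):
        masks = {"EX": (rng.random((3, 8, 8)) > 0.7).astype(np.uint8)}
        masks["EX"][:, 4, 4] = 1  # ensure every image has foreground
        images = rng.random((3, 3, 8, 8))
        report = evaluate(_OracleModel(masks), images, masks)
        m = report.per_lesion["EX"]
        assert m["dsc"] == 1.0 and m["sensitivity"] == 1.0 and m["mae"] == 0.0
        assert m["auc_roc"] == 1.0

    def test_threshold_zero_gives_full_sensitivity(self, rng):
        gt = {"MA": (rng.random((2, 8, 8)) > 0.8).astype(np.uint8)}
        gt["MA"][:, 0, 0] = 1
        probs = {"MA": np.clip(rng.random((2, 8, 8)), 0.01, 1.0)}

        class Noisy:
            def predict_proba(self, images):
                return {"MA": probs["MA"].reshape(2, 1, 8, 8)}

        report = evaluate(Noisy(), rng.random((2, 3, 8, 8)), gt, threshold=0.0)
        assert report.per_lesion["MA"]["sensitivity"] == 1.0

    def test_matches_independent_confusion_recount(self, rng):
        gt = {"HE": (rng.random((3, 6, 6)) > 0.6).astype(np.uint8)}
        gt["HE"][:, 2, 2] = 1
        probs = rng.random((3, 6, 6))

        class P:
            def predict_proba(self, images):
                return {"HE": probs.reshape(3, 1, 6, 6)}

        report = evaluate(P(), rng.random((3, 3, 6, 6)), gt)
        pred = (probs >= 0.5).astype(np.uint8)
        assert report.per_lesion["HE"]["dsc"] == pytest.approx(
            np.mean([oracle_dice(p, g) for p, g in zip(pred, gt["HE"])])
        )
        assert report.per_lesion["HE"]["sensitivity"] == pytest.approx(
            np.mean([oracle_sensitivity(p, g) for p, g in zip(pred, gt["HE"])])
        )
        assert report.per_lesion["HE"]["auc_roc"] == pytest.approx(
            oracle_auc_roc(probs.ravel(), gt["HE"].ravel()), abs=1e-12
        )

    def test_report_serialises_and_summarises(self, tmp_path, rng):
        masks = {"SE": (rng.random((2, 8, 8)) > 0.7).astype(np.uint8)}
        masks["SE"][:, 1, 1] = 1
        report = evaluate(_OracleModel(masks), rng.random((2, 3, 8, 8)), masks)
        out = tmp_path / "report.json"
        report.to_json(out)
        assert out.exists() and "SE" in report.summary()
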
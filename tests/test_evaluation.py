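"""Metrics vs. brute-force formulas, exact Wilcoxon, heatmaps, localization."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr
from skimage.transform import resize

from stainadapt import nn
from stainadapt.evaluation import (
    compare_arms,
    compute_metrics,
    localize,
    rank_patches,
    render_heatmap,
)
from stainadapt.fourier import Patch


# ---------------------------------------------------------------------------
# brute-force confusion-matrix oracles (independent of sklearn)
# ---------------------------------------------------------------------------

def brute_force_metrics(y_true, y_pred):
    classes = sorted(set(y_true))
    recalls, f1s = [], []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        recalls.append(recall)
        f1s.append(f1)
    n = len(y_true)
    po = sum(1 for t, p in zip(y_true, y_pred) if t == p) / n
    all_classes = sorted(set(y_true) | set(y_pred))
    pe = sum(
        (sum(1 for t in y_true if t == c) / n) * (sum(1 for p in y_pred if p == c) / n)
        for c in all_classes
    )
    kappa = (po - pe) / (1 - pe) if pe != 1 else 0.0
    return 100 * np.mean(recalls), kappa, float(np.mean(f1s))


def enumerate_signed_rank_p(d):
    """Exact two-sided p over all 2^n sign assignments (n <= 12)."""
    d = np.asarray(d, float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestComputeMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 2], [0, 1, 2], np.eye(3))
        assert m["balanced_accuracy"] == 100.0
        assert m["cohens_kappa"] == 1.0
        assert m["auc"] == 1.0

    def test_printed_confusion_matrix(self):
        # confusion matrix [[8,2],[4,6]]: po=0.7, pe=0.5 -> kappa 0.4
        y_true = [0] * 10 + [1] * 10
        y_pred = [0] * 8 + [1] * 2 + [0] * 4 + [1] * 6
        m = compute_metrics(y_true, y_pred)
        assert m["balanced_accuracy"] == pytest.approx(70.0)
        assert m["cohens_kappa"] == pytest.approx(0.4, abs=1e-12)

    def test_constant_predictor_on_balanced_labels(self):
        m = compute_metrics([0, 1] * 10, [0] * 20)
        assert m["balanced_accuracy"] == pytest.approx(50.0)
        assert m["cohens_kappa"] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            y_true = rng.integers(0, k, 50)
            y_pred = rng.integers(0, k, 50)
            if len(set(y_true)) < 2:
                continue
            m = compute_metrics(y_true, y_pred)
            ba, kappa, f1 = brute_force_metrics(list(y_true), list(y_pred))
            assert m["balanced_accuracy"] == pytest.approx(ba, abs=1e-10)
            assert m["cohens_kappa"] == pytest.approx(kappa, abs=1e-10)
            assert m["macro_f1"] == pytest.approx(f1, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestCompareArms:
    def test_all_zero_differences_flagged(self):
        r = compare_arms([1.0] * 6, [1.0] * 6)
        assert r.p_value == 1.0 and r.zero_variance and not r.significant

    def test_five_one_signed_pairs(self):
        r = compare_arms([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert r.p_value == pytest.approx(0.0625, abs=1e-12)

    def test_symmetry_under_arm_swap(self):
        a = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        b = [2.0, 1.1, 4.4, 1.0, 8.0, 3.0]
        assert compare_arms(a, b).p_value == pytest.approx(compare_arms(b, a).p_value)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = np.round(rng.normal(0, 1, n), 2)
        d[d == 0] = 0.5
        a = d
        b = np.zeros(n)
        r = compare_arms(a, b)
        assert r.p_value == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)

    def test_ties_handled_exactly(self):
        d = [1.0, 1.0, -1.0, 2.0, 2.0, 3.0]
        r = compare_arms(d, [0.0] * 6)
        assert r.p_value == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)

    def test_unpaired_or_short_rejected(self):
        with pytest.raises(ValueError):
            compare_arms([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            compare_arms([1, 2, 3, 4], [0, 0, 0, 0])


class TestHeatmap:
    def test_probability_one_tiles_are_red(self):
        slide = np.zeros((8, 8, 3))
        out = render_heatmap(slide, [(0, 0, 8, 8)], [1.0], alpha=1.0)
        np.testing.assert_array_equal(out[0, 0], [255, 0, 0])

    def test_colormap_endpoints(self):
        slide = np.full((4, 8, 3), 0.5)
        out = render_heatmap(slide, [(0, 0, 4, 4), (4, 0, 4, 4)], [0.0, 1.0], alpha=1.0)
        np.testing.assert_array_equal(out[0, 0], [0, 0, 255])   # blue = low
        np.testing.assert_array_equal(out[0, 7], [255, 0, 0])   # red = high

    def test_overlap_averaged(self):
        slide = np.zeros((4, 4, 3))
        out = render_heatmap(slide, [(0, 0, 4, 4), (0, 0, 4, 4)], [0.0, 1.0], alpha=1.0)
        mid = np.array(render_heatmap(slide, [(0, 0, 4, 4)], [0.5], alpha=1.0)[0, 0])
        np.testing.assert_array_equal(out[0, 0], mid)

    def test_pure_function_identical_png_bytes(self, tmp_path):
        rng = np.random.default_rng(0)
        slide = rng.random((16, 16, 3))
        coords = [(0, 0, 8, 8), (8, 8, 8, 8)]
        probs = [0.2, 0.9]
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_heatmap(slide, coords, probs, out_path=p1)
        render_heatmap(slide, coords, probs, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            render_heatmap(np.zeros((8, 8, 3)), [(4, 4, 8, 8)], [0.5])
        with pytest.raises(ValueError):
            render_heatmap(np.zeros((8, 8, 3)), [(0, 0, 4, 4)], [1.5])


class TestLocalization:
    def test_constructed_model_highlights_designated_channel(self, tiny_model):
        """A label head reading only channel 2's spatial mean must yield an
        importance map that rank-correlates with channel 2's activation."""
        tiny_model.classifier.weight.data[:] = 0.0
        tiny_model.classifier.bias.data[:] = 0.0
        tiny_model.classifier.weight.data[2, 0] = 1.0  # class 0 <- channel 2
        rng = np.random.default_rng(0)
        patch = Patch(rng.random((32, 32, 3)))
        cam = localize(tiny_model, patch, target_class=0)
        assert cam.shape == (32, 32)
        assert cam.min() >= 0.0 and cam.max() <= 1.0
        from stainadapt.adversarial import _stack

        acts = tiny_model.forward_blocks(nn.Tensor(_stack([patch])))[-1].data[0, 2]
        acts_up = resize(acts, (32, 32), order=1, preserve_range=True)
        rho = spearmanr(cam.ravel(), acts_up.ravel()).statistic
        assert rho >= 0.99

    def test_map_contract_for_plain_model(self, tiny_model):
        rng = np.random.default_rng(1)
        patch = Patch(rng.random((32, 32, 3)))
        cam = localize(tiny_model, patch, target_class=1)
        assert cam.shape == patch.pixels.shape[:2]
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_class_out_of_range(self, tiny_model):
        patch = Patch(np.zeros((32, 32, 3)))
        with pytest.raises(ValueError):
            localize(tiny_model, patch, target_class=5)


class TestRankPatches:
    def test_top_bottom_union_covers_all(self):
        probs = [0.2, 0.9, 0.5, 0.7]
        top, bottom = rank_patches(probs, j=4)
        assert sorted(top) == sorted(bottom) == [0, 1, 2, 3]
        assert top == [1, 3, 2, 0]
        assert bottom == [0, 2, 3, 1]

    def test_ties_broken_by_index(self):
        top, bottom = rank_patches([0.5, 0.5, 0.1], j=2)
        assert top == [0, 1]
        assert bottom == [2, 0]

    def test_j_too_large(self):
        with pytest.raises(ValueError):
            rank_patches([0.1], j=2)
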
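"""Metrics, paired-rank comparison of methods, heatmaps and localization.

Metric conventions: balanced accuracy is the unweighted mean of per-class
recalls reported on a 0-100 scale; Cohen's kappa comes from the confusion
matrix; F1 is macro-averaged; AUC is one-vs-rest macro-averaged over
calibrated class scores.  Method arms are compared with the two-sided
Wilcoxon signed-rank test over paired (fold, seed) scores, exact for
n <= 25 pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.stats import rankdata, wilcoxon
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from . import nn
from .adversarial import DomainAdversarialModel, _stack
from .fourier import Patch

logger = logging.getLogger("stainadapt")

__all__ = [
    "compute_metrics",
    "ArmComparison",
    "compare_arms",
    "render_heatmap",
    "localize",
    "rank_patches",
    "domain_probe_accuracy",
]

ALPHA = 0.05


def compute_metrics(y_true, y_pred, scores: np.ndarray | None = None) -> dict:
    """Balanced accuracy (percent), Cohen's kappa, macro-F1 and OvR AUC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    extra = set(np.unique(y_pred)) - set(np.unique(y_true))
    if extra:
        logger.warning("classes %s absent from y_true are excluded from the recall mean", extra)
    metrics = {
        "balanced_accuracy": 100.0 * balanced_accuracy_score(y_true, y_pred),
        "cohens_kappa": float(cohen_kappa_score(y_true, y_pred)),
        "macro_f1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
    }
    if scores is not None and len(np.unique(y_true)) > 1:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.ndim == 2 and scores.shape[1] == 2:
            auc = roc_auc_score(y_true, scores[:, 1])
        else:
            auc = roc_auc_score(y_true, scores, multi_class="ovr", average="macro")
        metrics["auc"] = float(auc)
    else:
        metrics["auc"] = float("nan")
    return metrics


@dataclass
class ArmComparison:
    p_value: float
    statistic: float
    n: int
    zero_variance: bool
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by dynamic programming over all sign assignments.

    Tied absolute differences get midranks; doubling makes them integral so
    the distribution of W+ is a polynomial product over the ranks.
    """
    ranks = rankdata(np.abs(d))
    r2 = np.round(ranks * 2).astype(int)
    w2 = int(np.round(2 * ranks[d > 0].sum()))
    total = r2.sum()
    dp = np.zeros(total + 1, dtype=np.float64)
    dp[0] = 1.0
    for r in r2:
        new = dp.copy()
        new[r:] += dp[: total + 1 - r]
        dp = new
    denom = dp.sum()  # 2^n
    p_le = dp[: w2 + 1].sum() / denom
    p_ge = dp[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge)), ranks[d > 0].sum()


def compare_arms(scores_a: Sequence[float], scores_b: Sequence[float]) -> ArmComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-(fold, seed) scores.

    Zero differences are dropped; an all-zero difference vector is reported
    as p = 1 with a zero-variance flag rather than an error, so degenerate
    but legitimate comparisons (identical arms) stay well-defined.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired scores")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return ArmComparison(p_value=1.0, statistic=0.0, n=0, zero_variance=True)
    if d.size <= 25:
        p, w = _exact_signed_rank_p(d)
    else:
        res = wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
        p, w = float(res.pvalue), float(res.statistic)
    return ArmComparison(p_value=float(p), statistic=float(w), n=int(d.size),
                         zero_variance=False)


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def render_heatmap(slide_image: np.ndarray, patch_coords: Sequence[tuple],
                   class_probs: Sequence[float], out_path=None,
                   alpha: float = 0.5) -> np.ndarray:
    """Blue-to-red probability overlay on a slide (red = high probability).

    ``patch_coords`` are (x, y, w, h) half-open boxes; overlapping patches
    are averaged before colorizing.  Pure function of its inputs; returns an
    RGB uint8 array and optionally writes it as PNG.
    """
    img = np.asarray(slide_image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    H, W = img.shape[:2]
    probs = np.asarray(class_probs, dtype=np.float64)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must be in [0, 1]")
    if len(patch_coords) != probs.size:
        raise ValueError("one probability per patch required")
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for (x, y, w, h), p in zip(patch_coords, probs):
        if x < 0 or y < 0 or x + w > W or y + h > H:
            raise ValueError(f"patch box ({x},{y},{w},{h}) outside slide {W}x{H}")
        acc[y : y + h, x : x + w] += p
        cnt[y : y + h, x : x + w] += 1
    covered = cnt > 0
    mean_p = np.zeros((H, W))
    mean_p[covered] = acc[covered] / cnt[covered]
    cmap = colormaps["bwr"]
    colors = cmap(mean_p)[:, :, :3]
    out = img.copy()
    out[covered] = (1 - alpha) * img[covered] + alpha * colors[covered]
    out8 = np.round(np.clip(out, 0, 1) * 255).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(out8).save(out_path)
    return out8


# ---------------------------------------------------------------------------
# Gradient-based class-discriminative localization
# ---------------------------------------------------------------------------

def localize(model: DomainAdversarialModel, patch: Patch, target_class: int) -> np.ndarray:
    """Importance map in [0, 1] for ``target_class`` over the patch.

    Gradient-weighted combination of the final conv block's activations
    (channel weights = spatially averaged gradients of the class logit),
    rectified, min-max scaled, and upsampled to the patch size.
    """
    if not 0 <= target_class < model.n_classes:
        raise ValueError(f"class index {target_class} out of range")
    model.eval()
    x = nn.Tensor(_stack([patch]))
    blocks = model.forward_blocks(x)
    final = blocks[-1]
    logits = model.label_logits(final)
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    scalar = nn.mean(nn.mul(logits, nn.Tensor(onehot)))
    model.zero_grad()
    scalar.backward()
    grads = final.grad[0]          # c x h x w
    acts = final.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    if cam.max() > cam.min():
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    else:
        cam = np.zeros_like(cam)
    h, w = patch.pixels.shape[:2]
    return np.clip(resize(cam, (h, w), order=1, preserve_range=True), 0.0, 1.0)


def rank_patches(patch_probs: Sequence[float], j: int = 5):
    """Top-j and bottom-j patch indices by ground-truth class probability.

    Ties are broken by slide-order index.  Returns (top, bottom), each a
    list of indices; top is descending in probability, bottom ascending.
    """
    probs = np.asarray(patch_probs, dtype=np.float64)
    if j > probs.size:
        raise ValueError(f"j={j} exceeds patch count {probs.size}")
    order_desc = np.lexsort((np.arange(probs.size), -probs))
    order_asc = np.lexsort((np.arange(probs.size), probs))
    return order_desc[:j].tolist(), order_asc[:j].tolist()


# ---------------------------------------------------------------------------
# Domain probe (measures how separable the two domains are in a feature space)
# ---------------------------------------------------------------------------

def domain_probe_accuracy(features_source: np.ndarray, features_target: np.ndarray,
                          seed: int = 0, test_fraction: float = 0.5) -> float:
    """Held-out accuracy of a logistic probe separating source from target.

    Near 0.5 means the feature space carries no domain information; used
    both to sanity-check the generator (identity transforms) and to verify
    that adversarial training suppresses domain information at the tap.
    """
    xs = np.asarray(features_source, dtype=np.float64).reshape(len(features_source), -1)
    xt = np.asarray(features_target, dtype=np.float64).reshape(len(features_target), -1)
    X = np.concatenate([xs, xt])
    y = np.concatenate([np.zeros(len(xs)), np.ones(len(xt))])
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_fraction, random_state=seed % (2**31), stratify=y)
    scaler = StandardScaler().fit(Xtr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(max_iter=1000, random_state=seed % (2**31))
        clf.fit(scaler.transform(Xtr), ytr)
    return float(clf.score(scaler.transform(Xte), yte))
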
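"""Slide-level pipeline: patch extraction, VLAD aggregation, classification.

A whole-slide image is represented here as one flat RGB array.  Patches are
sampled from it (inside an annotation mask when one is supplied), embedded
by the trained network, aggregated into a single fixed-length slide vector
with VLAD (vector of locally aggregated descriptors: per-patch residuals to
a k-means codebook, accumulated per centroid, intra- and globally
l2-normalized), and classified with a linear SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.svm import LinearSVC

from .fourier import Patch

__all__ = [
    "SlideRecord",
    "VladCodebook",
    "NoTissueError",
    "extract_patches",
    "fit_codebook",
    "vlad_encode",
    "fit_slide_classifier",
    "predict_slide",
]


class NoTissueError(ValueError):
    """Raised when an annotation mask contains no usable tissue area."""


@dataclass
class SlideRecord:
    """One slide with provenance, its image, and its extracted patches.

    ``label`` is the slide-level class for source slides and ``None`` for
    target slides during training; a generator-known target label may be
    stashed in the private ``_eval_label`` and read through an evaluation
    accessor only.
    """

    slide_id: str
    patient_id: str
    domain: str
    label: int | None = None
    image: np.ndarray | None = None
    patches: list[Patch] = field(default_factory=list)
    _eval_label: int | None = None


@dataclass
class VladCodebook:
    """k centroids in embedding space; slide vectors have length k*m."""

    centroids: np.ndarray  # k x m
    k: int
    fit_seed: int

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.k < 1 or self.centroids.shape[0] != self.k:
            raise ValueError("codebook must have k >= 1 centroid rows")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("codebook centroids must be finite")


def extract_patches(
    slide_image: np.ndarray,
    n: int = 150,
    patch_px: int = 1024,
    out_px: int = 512,
    mode: str = "random",
    mask: np.ndarray | None = None,
    seed: int = 0,
    slide_id: str = "",
    domain: str = "source",
    label: int | None = None,
) -> list[Patch]:
    """Sample ``n`` patches of ``patch_px`` pixels, resized to ``out_px``.

    Sampling first walks the non-overlapping ``patch_px`` grid in a
    seed-shuffled order (so small requests tile the slide without overlap)
    and falls back to uniform random offsets once the grid is exhausted.
    With ``mode="annotated_mask"`` only positions whose center lies in the
    binary mask are eligible.  Coordinates are 0-based, half-open boxes,
    recorded on each patch for later heatmap rendering.
    """
    img = np.asarray(slide_image, dtype=np.float64)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    H, W = img.shape[:2]
    if H < patch_px or W < patch_px:
        raise ValueError(f"slide {H}x{W} smaller than patch size {patch_px}")
    if mode not in ("random", "annotated_mask"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    if mode == "annotated_mask":
        if mask is None:
            raise ValueError("annotated_mask mode requires a mask")
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (H, W):
            raise ValueError("mask shape must match slide shape")
        if not mask.any():
            raise NoTissueError("annotation mask contains no tissue")

    def admissible(yy: int, xx: int) -> bool:
        if mask is None:
            return True
        return bool(mask[yy + patch_px // 2, xx + patch_px // 2])

    rng = np.random.default_rng(seed)
    grid = [
        (y, x)
        for y in range(0, H - patch_px + 1, patch_px)
        for x in range(0, W - patch_px + 1, patch_px)
        if admissible(y, x)
    ]
    rng.shuffle(grid)
    coords = grid[:n]
    attempts = 0
    while len(coords) < n:
        y = int(rng.integers(0, H - patch_px + 1))
        x = int(rng.integers(0, W - patch_px + 1))
        if admissible(y, x):
            coords.append((y, x))
        attempts += 1
        if attempts > 1000 * n:
            raise NoTissueError("could not place patches inside the mask")

    patches = []
    for y, x in coords:
        tile = img[y : y + patch_px, x : x + patch_px]
        if out_px != patch_px:
            tile = resize(tile, (out_px, out_px, 3), order=1,
                          anti_aliasing=out_px < patch_px, preserve_range=True)
        patches.append(
            Patch(np.clip(tile, 0.0, 1.0), slide_id=slide_id, domain=domain,
                  label=label, x=x, y=y, w=patch_px, h=patch_px)
        )
    return patches


def fit_codebook(embeddings: np.ndarray, k: int, seed: int = 0) -> VladCodebook:
    """k-means codebook over patch embeddings; k=1 is the exact mean."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    n = embeddings.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of embeddings n={n}")
    if k == 1:
        centroids = embeddings.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
        km.fit(embeddings)
        centroids = km.cluster_centers_
    return VladCodebook(centroids=centroids, k=k, fit_seed=seed)


def vlad_encode(slide_embeddings: np.ndarray, codebook: VladCodebook,
                normalize: bool = True) -> np.ndarray:
    """Slide vector of length k*m: accumulated residuals to nearest centroid,
    per-block l2 intra-normalized then globally l2 normalized.

    An all-zero accumulation (degenerate but possible, e.g. symmetric
    residual cancellation) returns the zero vector.
    """
    emb = np.asarray(slide_embeddings, dtype=np.float64)
    k, m = codebook.centroids.shape
    if emb.ndim != 2 or emb.shape[1] != m:
        raise ValueError(f"embedding dim {emb.shape} does not match codebook m={m}")
    assign = cdist(emb, codebook.centroids).argmin(axis=1)
    blocks = np.zeros((k, m))
    for j in range(k):
        sel = assign == j
        if sel.any():
            blocks[j] = (emb[sel] - codebook.centroids[j]).sum(axis=0)
    if not normalize:  # raw residual accumulations (used for conservation checks)
        return blocks.ravel()
    # norms below 1e-12 are rounding residue of cancelled accumulations and
    # are treated as the documented all-zero degenerate case
    for j in range(k):
        norm = np.linalg.norm(blocks[j])
        blocks[j] = blocks[j] / norm if norm > 1e-12 else 0.0
    vec = blocks.ravel()
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 1e-12 else np.zeros_like(vec)


def fit_slide_classifier(slide_vectors: np.ndarray, labels: np.ndarray,
                         seed: int = 0) -> LinearSVC:
    """Linear-kernel one-vs-rest SVM, C=1, balanced class weights."""
    slide_vectors = np.asarray(slide_vectors, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(slide_vectors)):
        raise ValueError("slide vectors must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("slide classifier needs at least two classes")
    clf = LinearSVC(C=1.0, class_weight="balanced", random_state=seed % (2**31))
    clf.fit(slide_vectors, labels)
    return clf


def predict_slide(classifier: LinearSVC, slide_vector: np.ndarray):
    """Predicted class plus per-class scores softmax-calibrated to a simplex."""
    v = np.asarray(slide_vector, dtype=np.float64).reshape(1, -1)
    margins = classifier.decision_function(v)
    if margins.ndim == 1:  # binary: one margin -> two symmetric pseudo-margins
        margins = np.column_stack([-margins, margins])
    z = margins - margins.max(axis=1, keepdims=True)
    scores = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    idx = int(scores[0].argmax())
    return classifier.classes_[idx], dict(zip(classifier.classes_.tolist(), scores[0]))
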
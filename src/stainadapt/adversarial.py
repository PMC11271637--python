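"""Domain-adversarial patch classifier with gradient reversal.

Three components share one feature extractor G_f: a label predictor G_y
trained with cross-entropy on (enhanced) source patches, and a domain
discriminator G_d trained on an intermediate "tap" block's feature map of
both domains.  A gradient reversal layer sits between the tap features and
the discriminator, so a single optimizer step minimizes

    L = L_p + L_adv

for the label predictor and discriminator while the feature extractor
receives the *reversed* adversarial gradient and learns features the
discriminator cannot use — i.e. domain-invariant features.

The discriminator taps block 4 by default: late enough to carry semantic
context, early enough not to be overfit to source-label semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from ._seeding import derive_seed, rng_for
from .fourier import EnhancerPolicy, Patch, enhance_batch

logger = logging.getLogger("stainadapt")

__all__ = [
    "TrainingConfig",
    "LossReport",
    "DomainAdversarialModel",
    "build_model",
    "extract_features",
    "label_loss",
    "adversarial_loss",
    "train_step",
    "fit",
]

_EPS = 1e-12


@dataclass
class TrainingConfig:
    """Hyper-parameters of the adversarial training procedure.

    Defaults follow the published protocol for the full-scale WSI setting:
    Adam with learning rate 1e-4, batches of 256 patches, at most 20 epochs
    with early stopping after 10 epochs without improvement, 3 folds and
    5 seeds.  Reduced-scale studies override them explicitly.
    """

    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 20
    patience: int = 10
    grl_lambda: float = 1.0
    adversarial: bool = True
    enhancer: EnhancerPolicy = field(default_factory=EnhancerPolicy)
    augment_rotation: bool = True
    augment_flip: bool = True
    augment_color_jitter: bool = True
    folds: int = 3
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    val_fraction: float = 0.25
    backbone: str = "tiny"          # "tiny" or "residual18"
    backbone_channels: int = 8      # tiny backbone width
    pretrained: str = "none"        # generic pretrained weights are not bundled
    input_px: int = 64


@dataclass
class LossReport:
    """Per-step losses; ``total`` is exactly their sum."""

    label_loss: float
    adversarial_loss: float

    @property
    def total(self) -> float:
        return self.label_loss + self.adversarial_loss


class DomainAdversarialModel(nn.Module):
    """Feature extractor + label predictor + domain discriminator."""

    def __init__(self, backbone: nn.Module, n_classes: int, tap_block: int = 4,
                 grl_lambda: float = 1.0, input_px: int = 64, seed: int = 0):
        super().__init__()
        if not 2 <= tap_block <= backbone.n_blocks:
            raise ValueError(f"tap_block must be in [2, {backbone.n_blocks}], got {tap_block}")
        if grl_lambda <= 0:
            raise ValueError("grl_lambda must be positive")
        self.backbone = backbone
        self.n_classes = n_classes
        self.tap_block = tap_block
        self.grl_lambda = grl_lambda
        self.input_px = input_px
        rng = np.random.default_rng(derive_seed(seed, "heads"))
        self.classifier = nn.Linear(backbone.embed_dim, n_classes, rng=rng)
        tap_ch = backbone.block_channels[tap_block - 1]
        tap_px = input_px // backbone.block_strides[tap_block - 1]
        # large feature maps are average-pooled onto a 32x32 grid before the
        # fully connected discriminator head (m x 32 x 32 -> 256 -> 100 -> 1)
        self.disc_grid = min(32, tap_px)
        self.discriminator = nn.Sequential(
            nn.Linear(tap_ch * self.disc_grid * self.disc_grid, 256, rng=rng),
            nn.ReLU(),
            nn.Linear(256, 100, rng=rng),
            nn.ReLU(),
            nn.Linear(100, 1, rng=rng),
        )

    # -- forward paths ------------------------------------------------------
    def forward_blocks(self, x: nn.Tensor) -> list[nn.Tensor]:
        return self.backbone.forward_blocks(x)

    def label_logits(self, final_block: nn.Tensor) -> nn.Tensor:
        return self.classifier(nn.global_avg_pool(final_block))

    def discriminate(self, tap: nn.Tensor, reverse: bool = True) -> nn.Tensor:
        """Domain logits from a tap-block feature map (optionally via GRL)."""
        h = nn.grl(tap, self.grl_lambda) if reverse else tap
        h = nn.adaptive_avg_pool2d(h, self.disc_grid)
        h = nn.reshape(h, (h.shape[0], -1))
        return self.discriminator(h)

    # -- inference helpers --------------------------------------------------
    def predict_proba(self, patches: Sequence[Patch]) -> np.ndarray:
        """Class probabilities (softmax) for a batch, in evaluation mode."""
        self.eval()
        x = nn.Tensor(_stack(patches))
        logits = self.label_logits(self.forward_blocks(x)[-1]).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def embed(self, patches: Sequence[Patch], batch_size: int = 256) -> np.ndarray:
        """Pooled final-block embeddings (n x m), evaluation mode."""
        self.eval()
        out = []
        patches = list(patches)
        for i in range(0, len(patches), batch_size):
            x = nn.Tensor(_stack(patches[i : i + batch_size]))
            out.append(nn.global_avg_pool(self.forward_blocks(x)[-1]).data)
        return np.concatenate(out, axis=0)


def build_model(config: TrainingConfig, n_classes: int, tap_block: int = 4,
                seed: int = 0) -> DomainAdversarialModel:
    if config.backbone == "tiny":
        backbone = nn.TinyBackbone(config.backbone_channels, seed=derive_seed(seed, "backbone"))
    elif config.backbone == "residual18":
        backbone = nn.ResidualBackbone(seed=derive_seed(seed, "backbone"))
    else:
        raise ValueError(f"unknown backbone {config.backbone!r}")
    return DomainAdversarialModel(
        backbone, n_classes, tap_block=tap_block,
        grl_lambda=config.grl_lambda, input_px=config.input_px,
        seed=seed,
    )


def _stack(patches: Sequence[Patch]) -> np.ndarray:
    """Patches -> N x 3 x H x W float32 batch."""
    return np.stack([p.pixels.transpose(2, 0, 1) for p in patches]).astype(np.float32)


def extract_features(model: DomainAdversarialModel, batch: Sequence[Patch],
                     block: int) -> np.ndarray:
    """Named block's activation map (n x c x h x w), evaluation mode."""
    nb = model.backbone.n_blocks
    if not 2 <= block <= nb:
        raise ValueError(f"block must be in [2, {nb}], got {block}")
    model.eval()
    x = nn.Tensor(_stack(batch))
    return model.forward_blocks(x)[block - 1].data


# ---------------------------------------------------------------------------
# Losses (array-level reference forms)
# ---------------------------------------------------------------------------

def label_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy -log p(true class) over a batch of simplex rows."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if probabilities.ndim != 2:
        raise ValueError("probabilities must be n x Y")
    n, y = probabilities.shape
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if labels.min() < 0 or labels.max() >= y:
        raise ValueError("labels out of range")
    p_true = probabilities[np.arange(n), labels]
    if np.any(p_true <= 0):
        logger.warning("zero probability at a true class; clamping to %.0e", _EPS)
        p_true = np.maximum(p_true, _EPS)
    return float(-np.log(p_true).mean())


def adversarial_loss(source_probs: np.ndarray, target_probs: np.ndarray) -> float:
    """Discriminator loss: -mean log p over source - mean log(1-p) over target."""
    source_probs = np.asarray(source_probs, dtype=np.float64).ravel()
    target_probs = np.asarray(target_probs, dtype=np.float64).ravel()
    if source_probs.size == 0 or target_probs.size == 0:
        raise ValueError("both domains must contribute at least one patch")
    s = np.clip(source_probs, _EPS, 1 - _EPS)
    t = np.clip(target_probs, _EPS, 1 - _EPS)
    return float(-np.log(s).mean() - np.log(1 - t).mean())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _augment(patches: list[Patch], rng: np.random.Generator,
             config: TrainingConfig) -> list[Patch]:
    out = []
    for p in patches:
        pix = p.pixels
        if config.augment_rotation:
            pix = np.rot90(pix, k=int(rng.integers(4)), axes=(0, 1))
        if config.augment_flip and rng.random() < 0.5:
            pix = pix[:, ::-1]
        if config.augment_color_jitter:
            sc = rng.uniform(0.9, 1.1, 3)
            sh = rng.uniform(-0.05, 0.05, 3)
            pix = np.clip(pix * sc + sh, 0.0, 1.0)
        out.append(replace(p, pixels=np.ascontiguousarray(pix)))
    return out


def train_step(model: DomainAdversarialModel, optimizer: nn.Adam,
               source_batch: Sequence[Patch], target_batch: Sequence[Patch],
               config: TrainingConfig, step_seed: int = 0) -> LossReport:
    """One joint update of feature extractor, label head and discriminator.

    The source batch first passes through the enhancer with the configured
    policy (re-seeded per step from ``step_seed``); the label loss is
    computed on the enhanced source only; the discriminator sees tap-block
    features of enhanced source (domain label 1) and raw target (0), routed
    through gradient reversal.  Returns the pre-update losses.
    """
    if not source_batch or (config.adversarial and not target_batch):
        raise ValueError("batches must be non-empty")
    if any(p.label is None for p in source_batch):
        raise ValueError("source batch must be fully labeled")

    policy = replace(config.enhancer, rng_seed=step_seed)
    enhanced = enhance_batch(source_batch, list(target_batch), policy)

    model.train()
    xs = nn.Tensor(_stack(enhanced))
    ys = np.array([p.label for p in enhanced])
    blocks_s = model.forward_blocks(xs)
    lp = nn.cross_entropy_logits(model.label_logits(blocks_s[-1]), ys)

    if config.adversarial:
        xt = nn.Tensor(_stack(target_batch))
        blocks_t = model.forward_blocks(xt)
        zs = model.discriminate(blocks_s[model.tap_block - 1])
        zt = model.discriminate(blocks_t[model.tap_block - 1])
        ps = nn.clip(nn.sigmoid(zs), 1e-7, 1 - 1e-7)
        pt = nn.clip(nn.sigmoid(zt), 1e-7, 1 - 1e-7)
        one = nn.Tensor(np.ones_like(pt.data))
        ladv = nn.add(
            nn.scale(nn.mean(nn.log(ps)), -1.0),
            nn.scale(nn.mean(nn.log(nn.add(one, nn.scale(pt, -1.0)))), -1.0),
        )
        total = nn.add(lp, ladv)
        report = LossReport(label_loss=lp.item(), adversarial_loss=ladv.item())
    else:
        total = lp
        report = LossReport(label_loss=lp.item(), adversarial_loss=0.0)

    model.zero_grad()
    total.backward()
    optimizer.step()
    return report


def _patch_label_loss(model: DomainAdversarialModel, patches: list[Patch],
                      batch_size: int = 256) -> float:
    """Evaluation-mode mean cross-entropy on a labeled patch list."""
    losses, counts = [], []
    for i in range(0, len(patches), batch_size):
        chunk = patches[i : i + batch_size]
        probs = model.predict_proba(chunk)
        labels = np.array([p.label for p in chunk])
        losses.append(label_loss(probs, labels) * len(chunk))
        counts.append(len(chunk))
    return float(np.sum(losses) / np.sum(counts))


def fit(source_slides, target_slides, config: TrainingConfig, seed: int = 0,
        tap_block: int = 4):
    """Train on labeled source + unlabeled target patches; early-stop on
    validation-fold source label loss; return (best model, per-epoch trace).

    ``source_slides`` / ``target_slides`` are SlideRecord-like objects with a
    ``patches`` list; source patches must carry labels.  A fraction of the
    source *slides* (grouped by patient) is held out to monitor the loss.
    """
    source_slides = list(source_slides)
    target_slides = list(target_slides)
    src_patches = [p for s in source_slides for p in s.patches]
    tgt_patches = [p for s in target_slides for p in s.patches]
    labels = {p.label for p in src_patches}
    if len(labels) < 2:
        raise ValueError("source data must contain at least two classes")
    n_classes = int(max(labels)) + 1

    model = build_model(config, n_classes, tap_block=tap_block, seed=seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    trace: list[dict] = []
    if config.max_epochs == 0:
        return model, trace

    # patient-grouped validation split of the source slides
    rng_split = rng_for(seed, "valsplit")
    patients = sorted({s.patient_id for s in source_slides})
    rng_split.shuffle(patients)
    n_val = max(1, int(round(config.val_fraction * len(patients)))) if len(patients) > 1 else 0
    val_patients = set(patients[:n_val])
    train_patches = [p for s in source_slides if s.patient_id not in val_patients
                     for p in s.patches]
    val_patches = [p for s in source_slides if s.patient_id in val_patients
                   for p in s.patches]
    if not train_patches or len({p.label for p in train_patches}) < 2:
        train_patches, val_patches = src_patches, []

    best_loss, best_state, wait = np.inf, None, 0
    for epoch in range(config.max_epochs):
        rng_epoch = rng_for(seed, "epoch", epoch)
        order_s = rng_epoch.permutation(len(train_patches))
        order_t = rng_epoch.permutation(len(tgt_patches)) if tgt_patches else np.array([], int)
        bs = config.batch_size
        n_steps = max(1, int(np.ceil(len(train_patches) / bs)))
        ep_lp, ep_ladv = [], []
        for step in range(n_steps):
            sb = [train_patches[i] for i in order_s[step * bs : (step + 1) * bs]]
            if not sb:
                continue
            if len(order_t):
                # cycle through the shuffled target patches
                idx = [order_t[(step * bs + j) % len(order_t)] for j in range(len(sb))]
                tb = [tgt_patches[i] for i in idx]
            else:
                tb = []
            aug_rng = rng_for(seed, "augment", epoch, step)
            sb = _augment(sb, aug_rng, config)
            tb = _augment(tb, aug_rng, config)
            report = train_step(model, optimizer, sb, tb, config,
                                step_seed=derive_seed(seed, "enhance", epoch, step))
            ep_lp.append(report.label_loss)
            ep_ladv.append(report.adversarial_loss)

        monitor = _patch_label_loss(model, val_patches) if val_patches \
            else float(np.mean(ep_lp))
        trace.append({
            "epoch": epoch,
            "label_loss": float(np.mean(ep_lp)),
            "adversarial_loss": float(np.mean(ep_ladv)),
            "total_loss": float(np.mean(ep_lp) + np.mean(ep_ladv)),
            "monitor_loss": monitor,
        })
        logger.info("epoch %d label=%.4f adv=%.4f monitor=%.4f",
                    epoch, trace[-1]["label_loss"], trace[-1]["adversarial_loss"], monitor)
        if monitor < best_loss - 1e-6:
            best_loss, best_state, wait = monitor, model.state_dict(), 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, trace
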
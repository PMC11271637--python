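"""Experiment orchestration: arms, cross-validation, manifests, seeding.

An experiment arm selects which components are active:

======== ==================== ====================
arm      adversarial branch   amplitude enhancer
======== ==================== ====================
base     off                  off (probability 0)
fft      off                  on
adv      on                   off (probability 0)
adv_fft  on                   on
======== ==================== ====================

``run_experiment`` drives patient-grouped cross-validation folds x seeds
through fit -> embed -> codebook -> VLAD -> slide classifier -> metrics on
the source validation fold and the full target set.  One master seed fans
out deterministically to every stochastic component, so every artifact is
reproducible from (config, seed); a config hash is recorded in all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import GroupKFold

from ._seeding import derive_seed
from .adversarial import TrainingConfig, extract_features, fit
from .evaluation import compute_metrics, domain_probe_accuracy
from .fourier import EnhancerPolicy
from .slides import SlideRecord, fit_codebook, fit_slide_classifier, predict_slide, vlad_encode
from .synthetic import SyntheticSpec, generate_dataset, true_label

logger = logging.getLogger("stainadapt")

__all__ = [
    "ARMS",
    "ExperimentSpec",
    "LeakageError",
    "run_experiment",
    "run_benchmark",
    "sweep_tap",
    "benchmark_config",
    "write_manifest",
    "validate_manifest",
    "config_hash",
]

ARMS = ("base", "fft", "adv", "adv_fft")

SCHEMA_VERSION = 1

MANIFEST_COLUMNS = ["slide_id", "patient_id", "domain", "label",
                    "x", "y", "w", "h", "path"]


class LeakageError(ValueError):
    """A target-domain label was about to reach a training loader."""


@dataclass
class ExperimentSpec:
    """Complete description of one experiment (config-hashable)."""

    arm: str = "adv_fft"
    tap_block: int = 4
    training: TrainingConfig = field(default_factory=TrainingConfig)
    k: int | None = None  # VLAD codebook size; default 4 multi-class, 1 binary
    out_dir: str | None = None
    schema_version: int = SCHEMA_VERSION

    def resolved_training(self) -> TrainingConfig:
        """Apply the arm's invariants to the training config."""
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; choose from {ARMS}")
        if not self.training.seeds:
            raise ValueError("at least one seed is required")
        cfg = self.training
        adversarial = self.arm in ("adv", "adv_fft")
        if self.arm in ("base", "adv"):
            enhancer = replace(cfg.enhancer, probability=0.0)
        else:
            if cfg.enhancer.probability <= 0:
                raise ValueError(f"arm {self.arm!r} requires enhancer probability > 0")
            enhancer = cfg.enhancer
        return replace(cfg, adversarial=adversarial, enhancer=enhancer)


def config_hash(spec: ExperimentSpec) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(spec), sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def spec_to_yaml(spec: ExperimentSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(spec), sort_keys=True))


def spec_from_yaml(path) -> ExperimentSpec:
    raw = yaml.safe_load(Path(path).read_text())
    if raw.get("schema_version", 1) != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {raw.get('schema_version')}")
    training = raw.pop("training", {})
    enhancer = training.pop("enhancer", {}) if isinstance(training, dict) else {}
    cfg = TrainingConfig(**{**training, "enhancer": EnhancerPolicy(**enhancer),
                            "seeds": tuple(training.get("seeds", (0, 1, 2, 3, 4)))}) \
        if isinstance(training, dict) else TrainingConfig()
    return ExperimentSpec(**{**raw, "training": cfg})


# ---------------------------------------------------------------------------
# Slide-level evaluation helpers
# ---------------------------------------------------------------------------

def _slide_vectors(model, slides: list[SlideRecord], codebook) -> np.ndarray:
    return np.stack([vlad_encode(model.embed(s.patches), codebook) for s in slides])


def _evaluate_split(model, train_slides, eval_slides, k: int, seed: int):
    """Codebook + VLAD + SVM fitted on train slides, applied to eval slides."""
    train_emb = np.concatenate([model.embed(s.patches) for s in train_slides])
    codebook = fit_codebook(train_emb, k=k, seed=derive_seed(seed, "codebook"))
    xtr = _slide_vectors(model, train_slides, codebook)
    ytr = np.array([s.label for s in train_slides])
    clf = fit_slide_classifier(xtr, ytr, seed=derive_seed(seed, "svm"))
    xev = _slide_vectors(model, eval_slides, codebook)
    preds, scores = [], []
    for v in xev:
        c, sc = predict_slide(clf, v)
        preds.append(c)
        scores.append([sc[cls] for cls in clf.classes_])
    y_eval = np.array([true_label(s) for s in eval_slides])
    metrics = compute_metrics(y_eval, np.array(preds), np.asarray(scores))
    pred_rows = [
        {"slide_id": s.slide_id, "domain": s.domain, "true": int(t), "pred": int(p)}
        for s, t, p in zip(eval_slides, y_eval, preds)
    ]
    return metrics, pred_rows


def run_experiment(spec: ExperimentSpec, source_slides, target_slides,
                   max_folds: int | None = None):
    """Patient-grouped folds x seeds; returns (report, predictions) tables.

    The report has one row per (arm, fold, seed, domain) with balanced
    accuracy, Cohen's kappa, macro-F1 and AUC; the predictions table holds
    slide-level predictions for every evaluation.
    """
    cfg = spec.resolved_training()
    source_slides = list(source_slides)
    target_slides = list(target_slides)
    n_classes = len({s.label for s in source_slides})
    k = spec.k if spec.k is not None else (4 if n_classes > 2 else 1)
    chash = config_hash(spec)

    groups = np.array([s.patient_id for s in source_slides])
    labels = np.array([s.label for s in source_slides])
    gkf = GroupKFold(n_splits=cfg.folds)
    rows, pred_rows = [], []
    for fold, (tr, va) in enumerate(gkf.split(np.zeros(len(source_slides)), labels, groups)):
        if max_folds is not None and fold >= max_folds:
            break
        train_slides = [source_slides[i] for i in tr]
        val_slides = [source_slides[i] for i in va]
        for seed in cfg.seeds:
            fit_seed = derive_seed(seed, "fold", fold)
            model, _ = fit(train_slides, target_slides, cfg, seed=fit_seed,
                           tap_block=spec.tap_block)
            for domain, eval_slides in (("source", val_slides), ("target", target_slides)):
                metrics, preds = _evaluate_split(
                    model, train_slides, eval_slides, k=k, seed=fit_seed)
                rows.append({"arm": spec.arm, "fold": fold, "seed": seed,
                             "domain": domain, "config_hash": chash, **metrics})
                for p in preds:
                    pred_rows.append({"arm": spec.arm, "fold": fold, "seed": seed, **p})
            logger.info("arm=%s fold=%d seed=%d done", spec.arm, fold, seed)
    return pd.DataFrame(rows), pd.DataFrame(pred_rows)


# ---------------------------------------------------------------------------
# The reduced-scale synthetic benchmark
# ---------------------------------------------------------------------------

def benchmark_config(arm: str = "adv_fft") -> ExperimentSpec:
    """Frozen conditions of the synthetic two-domain benchmark.

    Tiny backbone on 64x64 patches; learning rate and batch size are scaled
    for the small network and dataset (1e-3, 64); 12 epochs max with
    patience 5; enhancer probability 0.5; gradient reversal constant 1.
    """
    training = TrainingConfig(
        learning_rate=3e-3,
        batch_size=64,
        max_epochs=25,
        patience=8,
        backbone="tiny",
        input_px=64,
        enhancer=EnhancerPolicy(probability=0.5),
    )
    return ExperimentSpec(arm=arm, tap_block=4, training=training)


def run_benchmark(seeds=(0, 1, 2, 3, 4), arms=("base", "adv_fft"),
                  data_spec: SyntheticSpec | None = None,
                  probe_patches: int = 200) -> pd.DataFrame:
    """Train each arm per seed on the synthetic benchmark; one table out.

    Per (arm, seed): slide-level balanced accuracy on the held-out source
    fold and on the full target set, plus the held-out accuracy of a domain
    probe on frozen tap-block features (lower = more domain-invariant).
    """
    data_spec = data_spec or SyntheticSpec()
    source_slides, target_slides = generate_dataset(data_spec)
    # same patient-grouped split as run_experiment's first fold
    groups = np.array([s.patient_id for s in source_slides])
    labels = np.array([s.label for s in source_slides])
    gkf = GroupKFold(n_splits=3)
    tr, va = next(iter(gkf.split(np.zeros(len(source_slides)), labels, groups)))
    train_slides = [source_slides[i] for i in tr]
    val_slides = [source_slides[i] for i in va]
    rows = []
    for arm in arms:
        spec = benchmark_config(arm)
        cfg = replace(spec, arm=arm).resolved_training()
        for seed in seeds:
            fit_seed = derive_seed(seed, "fold", 0)
            model, _ = fit(train_slides, target_slides, cfg, seed=fit_seed,
                           tap_block=spec.tap_block)
            metrics = {}
            for domain, eval_slides in (("source", val_slides),
                                        ("target", target_slides)):
                metrics[domain], _ = _evaluate_split(
                    model, train_slides, eval_slides, k=1, seed=fit_seed)
            rng = np.random.default_rng(derive_seed(seed, "probe-sample"))
            src_patches = [p for s in source_slides for p in s.patches]
            tgt_patches = [p for s in target_slides for p in s.patches]
            src_sel = [src_patches[i] for i in
                       rng.choice(len(src_patches), min(probe_patches, len(src_patches)),
                                  replace=False)]
            tgt_sel = [tgt_patches[i] for i in
                       rng.choice(len(tgt_patches), min(probe_patches, len(tgt_patches)),
                                  replace=False)]
            fs = extract_features(model, src_sel, block=spec.tap_block)
            ft = extract_features(model, tgt_sel, block=spec.tap_block)
            probe = domain_probe_accuracy(fs, ft, seed=derive_seed(seed, "probe"))
            rows.append({
                "arm": arm, "seed": seed,
                "source_balanced_accuracy": metrics["source"]["balanced_accuracy"],
                "target_balanced_accuracy": metrics["target"]["balanced_accuracy"],
                "source_kappa": metrics["source"]["cohens_kappa"],
                "target_kappa": metrics["target"]["cohens_kappa"],
                "domain_probe_accuracy": probe,
            })
            logger.info("benchmark arm=%s seed=%d src=%.1f tgt=%.1f probe=%.3f",
                        arm, seed, rows[-1]["source_balanced_accuracy"],
                        rows[-1]["target_balanced_accuracy"], probe)
    return pd.DataFrame(rows)


def sweep_tap(taps=(2, 3, 4, 5), seed: int = 0,
              data_spec: SyntheticSpec | None = None) -> pd.DataFrame:
    """Adversarial+enhancer arm with the discriminator tapping each block.

    The tiny backbone has 4 blocks, so taps above it are skipped with a
    note; emits per-tap target balanced accuracy on the benchmark.
    """
    data_spec = data_spec or SyntheticSpec()
    source_slides, target_slides = generate_dataset(data_spec)
    rows = []
    for tap in taps:
        spec = benchmark_config("adv_fft")
        max_tap = 4 if spec.training.backbone == "tiny" else 5
        if not 2 <= tap <= max_tap:
            logger.warning("tap %d outside [2, %d] for this backbone; skipped", tap, max_tap)
            continue
        spec = replace(spec, tap_block=tap,
                       training=replace(spec.training, seeds=(seed,), max_epochs=8))
        report, _ = run_experiment(spec, source_slides, target_slides, max_folds=1)
        tgt = report[report.domain == "target"].iloc[0]
        rows.append({"tap_block": tap,
                     "target_balanced_accuracy": tgt.balanced_accuracy,
                     "target_kappa": tgt.cohens_kappa})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(slides: list[SlideRecord], path, image_paths: dict[str, str]) -> None:
    """One CSV row per slide; target labels are withheld from the manifest."""
    rows = []
    for s in slides:
        h, w = (s.image.shape[:2] if s.image is not None else (0, 0))
        rows.append({
            "slide_id": s.slide_id, "patient_id": s.patient_id, "domain": s.domain,
            "label": s.label if s.domain == "source" else "",
            "x": 0, "y": 0, "w": w, "h": h,
            "path": image_paths[s.slide_id],
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def validate_manifest(path, for_training: bool = False) -> pd.DataFrame:
    """Schema-check a manifest; errors name the offending row.

    With ``for_training=True`` any target-domain row carrying a label is
    rejected (labels of the target domain must never reach a training
    loader)."""
    df = pd.read_csv(path, dtype={"label": "object"})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    base = Path(path).parent
    for idx, row in df.iterrows():
        if row["domain"] not in ("source", "target"):
            raise ValueError(f"row {idx}: invalid domain {row['domain']!r}")
        has_label = pd.notna(row["label"]) and str(row["label"]) != ""
        if row["domain"] == "source" and not has_label:
            raise ValueError(f"row {idx}: source slide {row['slide_id']} lacks a label")
        if for_training and row["domain"] == "target" and has_label:
            raise LeakageError(
                f"row {idx}: target slide {row['slide_id']} carries a label; "
                "target labels must not reach training loaders")
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ValueError(f"row {idx}: file not found: {row['path']}")
    return df
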
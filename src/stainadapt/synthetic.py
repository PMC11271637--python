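"""Two-domain virtual-slide generator with controllable domain shift.

Each slide is a flat RGB texture image whose *class* is carried by motif
geometry (blob fields vs. oriented stripes — i.e. phase/structure), while
its *domain* is carried by appearance only: a 3x3 channel-mixing matrix, a
smooth radial gain on the amplitude spectrum, and additive noise.  Both
domains share identical class motif parameters, so by construction the
label signal lives in phase and the domain signal in amplitude/color — the
regime the adversarial Fourier pipeline is designed for.

Target labels are generated for evaluation but quarantined: target
``SlideRecord.label`` is ``None`` and the truth is reachable only through
:func:`true_label`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seeding import derive_seed, rng_for
from .slides import SlideRecord, extract_patches

__all__ = [
    "ClassMotif",
    "DomainTransform",
    "SyntheticSpec",
    "generate_dataset",
    "benchmark_shift_severity",
    "true_label",
]

_BACKGROUND = np.array([0.92, 0.80, 0.88])  # eosin-like pale pink
_FOREGROUND = np.array([0.42, 0.30, 0.58])  # hematoxylin-like purple


@dataclass(frozen=True)
class ClassMotif:
    """Texture parameters defining one class's structure."""

    kind: str  # "blobs" or "stripes"
    blob_density: float = 8.0        # expected blobs per 64x64 area
    blob_radius: tuple[float, float] = (4.0, 1.0)  # mean, sd in pixels
    stripe_freq: float = 6.0         # cycles per 64 px
    stripe_angle: float = 30.0       # degrees


@dataclass(frozen=True)
class DomainTransform:
    """Appearance-only transform: channel mixing, amplitude gain, noise."""

    mixing: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    gain_amp: float = 1.0     # amplitude gain at DC; 1.0 = no spectral shift
    gain_radius: float = 0.06  # radial extent of the gain (cycles/pixel)
    noise_sigma: float = 0.0

    def matrix(self) -> np.ndarray:
        m = np.asarray(self.mixing, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("mixing must be a 3x3 matrix")
        if abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("mixing matrix must be invertible")
        return m

    def apply(self, img: np.ndarray, rng: np.random.Generator | None = None,
              with_noise: bool = True) -> np.ndarray:
        if self.gain_amp <= 0:
            raise ValueError("amplitude gain must be positive")
        out = img @ self.matrix().T
        if self.gain_amp != 1.0:
            fy = np.fft.fftfreq(out.shape[0])[:, None]
            fx = np.fft.fftfreq(out.shape[1])[None, :]
            r = np.sqrt(fx**2 + fy**2)
            g = 1.0 + (self.gain_amp - 1.0) * np.exp(-((r / self.gain_radius) ** 2))
            spec = np.fft.fft2(out, axes=(0, 1)) * g[:, :, None]
            out = np.fft.ifft2(spec, axes=(0, 1)).real
        if with_noise and self.noise_sigma > 0:
            if rng is None:
                raise ValueError("noise requires an rng")
            out = out + rng.normal(0.0, self.noise_sigma, out.shape)
        return np.clip(out, 0.0, 1.0)


def _default_motifs() -> tuple[ClassMotif, ...]:
    return (
        ClassMotif(kind="blobs", blob_density=8.0, blob_radius=(4.0, 1.0)),
        ClassMotif(kind="stripes", stripe_freq=6.0, stripe_angle=30.0),
    )


def _default_target_transform() -> DomainTransform:
    # strong but invertible stain/scanner shift: hue rotation toward blue,
    # global darkening, low-frequency amplitude boost, more sensor noise
    return DomainTransform(
        mixing=((0.07, 0.10, 0.42), (0.10, 0.39, 0.10), (0.42, 0.07, 0.07)),
        gain_amp=1.6,
        gain_radius=0.06,
        noise_sigma=0.02,
    )


@dataclass
class SyntheticSpec:
    """Conditions of the synthetic benchmark; the defaults ARE the benchmark.

    2 classes x 20 slides per class per domain (40 slides/domain), 16
    patches of 64x64 per slide, sized so the full adversarial-vs-base
    comparison runs on one CPU in minutes.
    """

    n_classes: int = 2
    slides_per_class: int = 20
    patches_per_slide: int = 16
    patch_px: int = 64
    slide_px: int = 256
    class_motifs: tuple[ClassMotif, ...] = field(default_factory=_default_motifs)
    source_transform: DomainTransform = field(
        default_factory=lambda: DomainTransform(noise_sigma=0.01))
    target_transform: DomainTransform = field(default_factory=_default_target_transform)
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes != len(self.class_motifs):
            raise ValueError("need one motif per class")
        if len(set(self.class_motifs)) < len(self.class_motifs):
            warnings.warn("identical motifs across classes: classes are indistinguishable")
            raise ValueError("refusing to generate a degenerate (identical-motif) dataset")
        self.source_transform.matrix()
        self.target_transform.matrix()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_structure(motif: ClassMotif, px: int, rng: np.random.Generator) -> np.ndarray:
    """Grayscale structure field in [0, 1] realizing the motif."""
    yy, xx = np.mgrid[0:px, 0:px].astype(np.float64)
    if motif.kind == "blobs":
        s = np.zeros((px, px))
        n_blobs = rng.poisson(motif.blob_density * (px / 64.0) ** 2)
        for _ in range(max(1, n_blobs)):
            cy, cx = rng.uniform(0, px, 2)
            r = max(1.0, rng.normal(*motif.blob_radius))
            s += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r * r)))
        s = np.clip(s, 0, 1)
    elif motif.kind == "stripes":
        theta = np.deg2rad(motif.stripe_angle + rng.normal(0.0, 5.0))
        phase = rng.uniform(0, 2 * np.pi)
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        s = 0.5 + 0.5 * np.sin(2 * np.pi * motif.stripe_freq * proj / 64.0 + phase)
    else:
        raise ValueError(f"unknown motif kind {motif.kind!r}")
    return s


def _render_slide(motif: ClassMotif, px: int, rng: np.random.Generator) -> np.ndarray:
    s = _render_structure(motif, px, rng)
    img = _BACKGROUND[None, None, :] * (1 - s[:, :, None]) + \
        _FOREGROUND[None, None, :] * s[:, :, None]
    img = img * rng.uniform(0.97, 1.03)  # mild slide-to-slide intensity jitter
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSpec):
    """Render both domains; returns (source_slides, target_slides).

    Byte-deterministic for a fixed ``spec.seed``.  Every slide carries its
    extracted patches; source patches inherit the slide label, target
    patches are unlabeled.
    """
    spec.validate()
    out: dict[str, list[SlideRecord]] = {"source": [], "target": []}
    transforms = {"source": spec.source_transform, "target": spec.target_transform}
    for domain in ("source", "target"):
        for c in range(spec.n_classes):
            for i in range(spec.slides_per_class):
                rng = rng_for(spec.seed, "slide", domain, c, i)
                img = _render_slide(spec.class_motifs[c], spec.slide_px, rng)
                img = transforms[domain].apply(img, rng)
                sid = f"{domain}-c{c}-s{i:03d}"
                is_src = domain == "source"
                rec = SlideRecord(
                    slide_id=sid,
                    patient_id=f"pat-{sid}",
                    domain=domain,
                    label=c if is_src else None,
                    image=img,
                    _eval_label=c,
                )
                rec.patches = extract_patches(
                    img,
                    n=spec.patches_per_slide,
                    patch_px=spec.patch_px,
                    out_px=spec.patch_px,
                    mode="random",
                    seed=derive_seed(spec.seed, "patches", domain, c, i),
                    slide_id=sid,
                    domain=domain,
                    label=c if is_src else None,
                )
                out[domain].append(rec)
    return out["source"], out["target"]


def true_label(slide: SlideRecord) -> int:
    """Evaluation-only accessor for a slide's ground-truth class."""
    if slide.label is not None:
        return slide.label
    if slide._eval_label is None:
        raise ValueError(f"slide {slide.slide_id} has no ground-truth label")
    return slide._eval_label


def benchmark_shift_severity(spec: SyntheticSpec, n_probe: int = 24) -> float:
    """Mean per-bin log-amplitude distance between domain-averaged spectra.

    Both domain transforms are applied (noise-free) to the *same* probe
    content, so identical transforms score exactly 0 and the score grows
    strictly with amplitude-gain deviation from 1.
    """
    spec.validate()
    eps = 1e-9
    amps = {"source": [], "target": []}
    for i in range(n_probe):
        rng = rng_for(spec.seed, "shiftprobe", i)
        motif = spec.class_motifs[i % spec.n_classes]
        content = _render_slide(motif, spec.patch_px, rng)
        for domain, tf in (("source", spec.source_transform),
                           ("target", spec.target_transform)):
            img = tf.apply(content, with_noise=False)
            amps[domain].append(np.abs(np.fft.fft2(img, axes=(0, 1))))
    a_s = np.mean(amps["source"], axis=0)
    a_t = np.mean(amps["target"], axis=0)
    return float(np.mean(np.abs(np.log(a_s + eps) - np.log(a_t + eps))))
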
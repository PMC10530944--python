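"""Synthetic multi-class grayscale phantom generator.

Produces reproducible image sets whose class signal is confined to a
low-dimensional subspace of pixel space, emulating the structure the
eigenspace pipeline assumes: every image is a shared smooth "anatomy"
(an elliptical blob) plus a class-specific linear combination of a few
low-frequency cosine-product modes, plus i.i.d. pixel noise, clipped to
[0, 1].  With ``effect_size = 0`` the classes are statistically identical
and any classifier is reduced to chance; raising ``effect_size`` moves the
class means apart inside the mode span while leaving the noise untouched.

The default spec mirrors the class imbalance of a 4-class dementia-severity
MRI collection (3200/2240/896/64 slices at 128 x 128) scaled down roughly
tenfold, so stratification edge cases (a rare class thinner than the fold
count) are exercised cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .datatypes import LabeledImageSet, Manifest, ValidationError

# Per-coefficient amplitude at effect_size 1, chosen so the class pattern's
# pixel standard deviation is ~0.08 regardless of the mode count: visible
# against the default 0.05 noise floor yet rarely clipped.
_MODE_AMPLITUDE = 0.08

_DEFAULT_CLASSES = ("non_demented", "very_mild", "mild", "moderate")


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic dataset; equal specs give bit-identical data."""

    image_height: int = 128
    image_width: int = 128
    class_names: tuple[str, ...] = _DEFAULT_CLASSES
    n_per_class: tuple[int, ...] = (320, 224, 90, 8)
    effect_size: float = 1.0
    noise_sd: float = 0.05
    n_signal_modes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValidationError("image dimensions must be positive")
        if len(self.class_names) != len(self.n_per_class):
            raise ValidationError(
                f"{len(self.class_names)} class names but "
                f"{len(self.n_per_class)} per-class counts"
            )
        if any(n < 0 for n in self.n_per_class):
            raise ValidationError("per-class counts must be >= 0")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValidationError("effect_size and noise_sd must be >= 0")
        if self.n_signal_modes < 1:
            raise ValidationError("need at least one signal mode")


def _base_pattern(height: int, width: int) -> np.ndarray:
    """Smooth elliptical blob: bright interior fading into a dim background."""
    y = (np.arange(height) + 0.5) / height * 2.0 - 1.0
    x = (np.arange(width) + 0.5) / width * 2.0 - 1.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    r2 = (yy / 0.85) ** 2 + (xx / 0.7) ** 2
    return 0.2 + 0.5 * np.exp(-(r2**2))


def spatial_patterns(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """The deterministic spatial structure of a spec.

    Returns ``(base, modes)`` where ``base`` is the shared (H, W) anatomy
    and ``modes`` is an ``(n_signal_modes, H, W)`` stack of smooth
    cosine-product patterns.  The same seeded stream that drives
    :func:`generate_dataset` draws the mode frequencies, so both functions
    agree on the subspace that carries class information.
    """
    rng = np.random.default_rng(spec.seed)
    return _draw_patterns(spec, rng)


def _draw_patterns(spec: SynthSpec, rng: np.random.Generator):
    h, w = spec.image_height, spec.image_width
    base = _base_pattern(h, w)
    y = (np.arange(h) + 0.5) / h
    x = (np.arange(w) + 0.5) / w
    modes = []
    for _ in range(spec.n_signal_modes):
        fy, fx = rng.integers(1, 5, size=2)
        modes.append(np.outer(np.cos(np.pi * fy * y), np.cos(np.pi * fx * x)))
    return base, np.stack(modes)


def generate_dataset(spec: SynthSpec) -> LabeledImageSet:
    """Generate the phantom image set described by ``spec``.

    Class ``c`` has a fixed coefficient vector over the signal modes drawn
    once from the seeded stream; each of its images is base + effect-scaled
    class pattern + fresh pixel noise, clipped to [0, 1].  The draw order
    (mode frequencies, class coefficients, then per-image noise in class
    order) is fixed, so identical specs reproduce identical pixels.
    """
    rng = np.random.default_rng(spec.seed)
    base, modes = _draw_patterns(spec, rng)
    n_classes = len(spec.class_names)
    coefs = rng.normal(size=(n_classes, spec.n_signal_modes)) * (
        _MODE_AMPLITUDE / np.sqrt(spec.n_signal_modes)
    )

    images, labels = [], []
    for c in range(n_classes):
        pattern = base + spec.effect_size * np.tensordot(coefs[c], modes, axes=1)
        for _ in range(spec.n_per_class[c]):
            img = pattern + rng.normal(0.0, spec.noise_sd, size=base.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(c)

    stack = (
        np.stack(images)
        if images
        else np.empty((0, spec.image_height, spec.image_width))
    )
    return LabeledImageSet(stack, np.asarray(labels, np.int64), list(spec.class_names))


def write_dataset(dataset: LabeledImageSet, directory: str | Path) -> Manifest:
    """Write one 8-bit grayscale PNG per image plus a ``manifest.csv``.

    Round-tripping through :func:`eigenstep.preprocess.load_dataset` at the
    original size reproduces each intensity within 8-bit quantization
    (max abs error <= 1/255).  Returns the manifest, whose paths are
    relative to ``directory``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(max(len(dataset), 1))))
    records = []
    for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
        name = f"img_{i:0{width}d}.png"
        eight_bit = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(eight_bit, mode="L").save(directory / name)
        records.append((name, dataset.class_names[label]))
    manifest = Manifest(records)
    manifest.to_csv(directory / "manifest.csv")
    return manifest
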
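"""Image loading, normalization, and averaging-filter smoothing.

Images are loaded from a CSV manifest, converted to single-channel
luminance, resized to a fixed grid, and rescaled to [0, 1].  The smoothing
stage slides an odd-sized box mask over the image so each output pixel is
the unweighted mean of its neighborhood (for the default 3x3 mask every
weight is 1/9); borders use replicate (edge-value) padding so the output
has the input's shape and no artificial dark halo appears at the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .datatypes import LabeledImageSet, Manifest, ValidationError


@dataclass(frozen=True)
class SmoothingKernel:
    """Uniform box-average mask of odd side length ``size``."""

    size: int = 3

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValidationError(f"kernel size must be odd and >= 1, got {self.size}")

    @property
    def weights(self) -> np.ndarray:
        """The size x size mask; every entry is 1/size**2 and the mask sums to 1."""
        return np.full((self.size, self.size), 1.0 / self.size**2)


def apply_averaging_filter(
    image: np.ndarray, kernel: SmoothingKernel | int = SmoothingKernel()
) -> np.ndarray:
    """Replace each pixel by the mean of its ``size`` x ``size`` neighborhood.

    Border neighborhoods are completed by replicating the nearest edge
    pixel, so a constant image maps to itself exactly and the output range
    never leaves [min(input), max(input)].
    """
    if isinstance(kernel, int):
        kernel = SmoothingKernel(kernel)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {image.shape}")
    if kernel.size > min(image.shape):
        raise ValidationError(
            f"kernel size {kernel.size} exceeds image dims {image.shape}"
        )
    return ndimage.correlate(image, kernel.weights, mode="nearest")


def smooth_dataset(
    dataset: LabeledImageSet, kernel: SmoothingKernel | int = SmoothingKernel()
) -> LabeledImageSet:
    """Apply the averaging filter to every image in the set."""
    if isinstance(kernel, int):
        kernel = SmoothingKernel(kernel)
    smoothed = np.stack(
        [apply_averaging_filter(img, kernel) for img in dataset.images]
    ) if len(dataset) else dataset.images.copy()
    return LabeledImageSet(smoothed, dataset.labels, list(dataset.class_names))


def load_dataset(
    manifest: Manifest | str | Path,
    target_height: int = 128,
    target_width: int = 128,
    class_order: list[str] | None = None,
    root: str | Path | None = None,
) -> LabeledImageSet:
    """Load a manifest into a fixed-size grayscale image stack.

    Each file is decoded, converted to luminance, resized with bilinear
    resampling to ``(target_height, target_width)`` and scaled to [0, 1].
    Label indices follow first-appearance order of the label strings unless
    ``class_order`` supplies an explicit ordering.  ``root``, when given,
    resolves relative manifest paths (defaults to the manifest's own
    directory when the manifest is read from disk).
    """
    if isinstance(manifest, (str, Path)):
        if root is None:
            root = Path(manifest).parent
        manifest = Manifest.from_csv(manifest)
    if target_height < 1 or target_width < 1:
        raise ValidationError("target size must be positive")

    names = class_order if class_order is not None else manifest.class_names
    index = {name: i for i, name in enumerate(names)}

    images, labels = [], []
    for path, label in manifest.records:
        if label not in index:
            raise ValidationError(
                f"record {path!r}: label {label!r} not in declared classes {names}"
            )
        full = Path(root) / path if root is not None else Path(path)
        if not full.exists():
            raise ValidationError(f"record {path!r}: file not found at {full}")
        try:
            with Image.open(full) as im:
                gray = im.convert("L")
                resized = gray.resize((target_width, target_height), Image.BILINEAR)
                arr = np.asarray(resized, dtype=np.float64) / 255.0
        except ValidationError:
            raise
        except Exception as exc:  # undecodable file
            raise ValidationError(f"record {path!r}: cannot decode image ({exc})")
        images.append(arr)
        labels.append(index[label])

    stack = (
        np.stack(images)
        if images
        else np.empty((0, target_height, target_width))
    )
    return LabeledImageSet(stack, np.asarray(labels, dtype=np.int64), list(names))
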
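"""Core containers shared by every pipeline stage."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class LabeledImageSet:
    """A stack of same-size grayscale images with integer class labels.

    ``images`` is an ``(N, H, W)`` float array with intensities in [0, 1];
    ``labels`` holds indices into ``class_names``.  This is the universal
    currency of the pipeline: the synthetic generator produces one, the
    loader produces one, and every downstream stage consumes one.
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValidationError(
                f"images must be a (N, H, W) stack, got shape {self.images.shape}"
            )
        if len(self.images) != len(self.labels):
            raise ValidationError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        n_classes = len(self.class_names)
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= n_classes
        ):
            raise ValidationError(
                f"labels must lie in [0, {n_classes}), "
                f"got range [{self.labels.min()}, {self.labels.max()}]"
            )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def flatten(self) -> np.ndarray:
        """Row-major (N, H*W) view of the pixel data."""
        return self.images.reshape(len(self.images), -1)

    def subset(self, index: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            self.images[index], self.labels[index], list(self.class_names)
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class Manifest:
    """Maps image files to class-name labels; serialized as a two-column CSV."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        paths = [p for p, _ in self.records]
        if len(set(paths)) != len(paths):
            raise ValidationError("manifest paths must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_names(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for _, label in self.records:
            seen.setdefault(label, None)
        return list(seen)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label"])
            writer.writerows(self.records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header[:2]] != ["path", "label"]:
                raise ValidationError(
                    f"{path}: expected header 'path,label', got {header!r}"
                )
            records = [(row[0], row[1]) for row in reader if row]
        return cls(records)
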
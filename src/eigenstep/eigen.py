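"""Eigenspace feature extraction: PCA on flattened training images.

Images are flattened to pixel vectors, centered on the training mean, and
decomposed with a thin SVD — the rank-reduced route, equivalent to the
Gram-matrix trick, so the D x D pixel covariance is never materialized even
at D = 16384.  Projecting an image onto the top-K eigenvectors yields its
principal-component scores, the predictor columns consumed by the stepwise
selector.  The conventional operating point keeps the top 150 components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import LabeledImageSet, ValidationError

#: Default number of retained components for full-size (128 x 128) runs.
DEFAULT_N_COMPONENTS = 150


@dataclass
class EigenModel:
    """Fitted eigenspace: training mean, orthonormal components, eigenvalues.

    ``components`` is K x D with orthonormal rows (eigenvectors of the
    training covariance, divisor N-1) sorted by descending eigenvalue; each
    row's sign is fixed so its largest-magnitude entry is positive, making
    serialized models comparable across platforms.  ``total_variance`` is
    the trace of the full covariance, kept so explained-variance fractions
    refer to all the variance, not just the retained part.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def dim(self) -> int:
        return self.components.shape[1]


@dataclass
class FeatureMatrix:
    """N x K principal-component scores plus the component ids they came from."""

    scores: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.feature_ids = np.asarray(self.feature_ids, dtype=np.int64)
        if self.scores.ndim != 2:
            raise ValidationError(f"scores must be 2-D, got shape {self.scores.shape}")
        if self.scores.shape[1] != len(self.feature_ids):
            raise ValidationError("one feature id per score column required")

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]

    def restrict(self, feature_ids: list[int] | np.ndarray) -> "FeatureMatrix":
        """Keep only the named component columns, in the given order."""
        wanted = np.asarray(feature_ids, dtype=np.int64)
        pos = {int(f): i for i, f in enumerate(self.feature_ids)}
        try:
            cols = [pos[int(f)] for f in wanted]
        except KeyError as exc:
            raise ValidationError(f"feature id {exc} not present") from None
        return FeatureMatrix(self.scores[:, cols], wanted)


def _as_matrix(images) -> np.ndarray:
    if isinstance(images, LabeledImageSet):
        return images.flatten()
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 3:
        return arr.reshape(len(arr), -1)
    if arr.ndim != 2:
        raise ValidationError(f"expected images or an (N, D) matrix, got {arr.shape}")
    return arr


def fit_eigenmodel(images: LabeledImageSet | np.ndarray, k: int) -> EigenModel:
    """Fit the top-``k`` eigenspace of the training pixel covariance.

    Uses a thin SVD of the centered data matrix, so the cost is
    O(min(N, D)^2 * max(N, D)) and the eigenvalues carry the N-1 divisor.
    """
    data = _as_matrix(images)
    n, d = data.shape
    if n < 2:
        raise ValidationError(f"need at least 2 images to fit, got {n}")
    if not 1 <= k <= min(n - 1, d):
        raise ValidationError(
            f"k must lie in [1, min(N-1, D)] = [1, {min(n - 1, d)}], got {k}"
        )
    mean = data.mean(axis=0)
    centered = data - mean
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = singular**2 / (n - 1)
    components = vt[:k]
    # sign convention: largest-|entry| positive in every row
    anchor = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(k), anchor])
    signs[signs == 0] = 1.0
    components = components * signs[:, None]
    return EigenModel(
        mean=mean,
        components=components,
        eigenvalues=eigenvalues[:k],
        total_variance=float(eigenvalues.sum()),
    )


def project(model: EigenModel, images: LabeledImageSet | np.ndarray) -> FeatureMatrix:
    """Principal-component scores: (flattened image - mean) @ components.T."""
    data = _as_matrix(images)
    if data.shape[1] != model.dim:
        raise ValidationError(
            f"image dimension {data.shape[1]} does not match model dim {model.dim}"
        )
    scores = (data - model.mean) @ model.components.T
    return FeatureMatrix(scores, np.arange(model.n_components))


def explained_variance(model: EigenModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-component variance fractions and their cumulative sum.

    Fractions are relative to the *total* training variance, so the
    cumulative sequence is non-decreasing and bounded by 1.
    """
    if model.total_variance <= 0:
        fractions = np.zeros(model.n_components)
    else:
        fractions = model.eigenvalues / model.total_variance
    return fractions, np.cumsum(fractions)


def save_eigenmodel(model: EigenModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "mean.npy", model.mean)
    np.save(directory / "components.npy", model.components)
    np.save(directory / "eigenvalues.npy", model.eigenvalues)
    meta = {
        "dim": int(model.dim),
        "n_components": int(model.n_components),
        "total_variance": model.total_variance,
        "covariance_divisor": "n-1",
        "sign_convention": "largest-abs-entry-positive",
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_eigenmodel(directory: str | Path) -> EigenModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    return EigenModel(
        mean=np.load(directory / "mean.npy"),
        components=np.load(directory / "components.npy"),
        eigenvalues=np.load(directory / "eigenvalues.npy"),
        total_variance=float(meta["total_variance"]),
    )
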
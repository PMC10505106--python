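"""Core voxel-field containers for the evidential segmentation pipeline.

All fields use a channel-first layout: the class axis comes before the
spatial axes, so an array of shape ``(K, H, W)`` (2D) or ``(K, H, W, D)``
(3D) holds one value per class per voxel.  Spatial indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvidenceField",
    "DirichletField",
    "LabelField",
    "UncertaintyMap",
]


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim < 2:
        raise ValueError(
            "field arrays must be channel-first with at least one spatial "
            f"axis, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class EvidenceField:
    """Per-voxel, per-class non-negative evidence emitted by a network head.

    Evidence ``e_ij >= 0`` measures the support collected from the input for
    assigning voxel ``i`` to class ``j``.  Zero evidence everywhere encodes
    total ignorance (a uniform Dirichlet once mapped to ``alpha``).
    """

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.values)
        if not np.isfinite(arr).all():
            n_bad = int(np.count_nonzero(~np.isfinite(arr).all(axis=0)))
            raise ValueError(f"evidence contains non-finite values at {n_bad} voxel(s)")
        if (arr < 0).any():
            n_bad = int(np.count_nonzero((arr < 0).any(axis=0)))
            raise ValueError(f"evidence is negative at {n_bad} voxel(s)")
        if arr.shape[0] < 2:
            raise ValueError(f"need at least 2 classes, got K={arr.shape[0]}")
        object.__setattr__(self, "values", arr)

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape[1:]


@dataclass(frozen=True)
class DirichletField:
    """Per-voxel Dirichlet parameters ``alpha_ij >= 1``.

    The Dirichlet strength ``S_i = sum_j alpha_ij`` measures how much total
    evidence backs the opinion at voxel ``i``; large ``S_i`` means a
    confident (low-variance) opinion.
    """

    alpha: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.alpha)
        if not np.isfinite(arr).all():
            raise ValueError("alpha contains non-finite values")
        # allow a hair below 1 for round-off from upstream transforms
        if (arr < 1.0 - 1e-9).any():
            n_bad = int(np.count_nonzero((arr < 1.0 - 1e-9).any(axis=0)))
            raise ValueError(f"alpha < 1 at {n_bad} voxel(s)")
        if arr.shape[0] < 2:
            raise ValueError(f"need at least 2 classes, got K={arr.shape[0]}")
        object.__setattr__(self, "alpha", arr)

    @property
    def n_classes(self) -> int:
        return self.alpha.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.alpha.shape[1:]

    @property
    def strength(self) -> np.ndarray:
        """Dirichlet strength ``S_i``, one value per voxel."""
        return self.alpha.sum(axis=0)


@dataclass(frozen=True)
class LabelField:
    """One-hot ground-truth labels ``y_ij``.

    ``mode='exclusive'`` means classic multi-class labels: exactly one class
    per voxel.  ``mode='overlapping'`` holds independent binary channels
    (e.g. nested anatomical regions), where a voxel may belong to several
    channels at once.
    """

    onehot: np.ndarray
    mode: str = "exclusive"

    def __post_init__(self):
        arr = np.asarray(self.onehot)
        if arr.ndim < 2:
            raise ValueError(f"labels must be channel-first, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("label entries must be 0 or 1")
        if self.mode not in ("exclusive", "overlapping"):
            raise ValueError(f"unknown label mode {self.mode!r}")
        arr = arr.astype(np.float64)
        if self.mode == "exclusive":
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1.0):
                n_bad = int(np.count_nonzero(~np.isclose(sums, 1.0)))
                raise ValueError(
                    f"exclusive labels need exactly one class per voxel; "
                    f"{n_bad} voxel(s) violate this"
                )
        object.__setattr__(self, "onehot", arr)

    @property
    def n_classes(self) -> int:
        return self.onehot.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.onehot.shape[1:]

    @classmethod
    def from_class_indices(cls, indices: np.ndarray, n_classes: int) -> "LabelField":
        """Build an exclusive one-hot field from an integer class map."""
        indices = np.asarray(indices)
        if indices.min() < 0 or indices.max() >= n_classes:
            raise ValueError("class indices out of range")
        onehot = np.zeros((n_classes,) + indices.shape)
        for k in range(n_classes):
            onehot[k] = indices == k
        return cls(onehot=onehot, mode="exclusive")


@dataclass(frozen=True)
class UncertaintyMap:
    """Per-voxel scalar uncertainty in [0, 1] (normalized predictive entropy)."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
            raise ValueError("uncertainty values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(arr, 0.0, 1.0))

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape
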
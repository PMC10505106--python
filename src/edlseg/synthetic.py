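"""Deterministic segmentation phantoms with nested tumor-like regions.

A phantom mimics a multi-modality brain scan at desk scale: an ellipsoidal
"brain" containing three nested irregular blobs — a whole lesion, a core
inside it and an enhancing focus inside the core (the ET ⊆ TC ⊆ WT nesting
of glioma subregions).  Each image channel weights the regions differently,
the way MRI modalities weight tissue contrasts differently, and carries
additive Gaussian noise everywhere (so the extracranial background is noisy
rather than exactly zero, as in real scans after normalization).

Three corruption operators emulate low-quality acquisition: Gaussian blur
(sigma on voxels), additive Gaussian noise (variance on the normalized
intensity scale — a strong corruption), and gamma correction applied to
min-max-scaled intensities.  Corruptions act on images only; labels and
brain masks are never touched.

Everything is a pure function of its parameters and seed, and each phantom
records the full recipe needed to regenerate it bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fields import LabelField

__all__ = [
    "Phantom",
    "CorruptionSpec",
    "generate_phantom",
    "corrupt_blur",
    "corrupt_noise",
    "corrupt_gamma",
    "apply_corruption",
    "brain_from_image",
    "make_dataset",
    "load_manifest",
    "phantoms_from_manifest",
]


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray  # (C, *spatial) float
    labels: LabelField
    brain: np.ndarray  # (*spatial) bool
    recipe: dict

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.image.astype(np.float64)).tobytes())
        h.update(np.ascontiguousarray(self.labels.onehot).tobytes())
        h.update(np.ascontiguousarray(self.brain.astype(np.uint8)).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class CorruptionSpec:
    kind: str  # 'blur' | 'noise' | 'gamma'
    parameter: float  # sigma, variance, or gamma
    seed: int = 0  # used by 'noise' only

    def __post_init__(self):
        if self.kind not in ("blur", "noise", "gamma"):
            raise ValueError(f"unknown corruption kind {self.kind!r}")
        if self.parameter <= 0:
            raise ValueError("corruption parameter must be positive")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _blob(rng, shape, center, radius, roughness=0.35) -> np.ndarray:
    """Irregular blob: ellipsoid distance field perturbed by smooth noise."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = np.zeros(shape)
    axes = radius * rng.uniform(0.8, 1.2, size=len(shape))
    for g, c, a in zip(grids, center, axes):
        dist = dist + ((g - c) / a) ** 2
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 16)
    noise = noise / max(np.abs(noise).max(), 1e-12)
    return (dist + roughness * noise) <= 1.0


# Per-channel sensitivity to (whole, core, enhancing) region membership,
# loosely mimicking how four MRI modalities weight tumor compartments.
_CHANNEL_WEIGHTS = np.array(
    [
        [0.50, 0.10, 0.10],
        [-0.30, 0.20, 0.10],
        [0.35, 0.30, 0.20],
        [0.15, -0.15, 0.50],
    ]
)


def generate_phantom(
    seed: int,
    shape: tuple = (96, 96),
    n_channels: int = 4,
    n_classes: int = 2,
    contrast: float = 1.0,
    noise_sd: float = 0.08,
    label_mode: str = "exclusive",
) -> Phantom:
    """Generate one deterministic phantom.

    ``n_classes=2`` gives background vs whole lesion; ``n_classes=4`` splits
    the lesion into rim (whole minus core), core minus enhancing, and
    enhancing focus.  ``label_mode='overlapping'`` instead emits the three
    nested binary channels directly.  ``contrast`` scales all region
    intensity offsets (0 decouples image from labels); ``noise_sd`` is the
    per-channel Gaussian noise level before normalization.
    """
    if len(shape) not in (2, 3):
        raise ValueError("phantoms are 2D or 3D")
    if n_classes not in (2, 4):
        raise ValueError("n_classes must be 2 or 4")
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("blobs cannot fit: each spatial dimension must be >= 32")
    rng = np.random.default_rng(seed)

    center = np.array(shape) / 2.0
    brain = _ellipsoid(
        shape,
        center + rng.uniform(-0.02, 0.02, len(shape)) * np.array(shape),
        0.42 * np.array(shape) * rng.uniform(0.95, 1.05, len(shape)),
    )

    brain_r = 0.42 * min(shape)
    whole_c = center + rng.uniform(-0.25, 0.25, len(shape)) * brain_r
    whole = _blob(rng, shape, whole_c, radius=rng.uniform(0.35, 0.5) * brain_r) & brain
    core_c = whole_c + rng.uniform(-0.15, 0.15, len(shape)) * brain_r * 0.3
    core = _blob(rng, shape, core_c, radius=rng.uniform(0.5, 0.7) * 0.45 * brain_r) & whole
    enh = _blob(rng, shape, core_c, radius=rng.uniform(0.4, 0.6) * 0.3 * brain_r) & core
    if whole.sum() < 20:
        raise ValueError("degenerate phantom: lesion too small; change the seed")

    regions = np.stack([whole, core, enh]).astype(np.float64)
    weights = _CHANNEL_WEIGHTS[
        np.arange(n_channels) % len(_CHANNEL_WEIGHTS)
    ] * rng.uniform(0.85, 1.15, size=(n_channels, 3))
    image = np.empty((n_channels,) + shape)
    for c in range(n_channels):
        chan = 0.45 * brain + contrast * np.tensordot(weights[c], regions, axes=1)
        chan = chan + rng.normal(0.0, noise_sd, size=shape)
        lo, hi = chan.min(), chan.max()
        image[c] = (chan - lo) / (hi - lo) if hi > lo else chan * 0.0

    if label_mode == "overlapping":
        labels = LabelField(onehot=regions.astype(np.uint8), mode="overlapping")
    elif n_classes == 2:
        labels = LabelField.from_class_indices(whole.astype(int), 2)
    else:
        idx = whole.astype(int) + core.astype(int) + enh.astype(int)
        labels = LabelField.from_class_indices(idx, 4)

    recipe = {
        "seed": int(seed),
        "shape": list(shape),
        "n_channels": int(n_channels),
        "n_classes": int(n_classes),
        "contrast": float(contrast),
        "noise_sd": float(noise_sd),
        "label_mode": label_mode,
    }
    return Phantom(image=image, labels=labels, brain=brain, recipe=recipe)


def _spatial_filter(image, fn):
    image = np.asarray(image, dtype=np.float64)
    return np.stack([fn(image[c]) for c in range(image.shape[0])])


def corrupt_blur(image, sigma: float) -> np.ndarray:
    """Per-channel Gaussian smoothing with reflective boundaries."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _spatial_filter(
        image, lambda ch: ndimage.gaussian_filter(ch, sigma=sigma, mode="reflect")
    )


def corrupt_noise(image, variance: float, seed: int = 0) -> np.ndarray:
    """Additive i.i.d. zero-mean Gaussian noise of the given variance."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, np.sqrt(variance), size=image.shape)


def corrupt_gamma(image, gamma: float) -> np.ndarray:
    """Per-channel gamma correction on min-max-scaled intensities.

    Channels with zero intensity range are returned unchanged with a warning.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    image = np.asarray(image, dtype=np.float64)
    out = np.empty_like(image)
    for c in range(image.shape[0]):
        lo, hi = image[c].min(), image[c].max()
        if hi <= lo:
            warnings.warn(f"channel {c} is constant; gamma correction skipped")
            out[c] = image[c]
        else:
            out[c] = ((image[c] - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
    return out


def apply_corruption(image, spec: CorruptionSpec) -> np.ndarray:
    if spec.kind == "blur":
        return corrupt_blur(image, spec.parameter)
    if spec.kind == "noise":
        return corrupt_noise(image, spec.parameter, spec.seed)
    return corrupt_gamma(image, spec.parameter)


def brain_from_image(image, tol: float = 0.0) -> np.ndarray:
    """Fallback brain mask: voxels with above-threshold intensity in any channel."""
    image = np.asarray(image)
    return (np.abs(image) > tol).any(axis=0)


# ---------------------------------------------------------------------------
# dataset manifests


def make_dataset(
    seeds,
    split=(0.6, 0.2, 0.2),
    corruption: CorruptionSpec | None = None,
    out_dir: str | Path | None = None,
    **phantom_kwargs,
) -> dict:
    """Build a phantom collection split into train/val/test.

    The split fractions apply to the seed list in order.  A corruption spec,
    if given, is applied to the *test* split only — the clean-train /
    corrupted-test robustness design.  When ``out_dir`` is given, volumes
    are written as NIfTI and the manifest as JSON; either way the manifest
    (recipes + checksums) suffices to regenerate every case bit-exactly.
    """
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be unique across splits")
    if len(split) != 3 or abs(sum(split) - 1.0) > 1e-9 or min(split) < 0:
        raise ValueError("split must be three non-negative fractions summing to 1")
    n = len(seeds)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    split_of = (
        ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    )
    cases = []
    for seed, part in zip(seeds, split_of):
        phantom = generate_phantom(seed, **phantom_kwargs)
        corrupted = part == "test" and corruption is not None
        if corrupted:
            phantom = Phantom(
                image=apply_corruption(phantom.image, corruption),
                labels=phantom.labels,
                brain=phantom.brain,
                recipe=phantom.recipe,
            )
        case = {
            "seed": seed,
            "split": part,
            "recipe": phantom.recipe,
            "corrupted": corrupted,
            "checksum": phantom.checksum(),
        }
        if out_dir is not None:
            from . import io as nio

            case_dir = Path(out_dir) / f"case_{seed:05d}"
            case_dir.mkdir(parents=True, exist_ok=True)
            nio.save_nifti(phantom.image, case_dir / "image.nii.gz")
            nio.save_nifti(
                phantom.labels.onehot.argmax(axis=0).astype(np.int16)
                if phantom.labels.mode == "exclusive"
                else phantom.labels.onehot.astype(np.int16),
                case_dir / "labels.nii.gz",
            )
            nio.save_nifti(phantom.brain.astype(np.uint8), case_dir / "brain.nii.gz")
            case["files"] = {
                "image": str(case_dir / "image.nii.gz"),
                "labels": str(case_dir / "labels.nii.gz"),
                "brain": str(case_dir / "brain.nii.gz"),
            }
        cases.append(case)
    manifest = {
        "split": list(split),
        "corruption": None
        if corruption is None
        else {"kind": corruption.kind, "parameter": corruption.parameter,
              "seed": corruption.seed},
        "cases": cases,
    }
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def phantoms_from_manifest(manifest: dict, split: str | None = None, verify: bool = True):
    """Regenerate the phantoms recorded in a manifest (optionally one split).

    Regeneration is from the recipes, so it works without the NIfTI files;
    with ``verify`` each regenerated case must match its recorded checksum.
    """
    corruption = manifest.get("corruption")
    spec = (
        CorruptionSpec(corruption["kind"], corruption["parameter"], corruption["seed"])
        if corruption
        else None
    )
    out = []
    for case in manifest["cases"]:
        if split is not None and case["split"] != split:
            continue
        phantom = generate_phantom(**case["recipe"])
        if case["corrupted"] and spec is not None:
            phantom = Phantom(
                image=apply_corruption(phantom.image, spec),
                labels=phantom.labels,
                brain=phantom.brain,
                recipe=phantom.recipe,
            )
        if verify and phantom.checksum() != case["checksum"]:
            raise ValueError(f"checksum mismatch for seed {case['seed']}")
        out.append((case, phantom))
    return out
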
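"""Dirichlet-evidence transforms: evidence -> alpha -> probabilities -> entropy.

A network head emits non-negative evidence ``e_ij`` per voxel and class.
Under Subjective Logic the evidence parameterizes a Dirichlet distribution
over the per-voxel class probabilities; its mean gives the predicted
probabilities and its spread quantifies how much the prediction should be
trusted.  Two evidence-to-alpha maps are supported:

* ``squared`` (default): ``alpha = (e + 1)**2`` — lets the head reach large
  Dirichlet parameters (confident opinions) without extreme activations.
* ``linear``: ``alpha = e + 1`` — the classic parameterization.

Entropies use the natural logarithm throughout; the normalized predictive
entropy divides by ``log K`` so the base cancels and the result lies in
[0, 1].
"""

from __future__ import annotations

import numpy as np

from .fields import DirichletField, EvidenceField, UncertaintyMap

__all__ = [
    "evidence_to_dirichlet",
    "alpha_from_evidence",
    "expected_probabilities",
    "predictive_entropy",
    "normalized_predictive_entropy",
    "hard_labels",
]

_EPS = 1e-12


def alpha_from_evidence(e, parameterization: str = "squared"):
    """Array-level evidence-to-alpha map (autograd-safe; no validation).

    Works on plain arrays or traced arrays; used internally by the training
    loop.  Prefer :func:`evidence_to_dirichlet` for validated field objects.
    """
    if parameterization == "squared":
        return (e + 1.0) ** 2
    if parameterization == "linear":
        return e + 1.0
    raise ValueError(f"unknown parameterization {parameterization!r}")


def evidence_to_dirichlet(
    e: EvidenceField, parameterization: str = "squared"
) -> DirichletField:
    """Map an evidence field to its Dirichlet field.

    Squared mode: ``alpha_ij = (e_ij + 1)**2``; linear mode:
    ``alpha_ij = e_ij + 1``.  Either way ``alpha_ij >= 1``: each class keeps
    a minimal pseudo-count of one, so zero evidence yields the uniform
    Dirichlet (total ignorance).
    """
    if not isinstance(e, EvidenceField):
        e = EvidenceField(values=e)
    return DirichletField(alpha=alpha_from_evidence(e.values, parameterization))


def expected_probabilities(d: DirichletField) -> np.ndarray:
    """Expected class probabilities ``p_ij = alpha_ij / S_i`` (Dirichlet mean)."""
    if not isinstance(d, DirichletField):
        d = DirichletField(alpha=d)
    return d.alpha / d.strength


def _check_probabilities(p: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim < 2:
        raise ValueError("probabilities must be channel-first")
    if (p < -tol).any() or (p > 1 + tol).any():
        raise ValueError("probabilities must lie in [0, 1]")
    sums = p.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=tol):
        n_bad = int(np.count_nonzero(~np.isclose(sums, 1.0, atol=tol)))
        raise ValueError(f"probability rows do not sum to 1 at {n_bad} voxel(s)")
    return p


def predictive_entropy(p: np.ndarray) -> np.ndarray:
    """Per-voxel predictive entropy ``-sum_j p_ij log p_ij`` (natural log).

    Terms with ``p_ij == 0`` contribute exactly 0 (masked, not epsilon-fudged);
    an epsilon only guards values merely close to 0 against log(0).
    """
    p = _check_probabilities(p)
    logp = np.log(np.maximum(p, _EPS))
    terms = np.where(p > 0, -p * logp, 0.0)
    return terms.sum(axis=0)


def normalized_predictive_entropy(p: np.ndarray, n_classes: int | None = None) -> UncertaintyMap:
    """Normalized predictive entropy: entropy / log(K), clipped to [0, 1].

    1 means a uniform (maximally uncertain) prediction, 0 a one-hot
    (absolutely confident) one.
    """
    p = _check_probabilities(p)
    k = p.shape[0] if n_classes is None else int(n_classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    u = predictive_entropy(p) / np.log(k)
    return UncertaintyMap(values=np.clip(u, 0.0, 1.0))


def hard_labels(p: np.ndarray) -> np.ndarray:
    """Argmax class per voxel; ties resolve to the lowest class index."""
    p = _check_probabilities(p)
    return p.argmax(axis=0)
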
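"""Patch partitioning, per-patch encoding, and fixed mean-logit aggregation.

The architecture implemented here is a deliberately constrained special case
of multiple-instance learning: a square grayscale image is tiled into
``P x P`` non-overlapping ``p x p`` patches, every patch is encoded
*independently* by one shared encoder into a vector of per-label logits
``z_i``, and the image-level logits are the plain arithmetic mean
``Z = (1/P^2) * sum_i z_i``, followed by an elementwise sigmoid
``y_hat = sigma(Z)``.  Because aggregation is a fixed mean (no attention, no
inter-patch communication), each patch's exact additive contribution to the
decision is ``z_i / P^2`` — the logit field *is* the explanation.

Scaled patch logits ``z_hat_i = y_hat * z_i`` (elementwise) inject a limited
amount of global context into the per-patch attribution while preserving
sign.

Conventions (shared with :mod:`patchmil.saliency` and
:mod:`patchmil.evaluation`): patch indices are row-major, 0-based, origin at
the top-left; patch ``i = r * P + c`` covers pixel rows ``[r*p, (r+1)*p)``
and columns ``[c*p, (c+1)*p)``, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "EncoderContract",
    "PatchGrid",
    "GlobalPrediction",
    "validate_image",
    "partition_image",
    "assemble_patches",
    "encode_patches",
    "aggregate",
    "scale_patch_logits",
    "forward",
    "stable_sigmoid",
]


@runtime_checkable
class EncoderContract(Protocol):
    """A shared per-patch encoder: one ``p x p`` patch -> ``C`` logits.

    Implementations must be deterministic given fixed parameters, apply the
    same parameters to every patch, and must not receive or use the patch's
    position (that restriction is the interpretability guarantee: no
    information can bypass the patch logit field).  Batched evaluation is
    allowed but must be independent of batch composition and order.
    """

    n_labels: int

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        """Map a ``(N, p, p)`` batch of patches to ``(N, C)`` logits."""
        ...


@dataclass(frozen=True)
class PatchGrid:
    """Row-major tiling of a square image into non-overlapping patches.

    ``patches`` has shape ``(P*P, p, p)``; patch ``i`` corresponds to grid
    cell ``(r, c) = divmod(i, P)``.
    """

    patches: np.ndarray
    grid_side: int
    patch_side: int

    def __post_init__(self) -> None:
        P, p = self.grid_side, self.patch_side
        if self.patches.shape != (P * P, p, p):
            raise ValueError(
                f"patches shape {self.patches.shape} inconsistent with "
                f"grid_side={P}, patch_side={p}"
            )

    @property
    def image_side(self) -> int:
        return self.grid_side * self.patch_side

    def index_to_cell(self, i: int) -> tuple[int, int]:
        """Patch index -> (row, col) grid cell, row-major."""
        return divmod(int(i), self.grid_side)


@dataclass(frozen=True)
class GlobalPrediction:
    """Image-level logits ``Z`` (mean of patch logits) and ``y_hat = sigma(Z)``."""

    global_logits: np.ndarray
    probabilities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.global_logits, dtype=np.float64)
        object.__setattr__(self, "global_logits", z)
        if self.probabilities is None:
            object.__setattr__(self, "probabilities", stable_sigmoid(z))

    @property
    def n_labels(self) -> int:
        return self.global_logits.shape[0]


def stable_sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable elementwise logistic function.

    Uses the two-branch form so that ``exp`` is only ever evaluated on
    non-positive arguments; exact for large |z| without overflow warnings.
    """
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check an array is a square 2-D grayscale image with values in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {img.shape}")
    if img.shape[0] < 1:
        raise ValueError("image side must be >= 1")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(
            f"intensities must lie in [0, 1]; got range "
            f"[{img.min():.4g}, {img.max():.4g}]"
        )
    return img


def partition_image(img: np.ndarray, patch_side: int) -> PatchGrid:
    """Tile a square image into ``P x P`` non-overlapping ``p x p`` patches.

    ``P = S / p`` must be integral; non-divisible sizes are a hard error
    (silent padding would corrupt the attribution geometry).  Patch ``i``
    covers rows ``[r*p, (r+1)*p)`` and cols ``[c*p, (c+1)*p)`` with
    ``(r, c) = divmod(i, P)``.
    """
    img = validate_image(img)
    S = img.shape[0]
    p = int(patch_side)
    if p < 1:
        raise ValueError(f"patch_side must be >= 1, got {p}")
    if S % p != 0:
        raise ValueError(
            f"image side S={S} is not divisible by patch_side p={p}; "
            "only exact tilings are supported"
        )
    P = S // p
    # (P, p, P, p) -> (P, P, p, p) -> (P*P, p, p), row-major by construction
    patches = img.reshape(P, p, P, p).transpose(0, 2, 1, 3).reshape(P * P, p, p)
    return PatchGrid(patches=np.ascontiguousarray(patches), grid_side=P, patch_side=p)


def assemble_patches(grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`partition_image`; reproduces the source bit-exactly."""
    P, p = grid.grid_side, grid.patch_side
    return (
        grid.patches.reshape(P, P, p, p).transpose(0, 2, 1, 3).reshape(P * p, P * p)
    )


def encode_patches(grid: PatchGrid, enc: EncoderContract) -> np.ndarray:
    """Apply the shared encoder to every patch; returns the ``(P^2, C)`` logit field."""
    field = np.asarray(enc(grid.patches), dtype=np.float64)
    n = grid.patches.shape[0]
    if field.ndim != 2 or field.shape[0] != n:
        raise ValueError(
            f"encoder returned shape {field.shape}, expected ({n}, C)"
        )
    C = getattr(enc, "n_labels", field.shape[1])
    if field.shape[1] != C:
        raise ValueError(
            f"encoder output length {field.shape[1]} != declared n_labels {C}"
        )
    return field


def aggregate(field: np.ndarray) -> GlobalPrediction:
    """Mean the patch logit field into image-level logits and probabilities.

    The sigmoid is applied strictly *after* averaging; averaging raw logits
    (rather than probabilities) leaves each patch's influence on the global
    logit unconstrained.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2 or field.shape[0] == 0:
        raise ValueError(f"expected a non-empty (P^2, C) field, got shape {field.shape}")
    bad = ~np.isfinite(field).all(axis=1)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite logits at patch index {idx}")
    Z = field.mean(axis=0)
    return GlobalPrediction(global_logits=Z)


def scale_patch_logits(field: np.ndarray, pred: GlobalPrediction) -> np.ndarray:
    """Scaled patch logits ``z_hat_i = y_hat * z_i`` (elementwise, row-wise broadcast)."""
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2 or field.shape[1] != pred.n_labels:
        raise ValueError(
            f"field shape {field.shape} incompatible with {pred.n_labels} labels"
        )
    return field * pred.probabilities[np.newaxis, :]


def forward(
    img: np.ndarray, enc: EncoderContract, patch_side: int
) -> tuple[GlobalPrediction, np.ndarray]:
    """Full pipeline: partition -> encode -> aggregate.

    Returns the image-level prediction and the raw patch logit field.  With
    ``patch_side`` equal to the image side this degenerates to the bare
    encoder applied to the whole image (a standard image-level classifier):
    the mean over a single patch is the identity.
    """
    grid = partition_image(img, patch_side)
    field = encode_patches(grid, enc)
    return aggregate(field), field
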
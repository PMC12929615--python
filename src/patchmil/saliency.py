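"""Per-label pixel-resolution saliency from patch logits.

A raw patch saliency map is just the patch logit field painted onto the
image grid: every pixel of patch ``i`` carries ``z_i[label]`` (or the scaled
logit ``y_hat[label] * z_i[label]``).  Positive values are evidence *for*
the label, negative values evidence *against* it, and zero means the patch
abstains.  Because the image-level logit is the mean of the patch logits,
the pixel-mean of a raw map equals the image-level logit for that label —
the map is an exact decomposition of the decision, not an approximation.

The block artifacts of the single-tiling map are reduced by shift
smoothing: for every offset ``(dy, dx)`` in ``{0, o, 2o, ..., p-o}^2`` the
image content is shifted down-right by ``(dy, dx)`` on a zero-padded canvas
large enough that nothing is clipped, the canvas is tiled and classified in
one forward pass, its block map is cropped back to the original pixel
coordinates, and the ``(p/o)^2`` aligned maps are averaged pixelwise.
Every image pixel is covered by exactly one patch in each shifted tiling
(border patches are partially zero padding), so the smoothed map is a plain
average of ``(p/o)^2`` values everywhere — in particular an
input-independent encoder yields a spatially constant smoothed map.
``o = p`` reproduces the single block map exactly; ``o = 1`` gives
pixel-level resolution at the cost of ``p^2`` forward passes.

Shift direction convention: offsets are non-negative and move content
toward the bottom-right (the top-left is zero-padded).  This makes results
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (
    EncoderContract,
    aggregate,
    scale_patch_logits,
    validate_image,
)

__all__ = [
    "SaliencyMap",
    "patch_map",
    "shifted_saliency",
    "shifted_saliency_stack",
    "render_overlay",
    "save_map",
    "load_map",
]


@dataclass(frozen=True)
class SaliencyMap:
    """Signed per-pixel attribution field for one label.

    ``source`` records whether the map came from raw or probability-scaled
    patch logits; ``offset`` is the shift stride used (``offset == p`` means
    the single-tiling block map).
    """

    values: np.ndarray
    source: str = "raw"
    offset: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"saliency map must be square 2-D, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("saliency map contains non-finite values")
        if self.source not in ("raw", "scaled"):
            raise ValueError(f"source must be 'raw' or 'scaled', got {self.source!r}")
        object.__setattr__(self, "values", v)

    @property
    def side(self) -> int:
        return self.values.shape[0]


def patch_map(
    field: np.ndarray,
    label_index: int,
    image_side: int,
    patch_side: int,
    source: str = "raw",
) -> SaliencyMap:
    """Paint one label's patch logits onto the pixel grid, block-constant.

    Pixel ``(y, x)`` holds the logit of patch ``(y // p, x // p)``; no
    interpolation is performed.
    """
    field = np.asarray(field, dtype=np.float64)
    p = int(patch_side)
    if image_side % p != 0:
        raise ValueError(f"image side {image_side} not divisible by patch side {p}")
    P = image_side // p
    if field.shape[0] != P * P:
        raise ValueError(
            f"field has {field.shape[0]} rows, expected P^2 = {P * P} for S={image_side}, p={p}"
        )
    if not (0 <= label_index < field.shape[1]):
        raise IndexError(
            f"label_index {label_index} out of range for {field.shape[1]} labels"
        )
    blocks = field[:, label_index].reshape(P, P)
    values = np.repeat(np.repeat(blocks, p, axis=0), p, axis=1)
    return SaliencyMap(values=values, source=source, offset=p)


def _shifted_block_stack(
    img: np.ndarray,
    enc: EncoderContract,
    p: int,
    dy: int,
    dx: int,
    source: str,
) -> np.ndarray:
    """One shifted tiling: pad, classify all covering patches, crop back.

    The canvas grows by one patch row/column on the shifted axes so that the
    down-right-translated content is never clipped; the crop undoes the
    translation, so border pixels take the logit of a patch that partially
    covers zero padding (the paper-style plain zero-pad convention).
    """
    S = img.shape[0]
    Hy = S + (p if dy else 0)
    Hx = S + (p if dx else 0)
    canvas = np.zeros((Hy, Hx))
    canvas[dy : dy + S, dx : dx + S] = img
    Py, Px = Hy // p, Hx // p
    # row-major tiling of the (possibly non-square) canvas
    patches = (
        canvas.reshape(Py, p, Px, p).transpose(0, 2, 1, 3).reshape(Py * Px, p, p)
    )
    field = np.asarray(enc(patches), dtype=np.float64)
    if field.shape != (Py * Px, enc.n_labels):
        raise ValueError(
            f"encoder returned shape {field.shape}, expected ({Py * Px}, {enc.n_labels})"
        )
    if source == "scaled":
        field = scale_patch_logits(field, aggregate(field))
    blocks = field.T.reshape(enc.n_labels, Py, Px)
    full = np.repeat(np.repeat(blocks, p, axis=1), p, axis=2)
    return full[:, dy : dy + S, dx : dx + S]


def shifted_saliency_stack(
    img: np.ndarray,
    enc: EncoderContract,
    patch_side: int,
    offset: int,
    source: str = "raw",
) -> np.ndarray:
    """Shift-smoothed saliency for *all* labels at once; returns ``(C, S, S)``.

    Each shift is one forward pass; for the scaled source the global
    probabilities are recomputed per shifted tiling, because scaled logits
    are defined per forward pass.
    """
    img = validate_image(img)
    S = img.shape[0]
    p = int(patch_side)
    if S % p != 0:
        raise ValueError(f"image side {S} not divisible by patch side {p}")
    o = int(offset)
    if o < 1 or o > p or p % o != 0:
        raise ValueError(f"offset o={o} must satisfy 1 <= o <= p and o | p (p={p})")
    if source not in ("raw", "scaled"):
        raise ValueError(f"source must be 'raw' or 'scaled', got {source!r}")
    n_shift = p // o
    C = enc.n_labels
    acc = np.zeros((C, S, S))
    for dy in range(0, p, o):
        for dx in range(0, p, o):
            acc += _shifted_block_stack(img, enc, p, dy, dx, source)
    acc /= n_shift * n_shift
    return acc


def shifted_saliency(
    img: np.ndarray,
    enc: EncoderContract,
    patch_side: int,
    offset: int,
    label_index: int,
    source: str = "raw",
) -> SaliencyMap:
    """Shift-smoothed saliency map for a single label."""
    if not (0 <= label_index < enc.n_labels):
        raise IndexError(
            f"label_index {label_index} out of range for {enc.n_labels} labels"
        )
    stack = shifted_saliency_stack(img, enc, patch_side, offset, source=source)
    return SaliencyMap(values=stack[label_index], source=source, offset=int(offset))


def render_overlay(
    img: np.ndarray,
    smap: SaliencyMap | np.ndarray,
    out_path: str | Path,
    max_alpha: float = 0.6,
) -> np.ndarray:
    """Blend a diverging-color saliency overlay onto the grayscale image.

    Positive attribution is tinted red, negative blue; the color scale is
    symmetric about zero and anchored at the map's max |value| so zero stays
    visually neutral (near-transparent).  Writes an 8-bit RGB PNG and
    returns the rendered array.
    """
    from PIL import Image

    img = validate_image(img)
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap)
    if values.shape != img.shape:
        raise ValueError(f"map shape {values.shape} != image shape {img.shape}")
    vmax = np.abs(values).max()
    norm = values / vmax if vmax > 0 else np.zeros_like(values)
    # diverging tint: red for +, blue for -, alpha proportional to |value|
    color = np.zeros(img.shape + (3,))
    color[..., 0] = np.where(norm > 0, 1.0, 1.0 + norm)  # red channel
    color[..., 1] = 1.0 - np.abs(norm)                   # green fades out
    color[..., 2] = np.where(norm < 0, 1.0, 1.0 - norm)  # blue channel
    alpha = max_alpha * np.abs(norm)
    base = np.repeat(img[..., None], 3, axis=2)
    rgb = (1.0 - alpha[..., None]) * base + alpha[..., None] * color
    arr = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    out_path = Path(out_path)
    try:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(arr).save(out_path, format="PNG")
    except OSError as exc:
        raise OSError(f"cannot write overlay to {out_path}: {exc}") from exc
    return arr


def save_map(smap: SaliencyMap, path: str | Path) -> None:
    """Serialize a saliency map as a portable .npz (values + metadata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        values=smap.values,
        source=np.array(smap.source),
        offset=np.array(-1 if smap.offset is None else smap.offset),
    )


def load_map(path: str | Path) -> SaliencyMap:
    with np.load(Path(path).with_suffix(".npz")) as data:
        offset = int(data["offset"])
        return SaliencyMap(
            values=data["values"],
            source=str(data["source"]),
            offset=None if offset < 0 else offset,
        )
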
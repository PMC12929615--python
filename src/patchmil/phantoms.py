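"""Synthetic chest-phantom images with exact lesion masks.

The generator emulates the structure of a weakly labeled radiograph
collection: a smooth anatomy-like background (bright elliptical "thorax"
over a dark field, plus additive Gaussian noise), and per-label localized
lesions — bright disks (focal opacities), bright rotated bars (line-like
devices), and dark rotated ellipses (lucencies) — whose presence drives the
binary labels.  Every lesion's exact pixel support is recorded as a
ground-truth mask, so localization metrics have an unambiguous reference.

An optional *shortcut* mode stamps a small bright square marker in one
image corner with configurable correlation to one label, mimicking the
laterality-marker confound by which classifiers have been shown to cheat:
with correlation 1 the marker is a perfect proxy for the label and a model
may learn it instead of the lesion.

Counterfactual pairs (identical background and noise, lesions toggled) are
available for oracle tests: the absolute image difference is a saliency map
whose argmax is inside the lesion by construction, giving an exact hit-rate
ceiling; the mean mask area fraction gives the chance floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "LesionSpec",
    "ShortcutSpec",
    "PhantomSpec",
    "make_phantom",
    "make_phantom_pair",
    "inject_shortcut",
    "sample_phantoms",
    "make_dataset",
]


@dataclass(frozen=True)
class LesionSpec:
    """One label's lesion family: shape, size range, contrast, multiplicity."""

    shape: str = "disk"  # disk | ellipse | bar
    radius_range: tuple[float, float] = (12.0, 20.0)
    contrast: float = 0.3  # additive intensity delta in [-0.5, 0.5]
    count_range: tuple[int, int] = (1, 1)
    prevalence: float = 0.35

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse", "bar"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if not (-0.5 <= self.contrast <= 0.5):
            raise ValueError("contrast must lie in [-0.5, 0.5]")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class ShortcutSpec:
    """Corner-marker confound: a bright square correlated with one label."""

    corner: str = "top_left"  # top_left | top_right | bottom_left | bottom_right
    size: int = 8
    intensity: float = 0.95
    label_index: int = 0
    correlation: float = 1.0  # rho: P(marker | label=1); P(marker | label=0) = 1-rho
    margin: int = 4

    def __post_init__(self) -> None:
        if self.corner not in ("top_left", "top_right", "bottom_left", "bottom_right"):
            raise ValueError(f"unknown corner {self.corner!r}")
        if not (0.0 <= self.correlation <= 1.0):
            raise ValueError("correlation must lie in [0, 1]")


def _default_lesions() -> tuple[LesionSpec, ...]:
    return (
        LesionSpec("disk", (12.0, 20.0), 0.28, (1, 1), 0.35),
        LesionSpec("bar", (16.0, 26.0), 0.30, (1, 1), 0.35),
        LesionSpec("ellipse", (13.0, 19.0), -0.30, (1, 1), 0.35),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    Defaults give a 128 px image tiled 8x8 by 16 px patches, three labels
    with ~0.35 prevalence each and strong lesion contrast against the
    sigma = 0.03 background noise; mean lesion area is a few percent of the
    image, so pointing at random hits only rarely.
    """

    image_side: int = 128
    label_names: tuple[str, ...] = ("focal_opacity", "linear_device", "lucency")
    lesions: tuple[LesionSpec, ...] = field(default_factory=_default_lesions)
    noise_sigma: float = 0.03
    shortcut: ShortcutSpec | None = None

    def __post_init__(self) -> None:
        if len(self.lesions) != len(self.label_names):
            raise ValueError("one LesionSpec per label required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for les in self.lesions:
            if les.radius_range[1] >= self.image_side / 2:
                raise ValueError(
                    f"lesion radius {les.radius_range[1]} cannot fit in an "
                    f"image of side {self.image_side}"
                )
        if self.shortcut is not None:
            need = self.shortcut.size + self.shortcut.margin
            if need > self.image_side:
                raise ValueError("shortcut marker exceeds image bounds")

    @property
    def n_labels(self) -> int:
        return len(self.label_names)


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth thorax-like ellipse gradient plus Gaussian noise, in [0, 1]."""
    S = spec.image_side
    yy, xx = np.mgrid[0:S, 0:S]
    cy = cx = (S - 1) / 2.0
    # soft-edged bright body ellipse over a dark field
    d2 = ((yy - cy) / (0.46 * S)) ** 2 + ((xx - cx) / (0.38 * S)) ** 2
    base = 0.12 + 0.52 / (1.0 + np.exp(12.0 * (d2 - 1.0)))
    # gentle vertical gradient (tube-heel-like intensity falloff)
    base += 0.05 * (yy / S - 0.5)
    img = base + rng.normal(0.0, spec.noise_sigma, size=(S, S))
    return np.clip(img, 0.02, 0.98)


def _lesion_mask(
    shape: str, S: int, cy: float, cx: float, r: float, theta: float, aspect: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:S, 0:S]
    u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    if shape == "disk":
        return (u * u + v * v) <= r * r
    if shape == "ellipse":
        b = aspect * r
        return (u / r) ** 2 + (v / b) ** 2 <= 1.0
    # bar: half-length r, fixed half-thickness 4 px
    return (np.abs(u) <= r) & (np.abs(v) <= 4.0)


def _plan_lesions(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[list[dict]]]:
    """Draw labels and lesion geometry.

    Lesions are placed by rejection sampling so that masks of different
    lesions never overlap: overlapping opposite-contrast lesions could
    cancel pixelwise, which would break the mask-fidelity guarantee that
    every mask pixel differs from its lesion-free counterfactual.
    """
    S = spec.image_side
    labels = np.zeros(spec.n_labels, dtype=np.int64)
    plans: list[list[dict]] = []
    occupied = np.zeros((S, S), dtype=bool)
    for k, les in enumerate(spec.lesions):
        present = rng.random() < les.prevalence
        labels[k] = int(present)
        lesions_k: list[dict] = []
        if present:
            count = int(rng.integers(les.count_range[0], les.count_range[1] + 1))
            for _ in range(count):
                for _attempt in range(100):
                    r = float(rng.uniform(*les.radius_range))
                    margin = r + 2.0
                    cy = float(rng.uniform(margin, S - 1 - margin))
                    cx = float(rng.uniform(margin, S - 1 - margin))
                    theta = float(rng.uniform(0.0, np.pi))
                    aspect = float(rng.uniform(0.65, 0.9))
                    mask = _lesion_mask(les.shape, S, cy, cx, r, theta, aspect)
                    if not (mask & occupied).any():
                        occupied |= mask
                        lesions_k.append(
                            {"shape": les.shape, "cy": cy, "cx": cx, "r": r,
                             "theta": theta, "aspect": aspect,
                             "contrast": les.contrast}
                        )
                        break
                else:
                    raise RuntimeError(
                        "could not place a non-overlapping lesion in 100 tries; "
                        "lesion sizes are too large for the image"
                    )
        plans.append(lesions_k)
    return labels, plans


def _composite(
    spec: PhantomSpec,
    background: np.ndarray,
    plans: list[list[dict]],
    with_lesions: bool = True,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    img = background.copy()
    masks: dict[int, np.ndarray] = {}
    S = spec.image_side
    for k, lesions_k in enumerate(plans):
        if not lesions_k:
            continue
        union = np.zeros((S, S), dtype=bool)
        for les in lesions_k:
            m = _lesion_mask(
                les["shape"], S, les["cy"], les["cx"], les["r"], les["theta"],
                les["aspect"],
            )
            union |= m
            if with_lesions:
                img[m] += les["contrast"]
        masks[k] = union.astype(np.uint8)
    return np.clip(img, 0.0, 1.0), masks


def make_phantom(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], dict]:
    """Generate one phantom: image, label vector, per-positive-label masks, metadata.

    Labels are drawn Bernoulli(prevalence) independently; each present label
    places its lesion(s) at uniform random valid positions and records the
    exact rasterized mask.  Deterministic given the generator state.
    """
    background = _background(spec, rng)
    labels, plans = _plan_lesions(spec, rng)
    img, masks = _composite(spec, background, plans, with_lesions=True)
    if spec.shortcut is not None:
        img = inject_shortcut(img, labels, spec, rng)
    meta = {"lesions": plans, "labels": labels.tolist()}
    return img, labels, masks, meta


def make_phantom_pair(
    spec: PhantomSpec, seed: int, label_index: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Counterfactual pair from one RNG substream: lesions toggled off.

    Both images share background, noise and geometry draws; only the lesion
    compositing differs.  With ``label_index`` given, only that label's
    lesions are removed in the counterfactual (the per-label attribution
    oracle); otherwise all lesions are removed.  Returns
    ``(with, without, labels, masks)``.
    """
    spec_plain = PhantomSpec(
        image_side=spec.image_side,
        label_names=spec.label_names,
        lesions=spec.lesions,
        noise_sigma=spec.noise_sigma,
        shortcut=None,
    )
    rng = np.random.default_rng(seed)
    background = _background(spec_plain, rng)
    labels, plans = _plan_lesions(spec_plain, rng)
    with_les, masks = _composite(spec_plain, background, plans, with_lesions=True)
    if label_index is None:
        reduced = [[] for _ in plans]
    else:
        reduced = [lesions_k if k != label_index else []
                   for k, lesions_k in enumerate(plans)]
    without_les, _ = _composite(spec_plain, background, reduced, with_lesions=True)
    return with_les, without_les, labels, masks


def _corner_slices(spec: ShortcutSpec, S: int) -> tuple[slice, slice]:
    m, s = spec.margin, spec.size
    rows = slice(m, m + s) if spec.corner.startswith("top") else slice(S - m - s, S - m)
    cols = slice(m, m + s) if spec.corner.endswith("left") else slice(S - m - s, S - m)
    return rows, cols


def inject_shortcut(
    img: np.ndarray,
    labels: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stamp the corner marker with probability rho given label=1 (1-rho given 0).

    Marker pixels are set to the configured intensity exactly.  With
    rho = 1 the marker is a perfect proxy for the correlated label; with
    rho = 0.5 it is independent of it.
    """
    sc = spec.shortcut
    if sc is None:
        raise ValueError("shortcut mode is off in this spec")
    label = int(labels[sc.label_index])
    p_marker = sc.correlation if label == 1 else 1.0 - sc.correlation
    if rng.random() >= p_marker:
        return img
    out = img.copy()
    rows, cols = _corner_slices(sc, spec.image_side)
    out[rows, cols] = sc.intensity
    return out


def sample_phantoms(
    spec: PhantomSpec, n: int, seed: int, with_masks: bool = True
) -> tuple[np.ndarray, np.ndarray, list[dict[int, np.ndarray]]]:
    """Generate ``n`` phantoms in memory: images (n,S,S), labels (n,C), masks.

    ``masks[i]`` maps label index -> uint8 mask for image i's positive
    labels (empty dict entries are omitted); pass ``with_masks=False`` to
    drop them and save memory for training-only cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    S = spec.image_side
    images = np.empty((n, S, S))
    labels = np.empty((n, spec.n_labels), dtype=np.int64)
    masks: list[dict[int, np.ndarray]] = []
    for i in range(n):
        img, lab, mk, _ = make_phantom(spec, rng)
        images[i] = img
        labels[i] = lab
        masks.append(mk if with_masks else {})
    return images, labels, masks


def make_dataset(
    spec: PhantomSpec,
    n: int,
    out_dir: str | Path,
    seed: int,
    splits: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> dict:
    """Write a file-backed cohort: PNG images, label CSV, masks, split manifest.

    Produces ``images/<id>.png`` (8-bit grayscale), ``labels.csv`` (columns:
    path, then label names), per-positive-case masks under ``masks/`` in
    both PNG (0/255) and run-length JSON form, and ``splits.json`` with
    disjoint train/val/test ids.  Byte-identical on regeneration with the
    same seed.
    """
    from PIL import Image

    from .io import mask_to_rle, write_mask_png

    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc

    images, labels, masks = sample_phantoms(spec, n, seed)
    rows = []
    for i in range(n):
        img_id = f"img_{i:05d}"
        arr8 = np.clip(np.round(images[i] * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(out_dir / "images" / f"{img_id}.png")
        rows.append([f"images/{img_id}.png"] + labels[i].tolist())
        for k, mask in masks[i].items():
            name = f"{img_id}_{spec.label_names[k]}"
            write_mask_png(mask, out_dir / "masks" / f"{name}.png")
            (out_dir / "masks" / f"{name}.json").write_text(
                json.dumps(mask_to_rle(mask))
            )
    import pandas as pd

    table = pd.DataFrame(rows, columns=["path"] + list(spec.label_names))
    table.to_csv(out_dir / "labels.csv", index=False)

    n_train = int(round(splits[0] * n))
    n_val = int(round(splits[1] * n))
    ids = [f"img_{i:05d}" for i in range(n)]
    split_map = {
        "train": ids[:n_train],
        "val": ids[n_train : n_train + n_val],
        "test": ids[n_train + n_val :],
    }
    (out_dir / "splits.json").write_text(json.dumps(split_map, indent=2))
    manifest = {
        "n": n,
        "seed": seed,
        "splits": splits,
        "spec": _spec_to_dict(spec),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    """Inverse of the manifest serialization (lossless round-trip)."""
    lesions = tuple(
        LesionSpec(
            shape=les["shape"],
            radius_range=tuple(les["radius_range"]),
            contrast=les["contrast"],
            count_range=tuple(les["count_range"]),
            prevalence=les["prevalence"],
        )
        for les in d["lesions"]
    )
    shortcut = d.get("shortcut")
    return PhantomSpec(
        image_side=d["image_side"],
        label_names=tuple(d["label_names"]),
        lesions=lesions,
        noise_sigma=d["noise_sigma"],
        shortcut=ShortcutSpec(**shortcut) if shortcut else None,
    )
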
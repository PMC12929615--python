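"""File formats: label tables, binary-mask codecs, configs, manifests.

Label tables are CheXpert-style CSVs — one row per image, a ``path`` column
followed by one binary column per label.  Labels arrive pre-binarized;
anything that is not exactly 0 or 1 is a schema error (uncertainty-label
remapping happens upstream of this package and is deliberately not
guessed).

Binary masks travel in two equivalent codecs, exercised cross-wise by the
tests:

* 8-bit grayscale PNG with values {0, 255};
* run-length JSON: ``{"size": [S, S], "counts": [...]}`` where ``counts``
  are run lengths of the column-major (Fortran-order) flattened mask,
  alternating zero-runs and one-runs and always starting with a zero-run
  (``0`` first when the mask's first pixel is 1).  An empty S x S mask is
  ``[S*S]``; a full one is ``[0, S*S]``.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_label_table",
    "write_label_table",
    "mask_to_rle",
    "rle_to_mask",
    "write_mask_png",
    "read_mask_png",
    "save_config",
    "load_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """Malformed tabular input (wrong columns, non-binary labels, missing cells)."""


def read_label_table(
    path: str | Path, expected_labels: list[str] | None = None
) -> pd.DataFrame:
    """Read and validate a label CSV: ``path`` column + binary label columns."""
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse label table {path}: {exc}") from exc
    if table.columns.size == 0 or table.columns[0] != "path":
        raise SchemaError(f"{path}: first column must be 'path', got {list(table.columns)[:3]}")
    label_cols = list(table.columns[1:])
    if not label_cols:
        raise SchemaError(f"{path}: no label columns found")
    if expected_labels is not None:
        unknown = sorted(set(label_cols) - set(expected_labels))
        missing = sorted(set(expected_labels) - set(label_cols))
        if unknown or missing:
            raise SchemaError(
                f"{path}: unknown columns {unknown}, missing columns {missing}"
            )
    out = table.copy()
    for col in label_cols:
        for row_idx, value in enumerate(table[col]):
            if value not in ("0", "1"):
                raise SchemaError(
                    f"{path}: row {row_idx}, column {col!r}: "
                    f"expected binary 0/1, got {value!r}"
                )
        out[col] = table[col].astype(np.int64)
    for row_idx, value in enumerate(table["path"]):
        if not value:
            raise SchemaError(f"{path}: row {row_idx}: empty path")
    return out


def write_label_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a label table in canonical form (no index, plain integers)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def mask_to_rle(mask: np.ndarray) -> dict:
    """Encode a binary mask as column-major run lengths, zero-run first."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    flat = mask.astype(np.uint8).flatten(order="F")
    counts: list[int] = []
    if flat.size:
        change = np.flatnonzero(np.diff(flat)) + 1
        bounds = np.concatenate(([0], change, [flat.size]))
        runs = np.diff(bounds).tolist()
        if flat[0] == 1:  # convention: always start with a (possibly empty) zero-run
            runs = [0] + runs
        counts = [int(r) for r in runs]
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    """Decode the run-length JSON dialect back to a uint8 mask."""
    h, w = rle["size"]
    counts = list(rle["counts"])
    total = sum(counts)
    if total != h * w:
        raise ValueError(f"RLE counts sum to {total}, expected {h * w}")
    flat = np.zeros(h * w, dtype=np.uint8)
    pos, val = 0, 0
    for run in counts:
        if run:
            flat[pos : pos + run] = val
        pos += run
        val ^= 1
    return flat.reshape((h, w), order="F")


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit grayscale PNG with values {0, 255}."""
    from PIL import Image

    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path, format="PNG")


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a {0, 255} PNG mask; any other pixel value is a codec error."""
    from PIL import Image

    arr = np.asarray(Image.open(Path(path)).convert("L"))
    bad = ~np.isin(arr, (0, 255))
    if bad.any():
        vals = sorted(np.unique(arr[bad]).tolist())[:5]
        raise ValueError(f"{path}: non-binary mask PNG (values {vals} present)")
    return (arr == 255).astype(np.uint8)


def save_config(config: dict, path: str | Path) -> None:
    """Serialize a run configuration (JSON or YAML by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def write_manifest(path: str | Path, command: str, inputs: dict, seed: int | None) -> None:
    """Record what a run consumed: command, inputs, seed, library versions."""
    import patchmil

    manifest = {
        "command": command,
        "inputs": inputs,
        "seed": seed,
        "versions": {
            "patchmil": patchmil.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
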
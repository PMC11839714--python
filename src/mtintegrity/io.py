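"""TIFF and CSV input/output for image batches and score tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scoring import CellImage, project_stack

__all__ = [
    "write_image",
    "read_image",
    "write_batch",
    "read_manifest",
    "scores_to_frame",
]

MANIFEST_COLUMNS = ["filename", "tissue", "site", "fraction", "dose", "d", "seed"]


def write_image(image: CellImage, path: str | Path) -> None:
    """Write a single-plane grayscale TIFF (uncompressed)."""
    tifffile.imwrite(str(path), np.asarray(image.pixels))


def read_image(path: str | Path, bit_depth: int | None = None,
               metadata: dict | None = None) -> CellImage:
    """Read a grayscale TIFF; multi-plane stacks are max-projected."""
    arr = tifffile.imread(str(path))
    if bit_depth is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
    cid = Path(path).stem
    if arr.ndim == 3:
        planes = [CellImage(pixels=p, bit_depth=bit_depth, id=cid,
                            metadata=metadata) for p in arr]
        return project_stack(planes)
    return CellImage(pixels=arr, bit_depth=bit_depth, id=cid, metadata=metadata)


def write_batch(images: list[CellImage], out_dir: str | Path) -> pd.DataFrame:
    """Write TIFFs plus the sidecar CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for image in images:
        meta = image.metadata or {}
        filename = f"{image.id}.tif"
        write_image(image, out_dir / filename)
        rows.append({
            "filename": filename,
            "tissue": meta.get("tissue", ""),
            "site": meta.get("site", ""),
            "fraction": meta.get("fraction", ""),
            "dose": meta.get("dose", np.nan),
            "d": meta.get("d", np.nan),
            "seed": meta.get("seed", -1),
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def scores_to_frame(scores: list, metadata: list[dict] | None = None) -> pd.DataFrame:
    """Score table with the standard output columns."""
    rows = []
    for i, s in enumerate(scores):
        meta = (metadata[i] if metadata else None) or {}
        rows.append({
            "cell_id": s.cell_id,
            "tissue": meta.get("tissue", ""),
            "site": meta.get("site", ""),
            "fraction": meta.get("fraction", ""),
            "dose": meta.get("dose", np.nan),
            "score": s.value,
            "n_profiles_used": s.n_profiles_used,
        })
    return pd.DataFrame(
        rows, columns=["cell_id", "tissue", "site", "fraction", "dose",
                       "score", "n_profiles_used"])
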
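"""Reading and writing the pipeline's on-disk artifacts.

Scans are plain PNG or (tiled) TIFF rasters; masks are single-channel
PNGs; the manifest and all patch indexes are CSV.  Patch caches are laid
out as one directory per scan of small PNG tiles plus one index CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .tiling import GridSpec, PatchRecord, PatchSpec, resize_pad_mask

MANIFEST_COLUMNS = [
    "scan_id", "patient_id", "slide_id", "site",
    "abnormal", "active_inflammation", "chronic_changes", "granuloma",
]

INDEX_COLUMNS = [
    "scan_id", "origin_x", "origin_y", "padded_right", "padded_bottom",
    "qc_status", "artifact_prob", "tissue_frac",
]


def save_scan(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels, tile=(256, 256))
    else:
        iio.imwrite(path, pixels)


def load_scan(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=2)
    return arr[..., :3]


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"scan_id": str, "patient_id": str, "slide_id": str})


def write_patch_cache(out_dir: str | Path, patches: list[PatchRecord]) -> Path:
    """One PNG per patch under per-scan directories, plus ``patch_index.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in patches:
        scan_dir = out_dir / rec.scan_id
        scan_dir.mkdir(exist_ok=True)
        name = f"x{rec.spec.origin_x}_y{rec.spec.origin_y}.png"
        iio.imwrite(scan_dir / name, rec.pixels)
        rows.append(
            {
                "scan_id": rec.scan_id,
                "origin_x": rec.spec.origin_x,
                "origin_y": rec.spec.origin_y,
                "padded_right": rec.spec.padded_right,
                "padded_bottom": rec.spec.padded_bottom,
                "qc_status": rec.qc_status,
                "artifact_prob": rec.artifact_prob,
                "tissue_frac": rec.tissue_frac,
            }
        )
    index_path = out_dir / "patch_index.csv"
    pd.DataFrame(rows, columns=INDEX_COLUMNS).to_csv(index_path, index=False)
    return index_path


def read_patch_cache(out_dir: str | Path, grid: GridSpec) -> list[PatchRecord]:
    out_dir = Path(out_dir)
    index = pd.read_csv(out_dir / "patch_index.csv", dtype={"scan_id": str})
    records = []
    for row in index.itertuples(index=False):
        spec = PatchSpec(int(row.origin_x), int(row.origin_y), int(row.padded_right), int(row.padded_bottom))
        pixels = iio.imread(out_dir / row.scan_id / f"x{spec.origin_x}_y{spec.origin_y}.png")
        records.append(
            PatchRecord(
                scan_id=row.scan_id,
                spec=spec,
                pixels=pixels,
                pad_mask=resize_pad_mask(spec, grid),
                qc_status=str(row.qc_status),
                artifact_prob=float(row.artifact_prob),
                tissue_frac=float(row.tissue_frac),
            )
        )
    return records
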
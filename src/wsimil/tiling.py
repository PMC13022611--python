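"""Deterministic overlapping patch grids over tissue-section scans.

A section scan (often tens of thousands of pixels per side) is subdivided
into square patches of ``patch_size`` pixels with a fixed fractional
overlap along both axes.  Origins form the lattice ``0, stride, 2*stride,
...`` with ``stride = round(patch_size * (1 - overlap))``; the trailing
patch on each axis is zero-padded so that every scan pixel is covered.
Patches are then downsized with bilinear interpolation to a small square
(the CNN input), and the padding footprint is carried through the resize
so downstream QC can tell zero fill from genuinely dark tissue.

Coordinates are 0-based with half-open extents ``[origin, origin + size)``
and the grid is returned in row-major order (y outer, x inner).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass(frozen=True)
class GridSpec:
    """Patch-grid geometry.

    Defaults follow the full-scale convention: 4096-px patches with 25%
    overlap (stride 3072), resized to 128 px for the classifier.
    """

    patch_size: int = 4096
    overlap: float = 0.25
    resize_to: int = 128

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError(f"patch_size must be >= 1, got {self.patch_size}")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.resize_to < 1:
            raise ValueError(f"resize_to must be >= 1, got {self.resize_to}")
        if self.stride < 1:
            raise ValueError("stride rounds to zero; decrease overlap")

    @property
    def stride(self) -> int:
        return int(round(self.patch_size * (1.0 - self.overlap)))


@dataclass(frozen=True)
class PatchSpec:
    """Placement of one patch on the level-0 pixel grid."""

    origin_x: int
    origin_y: int
    padded_right: int
    padded_bottom: int


@dataclass
class PatchRecord:
    """One extracted tile: resized pixels plus provenance and QC state."""

    scan_id: str
    spec: PatchSpec
    pixels: np.ndarray  # (resize_to, resize_to, 3) uint8
    pad_mask: np.ndarray  # (resize_to, resize_to) bool, True where zero fill
    qc_status: str = "retained"  # retained | artifact_rejected | low_tissue_rejected
    artifact_prob: float = float("nan")
    tissue_frac: float = float("nan")
    extras: dict = field(default_factory=dict)


def _axis_origins(extent: int, grid: GridSpec) -> list[int]:
    if extent <= grid.patch_size:
        return [0]
    n = int(np.ceil((extent - grid.patch_size) / grid.stride)) + 1
    return [i * grid.stride for i in range(n)]


def compute_patch_grid(width: int, height: int, grid: GridSpec) -> list[PatchSpec]:
    """Enumerate patch placements covering a ``width x height`` scan.

    Per axis the origins are ``0, stride, 2*stride, ...`` with count 1 when
    the extent fits in a single patch and ``ceil((extent - patch_size) /
    stride) + 1`` otherwise; the trailing patch records how many of its
    pixels fall beyond the scan (zero padding).  Row-major order.
    """
    if width < 1 or height < 1:
        raise ValueError(f"scan dimensions must be positive, got {width}x{height}")
    xs = _axis_origins(width, grid)
    ys = _axis_origins(height, grid)
    specs = []
    for oy in ys:
        pad_b = max(0, oy + grid.patch_size - height)
        for ox in xs:
            pad_r = max(0, ox + grid.patch_size - width)
            specs.append(PatchSpec(ox, oy, pad_r, pad_b))
    return specs


def extract_patch(scan_pixels: np.ndarray, spec: PatchSpec, grid: GridSpec) -> np.ndarray:
    """Copy one raw ``patch_size**2 x 3`` tile, zero-filling out-of-bounds."""
    h, w = scan_pixels.shape[:2]
    if spec.origin_x < 0 or spec.origin_y < 0 or spec.origin_x >= w or spec.origin_y >= h:
        raise ValueError(
            f"patch origin ({spec.origin_x},{spec.origin_y}) outside scan {w}x{h}"
        )
    if spec.padded_right != max(0, spec.origin_x + grid.patch_size - w) or (
        spec.padded_bottom != max(0, spec.origin_y + grid.patch_size - h)
    ):
        raise ValueError("PatchSpec padding inconsistent with this scan's dimensions")
    p = grid.patch_size
    out = np.zeros((p, p, 3), dtype=scan_pixels.dtype)
    ys = slice(spec.origin_y, min(spec.origin_y + p, h))
    xs = slice(spec.origin_x, min(spec.origin_x + p, w))
    out[: ys.stop - ys.start, : xs.stop - xs.start] = scan_pixels[ys, xs]
    return out


def resize_patch(raw: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Bilinear downsizing of a raw tile to ``resize_to`` pixels square."""
    if raw.shape[0] != grid.patch_size or raw.shape[1] != grid.patch_size:
        raise ValueError(f"expected {grid.patch_size}-px square tile, got {raw.shape}")
    if grid.patch_size == grid.resize_to:
        return raw.copy()
    out = _sk_resize(
        raw.astype(np.float64),
        (grid.resize_to, grid.resize_to, raw.shape[2]) if raw.ndim == 3 else (grid.resize_to, grid.resize_to),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    if np.issubdtype(raw.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(raw.dtype)
    return out.astype(raw.dtype)


def resize_pad_mask(spec: PatchSpec, grid: GridSpec) -> np.ndarray:
    """Padding footprint at the resized resolution (thresholded at 0.5)."""
    p = grid.patch_size
    mask = np.zeros((p, p), dtype=np.float64)
    if spec.padded_right > 0:
        mask[:, p - spec.padded_right :] = 1.0
    if spec.padded_bottom > 0:
        mask[p - spec.padded_bottom :, :] = 1.0
    if grid.patch_size == grid.resize_to:
        return mask >= 0.5
    small = _sk_resize(
        mask, (grid.resize_to, grid.resize_to), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return small >= 0.5


def tile_scan(scan_pixels: np.ndarray, scan_id: str, grid: GridSpec) -> list[PatchRecord]:
    """Full tiling of one scan: grid, extraction, resize, pad-mask carry."""
    records = []
    for spec in compute_patch_grid(scan_pixels.shape[1], scan_pixels.shape[0], grid):
        raw = extract_patch(scan_pixels, spec, grid)
        records.append(
            PatchRecord(
                scan_id=scan_id,
                spec=spec,
                pixels=resize_patch(raw, grid),
                pad_mask=resize_pad_mask(spec, grid),
            )
        )
    return records
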
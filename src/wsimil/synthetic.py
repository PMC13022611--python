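"""Seeded synthetic tissue-section cohorts with pixel-level ground truth.

Real section scans of H&E-stained gut biopsies are bright slide background
with darker pink/purple tissue fragments; abnormal sections carry localized
histologic change (dense inflammatory infiltrates, distorted crypt
architecture) occupying only part of the tissue, and slides accumulate
pen-mark and air-bubble artifacts.  This module emulates exactly those
structural features — not photorealistic histology — so that tiling, QC,
weakly supervised training and aggregation can all be exercised against a
known ground truth:

* near-white background, elliptical textured tissue blobs;
* in abnormal sections, one contiguous "witness" region covering a
  configurable fraction of the tissue, rendered with a phenotype-specific
  high-contrast texture (dense dark spots for active inflammation,
  oriented ridges for chronic changes, coarse blotches for abnormal
  sections with neither phenotype);
* saturated pen strokes and bright bubble rings as artifacts.

Every scan is a pure function of (seed, patient id, scan id): the same
parameters reproduce bit-identical pixels and labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

BIOPSY_SITES = ("duodenum", "stomach", "esophagus", "ileum", "cecum", "colon", "rectum")


@dataclass(frozen=True)
class SynthParams:
    """Cohort-level generation parameters.

    Defaults mirror the data regime the pipeline targets: ~41% abnormal
    sections, with active inflammation in ~87% and chronic changes in
    ~80% of abnormal sections, a witness region covering 60% of tissue
    in abnormal scans, and sparse artifacts.  Scan sides default to
    1024-1536 px so a full cohort is desk-scale.
    """

    seed: int = 0
    n_patients: int = 25
    scans_per_patient: int = 4
    scan_width_range: tuple[int, int] = (1024, 1536)
    scan_height_range: tuple[int, int] = (1024, 1536)
    background_level: int = 242
    tissue_blob_count: int = 3
    abnormal_scan_fraction: float = 0.412
    phenotype_probs: tuple[float, float] = (0.873, 0.795)
    witness_fraction: float = 0.6
    artifact_density: float = 0.015
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        for name in ("abnormal_scan_fraction", "witness_fraction", "artifact_density"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p in self.phenotype_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"phenotype probabilities must be in [0, 1], got {p}")
        for name in ("scan_width_range", "scan_height_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive ordered range, got {(lo, hi)}")
        if self.n_patients < 0 or self.scans_per_patient < 0:
            raise ValueError("cohort counts must be non-negative")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be a gray level in [0, 255]")


@dataclass
class GroundTruth:
    """Pixel-level truth for one synthetic scan."""

    tissue_mask: np.ndarray  # (H, W) bool
    abnormal_mask: np.ndarray  # (H, W) bool, subset of tissue_mask
    artifact_mask: np.ndarray  # (H, W) bool
    labels: dict  # abnormal / active_inflammation / chronic_changes -> 0|1


@dataclass
class SectionScan:
    """One tissue-section RGB image with identifiers and section labels."""

    scan_id: str
    patient_id: str
    slide_id: str
    site: str
    pixels: np.ndarray  # (H, W, 3) uint8
    labels: dict = field(default_factory=dict)


def _scan_rng(params: SynthParams, patient_id: str, scan_id: str) -> np.random.Generator:
    """Generator keyed on (seed, ids) so each scan is independently reproducible."""
    ss = np.random.SeedSequence(
        [params.seed, zlib.crc32(patient_id.encode()), zlib.crc32(scan_id.encode())]
    )
    return np.random.default_rng(ss)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], cell: int) -> np.ndarray:
    """Low-frequency random field in [-1, 1] by bilinear upsampling of coarse noise."""
    h, w = shape
    gh, gw = max(2, h // cell + 2), max(2, w // cell + 2)
    coarse = rng.uniform(-1.0, 1.0, size=(gh, gw)).astype(np.float32)
    from skimage.transform import resize

    return resize(coarse, (h, w), order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def _tissue_mask(rng: np.random.Generator, h: int, w: int, n_blobs: int) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    yy = np.arange(h, dtype=np.float32)[:, None]
    xx = np.arange(w, dtype=np.float32)[None, :]
    for _ in range(max(1, n_blobs)):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        ry = rng.uniform(0.16, 0.32) * h
        rx = rng.uniform(0.16, 0.32) * w
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return mask


def _witness_region(rng: np.random.Generator, tissue: np.ndarray, frac: float) -> np.ndarray:
    """Contiguous sub-region of the tissue covering ~``frac`` of its area."""
    if frac <= 0 or not tissue.any():
        return np.zeros_like(tissue)
    ys, xs = np.nonzero(tissue)
    k = rng.integers(len(ys))
    cy, cx = ys[k], xs[k]
    yy = np.arange(tissue.shape[0], dtype=np.float32)[:, None]
    xx = np.arange(tissue.shape[1], dtype=np.float32)[None, :]
    dist = np.hypot(yy - np.float32(cy), xx - np.float32(cx))
    radius = np.quantile(dist[tissue], min(frac, 1.0))
    return tissue & (dist <= radius)


def _spot_texture(rng, shape, density=0.10):
    spots = rng.random(shape) < density / 5.0
    return ndimage.binary_dilation(spots, iterations=1)


def _ridge_texture(rng, shape, period=9.0):
    theta = rng.uniform(0, np.pi)
    yy = np.arange(shape[0], dtype=np.float32)[:, None]
    xx = np.arange(shape[1], dtype=np.float32)[None, :]
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(
        np.float32(2 * np.pi / period) * (xx * np.float32(np.cos(theta)) + yy * np.float32(np.sin(theta)))
        + np.float32(phase)
    )
    return wave > 0.25


def _blotch_texture(rng, shape):
    return _smooth_field(rng, shape, cell=24) > 0.35


def _draw_labels(rng: np.random.Generator, params: SynthParams) -> dict:
    abnormal = int(rng.random() < params.abnormal_scan_fraction)
    if abnormal:
        infl = int(rng.random() < params.phenotype_probs[0])
        chron = int(rng.random() < params.phenotype_probs[1])
    else:
        infl = chron = 0
    return {"abnormal": abnormal, "active_inflammation": infl, "chronic_changes": chron}


def generate_section_scan(
    params: SynthParams,
    patient_id: str,
    scan_id: str,
    rng: np.random.Generator | None = None,
    slide_id: str = "",
    site: str = "colon",
) -> tuple[SectionScan, GroundTruth]:
    """Render one synthetic section scan plus its ground truth.

    Section labels are drawn from the cohort-level rates inside this call,
    so a scan is fully determined by (params, patient_id, scan_id).
    """
    if rng is None:
        rng = _scan_rng(params, patient_id, scan_id)
    h = int(rng.integers(params.scan_height_range[0], params.scan_height_range[1] + 1))
    w = int(rng.integers(params.scan_width_range[0], params.scan_width_range[1] + 1))
    labels = _draw_labels(rng, params)

    img = np.full((h, w, 3), np.float32(params.background_level), dtype=np.float32)
    img += (_smooth_field(rng, (h, w), cell=96) * np.float32(4.0))[..., None]

    tissue = _tissue_mask(rng, h, w, params.tissue_blob_count)
    # H&E-like tissue: pink base with gentle low-frequency mottling.
    base = np.array([198.0, 152.0, 188.0])
    mottle = _smooth_field(rng, (h, w), cell=48) * 14.0
    for c in range(3):
        img[..., c][tissue] = base[c] + mottle[tissue]

    if labels["abnormal"]:
        witness = _witness_region(rng, tissue, params.witness_fraction)
        infl, chron = labels["active_inflammation"], labels["chronic_changes"]
        if infl:
            tex = _spot_texture(rng, (h, w)) & witness
            for c, v in enumerate((96.0, 58.0, 120.0)):
                img[..., c][tex] = v
        if chron:
            tex = _ridge_texture(rng, (h, w)) & witness
            for c, dv in enumerate((78.0, 82.0, 48.0)):
                img[..., c][tex] -= dv
        if not (infl or chron):
            tex = _blotch_texture(rng, (h, w)) & witness
            for c, dv in enumerate((64.0, 70.0, 40.0)):
                img[..., c][tex] -= dv
    else:
        witness = np.zeros((h, w), dtype=bool)

    artifact = np.zeros((h, w), dtype=bool)
    target = params.artifact_density * h * w
    kind = 0
    while artifact.sum() < target:
        if kind % 2 == 0:
            artifact |= _pen_stroke(rng, img)
        else:
            artifact |= _bubble_ring(rng, img)
        kind += 1

    img += rng.standard_normal(img.shape, dtype=np.float32) * np.float32(params.noise_sd)
    pixels = np.clip(np.rint(img, out=img), 0, 255).astype(np.uint8)

    scan = SectionScan(scan_id, patient_id, slide_id, site, pixels, labels)
    truth = GroundTruth(tissue, witness, artifact, dict(labels))
    return scan, truth


def _pen_stroke(rng: np.random.Generator, img: np.ndarray) -> np.ndarray:
    """Saturated marker stroke; paints img in place, returns its mask."""
    h, w = img.shape[:2]
    y0, x0 = rng.integers(h), rng.integers(w)
    ang = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.2, 0.5) * min(h, w)
    y1 = int(np.clip(y0 + length * np.sin(ang), 0, h - 1))
    x1 = int(np.clip(x0 + length * np.cos(ang), 0, w - 1))
    n = max(abs(y1 - y0), abs(x1 - x0)) + 1
    ys = np.linspace(y0, y1, n).astype(int)
    xs = np.linspace(x0, x1, n).astype(int)
    mask = np.zeros((h, w), dtype=bool)
    mask[ys, xs] = True
    mask = ndimage.binary_dilation(mask, iterations=int(rng.integers(3, 6)))
    color = (12.0, 120.0, 45.0) if rng.random() < 0.5 else (20.0, 55.0, 190.0)
    for c, v in enumerate(color):
        img[..., c][mask] = v
    return mask


def _bubble_ring(rng: np.random.Generator, img: np.ndarray) -> np.ndarray:
    """Bright air-bubble ring; paints img in place, returns its mask."""
    h, w = img.shape[:2]
    r = rng.uniform(0.04, 0.10) * min(h, w)
    cy = rng.uniform(r, h - r)
    cx = rng.uniform(r, w - r)
    yy = np.arange(h, dtype=np.float32)[:, None]
    xx = np.arange(w, dtype=np.float32)[None, :]
    dist = np.hypot(yy - np.float32(cy), xx - np.float32(cx))
    ring = np.abs(dist - np.float32(r)) <= np.float32(max(3.0, 0.12 * r))
    for c, v in enumerate((252.0, 252.0, 236.0)):
        img[..., c][ring] = v
    return ring


def iter_cohort(params: SynthParams) -> Iterator[tuple[SectionScan, GroundTruth]]:
    """Yield the cohort scan by scan (memory-friendly for large cohorts)."""
    if params.n_patients == 0:
        raise ValueError("n_patients must be positive")
    for p in range(params.n_patients):
        pid = f"P{p + 1:03d}"
        for s in range(params.scans_per_patient):
            sid = f"{pid}_S{s + 1}"
            slide = f"{pid}_SL{s // 2 + 1}"
            site = BIOPSY_SITES[(p + s) % len(BIOPSY_SITES)]
            yield generate_section_scan(params, pid, sid, slide_id=slide, site=site)


def manifest_row(scan: SectionScan) -> dict:
    return {
        "scan_id": scan.scan_id,
        "patient_id": scan.patient_id,
        "slide_id": scan.slide_id,
        "site": scan.site,
        "abnormal": scan.labels["abnormal"],
        "active_inflammation": scan.labels["active_inflammation"],
        "chronic_changes": scan.labels["chronic_changes"],
        "granuloma": 0,  # recorded for schema parity; never rendered or modeled
    }


def generate_cohort(
    params: SynthParams,
) -> tuple[list[tuple[SectionScan, GroundTruth]], pd.DataFrame]:
    """Materialize the whole cohort and its manifest table."""
    pairs = list(iter_cohort(params))
    manifest = pd.DataFrame([manifest_row(s) for s, _ in pairs])
    return pairs, manifest


def local_contrast(gray: np.ndarray, size: int = 5) -> np.ndarray:
    """Local standard deviation map; used to verify texture separability."""
    g = gray.astype(np.float64)
    mean = ndimage.uniform_filter(g, size=size)
    sq = ndimage.uniform_filter(g * g, size=size)
    return np.sqrt(np.maximum(sq - mean * mean, 0.0))
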
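"""Synthetic slide cohorts for exercising the patch/slide/patient pipeline.

A whole-slide image is modelled as a grid of 300x300-pixel patch positions.
Positive slides carry a spatially contiguous "tumor" region (grown by random
4-connected accretion) large enough that the cluster-of-four slide rule can
fire on the ground truth.  Patch appearance is a simple blob texture: a base
tissue colour with darker nuclei-like disks at a class-specific density, plus
Gaussian pixel noise.  The classes are separable by a small classifier but
share a common appearance family, standing in for H&E morphology without
claiming realism.

Everything is deterministic given the cohort seed; per-slide randomness is
derived by hashing the slide id into the seed so slides are independent yet
reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

PATCH_SIZE = 300
#: grid footprint of one region of interest: a ~1024x768 field splits into
#: 2 rows x 3 cols of non-overlapping 300x300 patches
ROI_SHAPE = (2, 3)
PATCHES_PER_ROI = ROI_SHAPE[0] * ROI_SHAPE[1]
POSITIVE_ROI_RANGE = (4, 10)
NEGATIVE_ROI_RANGE = (10, 25)


@dataclass(frozen=True)
class TextureParams:
    """Appearance of one patch class.

    blob_density is the expected number of disks per patch; disks are drawn
    in a darkened base colour on a canvas of ``base_color`` with additive
    Gaussian noise of ``noise_sd`` grey levels.
    """

    class_name: str
    blob_density: float = 30.0
    blob_radius_px: float = 5.0
    base_color: tuple[int, int, int] = (220, 170, 190)
    noise_sd: float = 20.0
    #: lognormal sigma of per-patch density heterogeneity; makes single-patch
    #: classification genuinely imperfect, as within-class tissue variation does
    density_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.blob_density < 0:
            raise ValueError("blob_density must be >= 0")
        if self.blob_radius_px <= 0:
            raise ValueError("blob_radius_px must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color channels must lie in [0, 255]")


#: default study conditions: the two tissue classes share a base colour and
#: differ only in nuclear blob density and size (the histologic discriminator),
#: with per-patch density heterogeneity so neither class is trivially separable
DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "tumor": TextureParams("tumor", blob_density=45.0, blob_radius_px=5.5,
                           base_color=(215, 170, 190), noise_sd=25.0,
                           density_dispersion=0.25),
    "normal": TextureParams("normal", blob_density=22.0, blob_radius_px=4.5,
                            base_color=(215, 170, 190), noise_sd=25.0,
                            density_dispersion=0.25),
    "background": TextureParams("background", blob_density=0.0,
                                blob_radius_px=1.0,
                                base_color=(248, 248, 246), noise_sd=3.0),
}


@dataclass
class PatchRecord:
    """One patch: identity, grid position, optional class label, labeled flag.

    ``label`` may be present on unlabeled patches for evaluation; training
    code must mask it whenever ``labeled`` is False.
    """

    patch_id: str
    slide_id: str
    subject_id: str
    row: int
    col: int
    label: str | None = None
    labeled: bool = False
    path: str | None = None
    tumor_truth: bool = False
    render_seed: int | None = None

    def key(self) -> tuple[str, int, int]:
        return (self.slide_id, self.row, self.col)


@dataclass
class SyntheticSlide:
    slide_id: str
    subject_id: str
    label: str  # "positive" | "negative"
    grid_shape: tuple[int, int]
    tumor_mask: np.ndarray  # bool grid, all False on negative slides
    patches: list[PatchRecord] = field(default_factory=list)

    def tissue_mask(self) -> np.ndarray:
        """Cells that actually hold a sampled patch (the rest is glass)."""
        m = np.zeros(self.grid_shape, dtype=bool)
        for p in self.patches:
            m[p.row, p.col] = True
        return m


def _slide_rng(global_seed: int, slide_id: str, *extra: int) -> np.random.Generator:
    # crc32 keeps the derived entropy well below 2**32 and stable across runs
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(slide_id.encode())]
                                + [int(e) for e in extra])
    return np.random.default_rng(ss)


def grow_tumor_mask(grid_shape: tuple[int, int], area_fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Grow one contiguous region by random 4-connected neighbour accretion."""
    rows, cols = grid_shape
    target = max(4, int(round(area_fraction * rows * cols)))
    if rows * cols < 4:
        raise ValueError(
            f"grid {grid_shape} has fewer than 4 cells; cannot host a "
            "4-patch tumor cluster")
    mask = np.zeros(grid_shape, dtype=bool)
    r0 = int(rng.integers(rows))
    c0 = int(rng.integers(cols))
    mask[r0, c0] = True
    frontier = {(r0, c0)}
    while mask.sum() < target:
        candidates = set()
        for (r, c) in frontier:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and not mask[nr, nc]:
                    candidates.add((nr, nc))
        if not candidates:
            break
        pick = sorted(candidates)[int(rng.integers(len(candidates)))]
        mask[pick] = True
        frontier.add(pick)
    return mask


def render_patch(class_name: str, params: TextureParams, seed: int,
                 size: int = PATCH_SIZE) -> np.ndarray:
    """Render one 8-bit RGB patch of the given texture class.

    Deterministic given ``seed``.  With zero density and zero noise the
    output is a constant image equal to ``base_color``.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = np.asarray(params.base_color, dtype=np.float64)

    lam = params.blob_density
    if lam > 0 and params.density_dispersion > 0:
        lam *= float(np.exp(rng.normal(0.0, params.density_dispersion)))
    n_blobs = rng.poisson(lam) if lam > 0 else 0
    if n_blobs:
        blob_color = np.asarray(params.base_color, dtype=np.float64) * 0.45
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_blobs):
            cy = rng.uniform(0, size)
            cx = rng.uniform(0, size)
            r = params.blob_radius_px * rng.uniform(0.7, 1.3)
            box = (slice(max(0, int(cy - r - 1)), min(size, int(cy + r + 2))),
                   slice(max(0, int(cx - r - 1)), min(size, int(cx + r + 2))))
            d2 = (yy[box] - cy) ** 2 + (xx[box] - cx) ** 2
            inside = d2 <= r * r
            img[box][inside] = blob_color

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_record(record: PatchRecord,
                  textures: dict[str, TextureParams] | None = None,
                  size: int = PATCH_SIZE) -> np.ndarray:
    """Render the image for a cohort patch from its class and stored seed."""
    textures = textures or DEFAULT_TEXTURES
    if record.label is None:
        raise ValueError(f"patch {record.patch_id} has no class to render")
    if record.render_seed is None:
        raise ValueError(f"patch {record.patch_id} has no render seed")
    return render_patch(record.label, textures[record.label],
                        record.render_seed, size=size)


def _place_rois(free: np.ndarray, n_rois: int, prefer: np.ndarray | None,
                rng: np.random.Generator) -> list[tuple[int, int]]:
    """Choose top-left corners for 2x3 ROI blocks on unused cells.

    ``prefer`` marks cells the ROI should overlap (the tumor region); when it
    cannot be satisfied any free placement is allowed.
    """
    rows, cols = free.shape
    rh, rw = ROI_SHAPE
    placed: list[tuple[int, int]] = []
    for _ in range(n_rois):
        options, preferred = [], []
        for r in range(rows - rh + 1):
            for c in range(cols - rw + 1):
                block = free[r:r + rh, c:c + rw]
                if block.all():
                    options.append((r, c))
                    if prefer is not None and prefer[r:r + rh, c:c + rw].any():
                        preferred.append((r, c))
        pool = preferred if preferred else options
        if not pool:
            break
        r, c = pool[int(rng.integers(len(pool)))]
        free[r:r + rh, c:c + rw] = False
        placed.append((r, c))
    return placed


def emulate_roi_sampling(slide: SyntheticSlide, seed: int) -> list[PatchRecord]:
    """Sample patches from a slide the way pathologists export ROIs.

    Positive slides contribute 4-10 regions of interest, negative slides
    10-25; each ROI is a 2x3 block of grid cells yielding six non-overlapping
    300x300 patches.  ROI counts exceeding the grid capacity are clamped with
    a warning.  Patch classes follow the per-cell tumor truth.
    """
    rng = _slide_rng(seed, slide.slide_id, 1)
    lo, hi = POSITIVE_ROI_RANGE if slide.label == "positive" else NEGATIVE_ROI_RANGE
    n_rois = int(rng.integers(lo, hi + 1))
    capacity = (slide.grid_shape[0] * slide.grid_shape[1]) // PATCHES_PER_ROI
    if n_rois > capacity:
        logger.warning("slide %s: requested %d ROIs but grid fits at most %d; "
                       "clamping", slide.slide_id, n_rois, capacity)
        n_rois = capacity

    free = np.ones(slide.grid_shape, dtype=bool)
    prefer = slide.tumor_mask if slide.label == "positive" else None
    corners = _place_rois(free, n_rois, prefer, rng)
    if len(corners) < n_rois:
        logger.warning("slide %s: placed only %d of %d ROIs (fragmented grid)",
                       slide.slide_id, len(corners), n_rois)

    records: list[PatchRecord] = []
    for (r0, c0) in corners:
        for dr in range(ROI_SHAPE[0]):
            for dc in range(ROI_SHAPE[1]):
                r, c = r0 + dr, c0 + dc
                is_tumor = bool(slide.tumor_mask[r, c])
                records.append(PatchRecord(
                    patch_id=f"{slide.slide_id}_r{r}c{c}",
                    slide_id=slide.slide_id,
                    subject_id=slide.subject_id,
                    row=r, col=c,
                    label="tumor" if is_tumor else "normal",
                    tumor_truth=is_tumor,
                    render_seed=int(rng.integers(2 ** 31)),
                ))
    return records


def generate_cohort(n_subjects: int,
                    positive_fraction: float = 0.5,
                    grid_shape: tuple[int, int] = (12, 16),
                    texture_params_by_class: dict[str, TextureParams] | None = None,
                    seed: int = 0,
                    tumor_area_range: tuple[float, float] = (0.1, 0.5),
                    ) -> list[SyntheticSlide]:
    """Generate a cohort of one slide per subject, ROI-sampled and labelled.

    round(n_subjects * positive_fraction) subjects are positive.  Tumor
    regions are contiguous and cover a uniform-random fraction of the grid in
    ``tumor_area_range``.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    if grid_shape[0] * grid_shape[1] < 4:
        raise ValueError(
            f"grid {grid_shape} cannot host a 4-patch tumor cluster")
    # texture params only affect rendering; keep the arg for config plumbing
    _ = texture_params_by_class

    n_pos = int(np.floor(n_subjects * positive_fraction + 0.5))
    slides: list[SyntheticSlide] = []
    for i in range(n_subjects):
        positive = i < n_pos
        sid = f"s{i:04d}"
        slide_id = f"{sid}_w0"
        rng = _slide_rng(seed, slide_id, 0)
        if positive:
            area = rng.uniform(*tumor_area_range)
            mask = grow_tumor_mask(grid_shape, area, rng)
        else:
            mask = np.zeros(grid_shape, dtype=bool)
        slide = SyntheticSlide(slide_id=slide_id, subject_id=sid,
                               label="positive" if positive else "negative",
                               grid_shape=tuple(grid_shape), tumor_mask=mask)
        slide.patches = emulate_roi_sampling(slide, seed)
        slides.append(slide)
    return slides


def balanced_pool(n_per_class: dict[str, int],
                  textures: dict[str, TextureParams] | None = None,
                  seed: int = 0) -> list[PatchRecord]:
    """IID patch pool with exact per-class counts (LC25000/PatchCamelyon-style
    flat datasets, where patches carry no slide structure)."""
    textures = textures or DEFAULT_TEXTURES
    rng = np.random.default_rng(seed)
    records = []
    for cls in sorted(n_per_class):
        if cls not in textures:
            raise KeyError(f"no texture parameters for class {cls!r}")
        for j in range(n_per_class[cls]):
            records.append(PatchRecord(
                patch_id=f"pool_{cls}_{j:06d}", slide_id=f"pool_{cls}",
                subject_id=f"pool_{cls}", row=j, col=0, label=cls,
                tumor_truth=(cls == "tumor"),
                render_seed=int(rng.integers(2 ** 31))))
    return records


def write_patch_images(slides: list[SyntheticSlide], out_dir,
                       textures: dict[str, TextureParams] | None = None,
                       size: int = PATCH_SIZE) -> list[PatchRecord]:
    """Materialise patch PNGs on disk; returns records with paths filled in."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    updated = []
    for slide in slides:
        for p in slide.patches:
            img = render_record(p, textures, size=size)
            path = out / f"{p.patch_id}.png"
            Image.fromarray(img).save(path)
            updated.append(replace(p, path=str(path)))
    return updated
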
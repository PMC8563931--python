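"""Cluster-based whole-slide inference and patient-level aggregation.

A slide is called positive only when the binarised patch probability map
contains a connected component of at least ``min_cluster_size`` positive
tissue cells (default four, 4-neighbour connectivity) — single hot patches,
the dominant failure mode of patch classifiers on negative slides, cannot
flip a slide on their own.  A patient is positive iff any of their slides is.

For ROC analysis the binary rule is extended to a continuous "bottleneck"
score: the largest patch threshold t at which a qualifying cluster still
exists.  Thresholding the score at t reproduces the binary decision at patch
threshold t exactly, so the published rule is the 0.5 slice of the score.
Background-removed cells are holes: they carry no probability and break
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import PatchRecord

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class InferenceConfig:
    patch_threshold: float = 0.5
    min_cluster_size: int = 4
    connectivity: int = 4  # 4 or 8 neighbours

    def __post_init__(self) -> None:
        if not 0.0 <= self.patch_threshold <= 1.0:
            raise ValueError("patch_threshold must lie in [0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        return FOUR_CONNECTED if self.connectivity == 4 else EIGHT_CONNECTED


@dataclass
class SlideProbabilityMap:
    slide_id: str
    grid_shape: tuple[int, int]
    prob: np.ndarray         # float grid; meaningful only on tissue cells
    tissue_mask: np.ndarray  # bool grid; False = background-removed

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.prob.shape != tuple(self.grid_shape) or \
                self.tissue_mask.shape != tuple(self.grid_shape):
            raise ValueError("grid shapes disagree")
        on_tissue = self.prob[self.tissue_mask]
        if on_tissue.size and (on_tissue.min() < 0 or on_tissue.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def predict_slide(model, slide_patches: list[PatchRecord],
                  preprocess_config=None, textures=None,
                  grid_shape: tuple[int, int] | None = None,
                  cache=None) -> SlideProbabilityMap:
    """Run a trained patch model over one slide's patches.

    Cells without a patch (or whose patch was background-filtered) are
    masked out of the tissue mask.
    """
    from .trainer import PatchImageCache

    if not slide_patches:
        raise ValueError("no patches for slide")
    slide_id = slide_patches[0].slide_id
    for p in slide_patches:
        if p.row is None or p.col is None:
            raise ValueError(f"patch {p.patch_id} lacks grid coordinates")
    if grid_shape is None:
        grid_shape = (max(p.row for p in slide_patches) + 1,
                      max(p.col for p in slide_patches) + 1)

    if cache is None:
        cache = PatchImageCache(preprocess_config or model.preprocess, textures)
    kept = cache.add(slide_patches)
    prob = np.zeros(grid_shape, dtype=float)
    tissue = np.zeros(grid_shape, dtype=bool)
    if kept:
        probs = model.predict_proba([cache.image(p) for p in kept])
        pos = probs[:, model.positive_class_index()]
        for p, q in zip(kept, pos):
            prob[p.row, p.col] = q
            tissue[p.row, p.col] = True
    return SlideProbabilityMap(slide_id=slide_id, grid_shape=tuple(grid_shape),
                               prob=prob, tissue_mask=tissue)


def slide_decision(pmap: SlideProbabilityMap,
                   config: InferenceConfig | None = None) -> bool:
    """True (positive) iff a connected cluster of >= min_cluster_size tissue
    cells reaches the patch threshold."""
    config = config or InferenceConfig()
    hot = (pmap.prob >= config.patch_threshold) & pmap.tissue_mask
    if not hot.any():
        return False
    labels, n = ndimage.label(hot, structure=config.structure)
    if n == 0:
        return False
    sizes = np.bincount(labels.ravel())[1:]
    return bool(sizes.max() >= config.min_cluster_size)


def slide_score(pmap: SlideProbabilityMap,
                config: InferenceConfig | None = None) -> float:
    """Bottleneck score: sup{t : the slide is positive at patch threshold t}.

    Computed by admitting tissue cells in descending probability order into a
    union-find forest; the score is the probability of the cell whose arrival
    first creates a component of min_cluster_size.  0.0 when no threshold
    yields a qualifying cluster.
    """
    config = config or InferenceConfig()
    k = config.min_cluster_size
    rows, cols = pmap.grid_shape
    cells = [(float(pmap.prob[r, c]), r, c)
             for r in range(rows) for c in range(cols)
             if pmap.tissue_mask[r, c]]
    if len(cells) < k:
        return 0.0
    cells.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent: dict[tuple[int, int], tuple[int, int]] = {}
    size: dict[tuple[int, int], int] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if config.connectivity == 4:
        neigh = ((1, 0), (-1, 0), (0, 1), (0, -1))
    else:
        neigh = tuple((dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                      if (dr, dc) != (0, 0))

    active: set[tuple[int, int]] = set()
    for p, r, c in cells:
        cell = (r, c)
        parent[cell] = cell
        size[cell] = 1
        active.add(cell)
        for dr, dc in neigh:
            nb = (r + dr, c + dc)
            if nb in active:
                ra, rb = find(cell), find(nb)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
        if size[find(cell)] >= k:
            return p
    return 0.0


def slide_score_bruteforce(pmap: SlideProbabilityMap,
                           config: InferenceConfig | None = None) -> float:
    """Oracle: scan every distinct tissue probability as a threshold."""
    from dataclasses import replace

    config = config or InferenceConfig()
    values = sorted({float(v) for v in pmap.prob[pmap.tissue_mask].ravel()},
                    reverse=True)
    for t in values:
        if slide_decision(pmap, replace(config, patch_threshold=t)):
            return t
    return 0.0


def patient_decision(slide_decisions: list[bool]) -> bool:
    """Positive iff any slide is positive; all-negative slides -> negative."""
    if not slide_decisions:
        raise ValueError("patient has no slides")
    return any(slide_decisions)


def patient_score(slide_scores: list[float]) -> float:
    """Max slide score; thresholding at t reproduces patient_decision at
    patch threshold t."""
    if not slide_scores:
        raise ValueError("patient has no slides")
    return max(slide_scores)


def maps_to_frame(maps: list[SlideProbabilityMap]) -> pd.DataFrame:
    rows = []
    for m in maps:
        for r in range(m.grid_shape[0]):
            for c in range(m.grid_shape[1]):
                rows.append({"slide_id": m.slide_id, "row": r, "col": c,
                             "prob": float(m.prob[r, c]),
                             "tissue": bool(m.tissue_mask[r, c])})
    return pd.DataFrame(rows)


def frame_to_maps(df: pd.DataFrame) -> list[SlideProbabilityMap]:
    maps = []
    for slide_id, g in df.groupby("slide_id", sort=True):
        shape = (int(g["row"].max()) + 1, int(g["col"].max()) + 1)
        prob = np.zeros(shape)
        tissue = np.zeros(shape, dtype=bool)
        for _, r in g.iterrows():
            prob[int(r["row"]), int(r["col"])] = float(r["prob"])
            tissue[int(r["row"]), int(r["col"])] = bool(r["tissue"])
        maps.append(SlideProbabilityMap(slide_id=str(slide_id),
                                        grid_shape=shape, prob=prob,
                                        tissue_mask=tissue))
    return maps
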
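"""Five-step vessel segmentation of registered slices.

Preparation converts each RGB slice to grayscale, homogenizes brightness
with contrast-limited adaptive histogram equalization (CLAHE) and removes
cell-nucleus speckle with a median filter.  Then:

(i)   vessel interiors — bright, plain-white lumina — by a fixed global
      intensity cutoff (82.35% of full intensity, an Otsu-derived value
      shared by the whole stack; a helper recomputes Otsu's threshold from a
      reference slice for new datasets);
(ii)  vessel contours — stained walls, darker than surrounding tissue and of
      varying absolute intensity — by tiled local thresholding: within each
      tile a pixel is a contour candidate when its intensity is at least x
      standard deviations below the tile mean (cutoff = mu - x*sigma);
(iii) heuristic cleanup: (a) a sliding-window despeckle that deletes every
      component fitting inside an n-by-n window, (b) a contour-support rule —
      contours are dilated by 5 px and an interior survives only if at least
      45% of its Moore-traced boundary lies in the dilated contour mask,
      (c) temporal consistency across consecutive slices: structures that do
      not recur in a neighboring slice (within a 10 px positional offset)
      are removed, and structures present in both neighbors but missing in
      the center slice are copied in;
(iv)  fusion of interiors and contours (pixelwise union);
(v)   gap closing and filling: iterative dilate/fill/erode with a disk whose
      radius starts at 5 px and escalates per iteration, rejecting any fill
      larger than the biggest vessel in the slice, followed by a final
      density-adaptive closing pass whose dilation radius shrinks in
      vessel-dense tiles to prevent clustering.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy import ndimage
from skimage import color, exposure, filters

from .image_io import SliceImage

__all__ = [
    "SegmentationConfig",
    "SegmentedSlice",
    "prepare",
    "otsu_cutoff",
    "segment_interiors",
    "local_cutoff",
    "segment_contours",
    "despeckle",
    "moore_trace",
    "contour_support_filter",
    "temporal_consistency",
    "fuse",
    "close_and_fill",
    "segment_stack",
    "render_overlay",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for 2D components


def _disk_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by a Euclidean disk via the distance transform
    (O(n) in the image size, independent of the radius)."""
    if radius < 1:
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def _disk_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return mask.copy()
    return ndimage.distance_transform_edt(mask) > radius


@dataclass
class SegmentationConfig:
    #: global interior cutoff as a fraction of full intensity (Otsu-derived)
    interior_cutoff_fraction: float = 0.8235
    #: empirical factor x in the local contour cutoff mu - x*sigma
    local_x: float = 2.0
    #: tile edge for the rasterized local thresholding, px
    tile_px: int = 256
    #: intensity at and above which a pixel counts as white background and is
    #: excluded from tile statistics (and can never be a contour)
    contour_white_exclude: float = 0.95
    #: minimum tissue pixels a tile needs for a meaningful local threshold
    min_tile_tissue_px: int = 32
    #: despeckle window edge n: components fitting in n x n are removed
    despeckle_n: int = 9
    #: contour dilation before the support test, px
    contour_dilate_px: int = 5
    #: minimum fraction of an interior's boundary backed by contour
    min_support_fraction: float = 0.45
    #: positional offset tolerated when matching structures across slices, px
    consistency_offset_px: int = 10
    #: number of consecutive slices compared (odd)
    consistency_span: int = 3
    #: starting disk radius for gap closing, px
    gap_disc_px: int = 5
    #: radius escalation after the first rejected fill, px per iteration
    gap_escalation_px: int = 5
    max_close_iters: int = 6
    #: base radius of the final density-adaptive closing pass (0 disables)
    adaptive_dilate_px: int = 3
    #: tile vessel density at which adaptive dilation reaches zero
    adaptive_density_cap: float = 0.5
    # preparation
    clahe_clip: float = 0.01
    clahe_tile_px: int = 64
    median_kernel_px: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.interior_cutoff_fraction < 1.0):
            raise ValueError("interior_cutoff_fraction must be in (0, 1)")
        if not (0.0 < self.min_support_fraction < 1.0):
            raise ValueError("min_support_fraction must be in (0, 1)")
        if self.consistency_span < 3 or self.consistency_span % 2 == 0:
            raise ValueError("consistency_span must be an odd integer >= 3")
        for name in ("tile_px", "despeckle_n", "contour_dilate_px", "gap_disc_px", "median_kernel_px", "clahe_tile_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SegmentedSlice:
    """Per-slice masks produced by the pipeline (all the same shape)."""

    interiors: np.ndarray  # surviving vessel interiors after step (iii)
    contours: np.ndarray   # vessel contours from step (ii)
    fused: np.ndarray      # union of interiors and contours, step (iv)
    final: np.ndarray      # closed and filled mask, step (v)
    discarded: np.ndarray  # everything removed by the heuristics (overlay red)
    index: int = 0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.interiors, self.contours, self.fused, self.final, self.discarded)}
        if len(shapes) != 1:
            raise ValueError("all masks of a SegmentedSlice must share one shape")


# ---------------------------------------------------------------------------
# preparation and thresholding
# ---------------------------------------------------------------------------

def prepare(image: SliceImage | np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Grayscale + CLAHE + median filter; returns a float raster in [0, 1]."""
    cfg = cfg or SegmentationConfig()
    arr = image.pixels if isinstance(image, SliceImage) else np.asarray(image)
    gray = color.rgb2gray(arr) if arr.ndim == 3 else arr.astype(float)
    if gray.max() > 1.0:
        gray = gray / 255.0
    if gray.std() > 1e-9:  # CLAHE of a perfectly flat image is undefined
        gray = exposure.equalize_adapthist(
            gray, kernel_size=cfg.clahe_tile_px, clip_limit=cfg.clahe_clip
        )
    gray = ndimage.median_filter(gray, size=cfg.median_kernel_px)
    return np.clip(gray, 0.0, 1.0)


def otsu_cutoff(gray: np.ndarray) -> float:
    """Recompute the interior cutoff from a reference slice with Otsu's
    method (256-bin histogram), for recalibration on new datasets."""
    return float(filters.threshold_otsu(np.asarray(gray, dtype=float), nbins=256))


def segment_interiors(gray: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Step (i): pixels at or above the fixed stack-wide intensity cutoff."""
    cfg = cfg or SegmentationConfig()
    return np.asarray(gray, dtype=float) >= cfg.interior_cutoff_fraction


def local_cutoff(tile: np.ndarray, x: float) -> float:
    """Local threshold mu + x*sigma of a tile (population sigma)."""
    tile = np.asarray(tile, dtype=float)
    if tile.size == 0:
        raise ValueError("local_cutoff of an empty tile is undefined")
    return float(tile.mean() + x * tile.std())


def segment_contours(gray: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Step (ii): tiled local thresholding for the dark vessel walls.

    The slice is rasterized into tiles of ``tile_px``; within each tile,
    pixels at or below mu - x*sigma are marked (contours are darker than the
    surrounding tissue, so the empirical factor enters with negative sign).
    The statistics are computed over tissue pixels only: white background
    (the slide around the tissue and the registration margin) would otherwise
    collapse sigma in border tiles and mark faint interpolation ramps at the
    tissue boundary as contours.  Near-white pixels are never marked.
    """
    cfg = cfg or SegmentationConfig()
    gray = np.asarray(gray, dtype=float)
    h, w = gray.shape
    out = np.zeros((h, w), dtype=bool)
    t = cfg.tile_px
    for y0 in range(0, h, t):
        for x0 in range(0, w, t):
            tile = gray[y0 : y0 + t, x0 : x0 + t]
            tissue = tile[tile < cfg.contour_white_exclude]
            if tissue.size < cfg.min_tile_tissue_px:
                continue
            cut = local_cutoff(tissue, -cfg.local_x)
            out[y0 : y0 + t, x0 : x0 + t] = tile <= min(cut, cfg.contour_white_exclude)
    return out


# ---------------------------------------------------------------------------
# step (iii): heuristic removal / addition
# ---------------------------------------------------------------------------

def despeckle(mask: np.ndarray, n: int) -> np.ndarray:
    """Remove every 8-connected component whose bounding box fits in n x n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, num = ndimage.label(mask, structure=_STRUCT8)
    if num == 0:
        return mask.copy()
    out = mask.copy()
    for sl, lab in zip(ndimage.find_objects(labels), range(1, num + 1)):
        if sl is None:
            continue
        height = sl[0].stop - sl[0].start
        width = sl[1].stop - sl[1].start
        if height <= n and width <= n:
            out[sl][labels[sl] == lab] = False
    return out


# Moore neighborhood in clockwise order starting at West: (dr, dc)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def moore_trace(mask: np.ndarray) -> np.ndarray:
    """Moore-Neighbor boundary trace with Jacob's stopping criterion.

    Traces the outer boundary of the first (top-left in raster order)
    foreground component and returns the ordered, de-duplicated boundary
    pixels as an (N, 2) array of (row, col).  The trace starts at the first
    foreground pixel found scanning rows top-to-bottom, columns
    left-to-right, entered from the West, and stops when the start pixel is
    re-entered from the same direction.
    """
    mask = np.asarray(mask, dtype=bool)
    fg = np.argwhere(mask)
    if fg.size == 0:
        return np.empty((0, 2), dtype=int)
    start = tuple(fg[0])

    h, w = mask.shape

    def is_set(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    # entered from the West: the backtrack pixel is start + West offset
    start_back = (start[0], start[1] - 1)
    boundary: list[tuple[int, int]] = [start]
    seen = {start}
    cur, back = start, start_back
    max_steps = 4 * (mask.sum() + 8)
    for _ in range(int(max_steps)):
        # index of the backtrack position in the Moore order around cur
        dr, dc = back[0] - cur[0], back[1] - cur[1]
        k = _MOORE.index((dr, dc))
        nxt = None
        for step in range(1, 9):
            cand_off = _MOORE[(k + step) % 8]
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if is_set(*cand):
                nxt = cand
                prev_off = _MOORE[(k + step - 1) % 8]
                new_back = (cur[0] + prev_off[0], cur[1] + prev_off[1])
                break
        if nxt is None:  # isolated pixel
            break
        if nxt == start and new_back == start_back:  # Jacob's criterion
            break
        cur, back = nxt, new_back
        if cur not in seen:
            seen.add(cur)
            boundary.append(cur)
    return np.array(boundary, dtype=int)


def contour_support_filter(
    interiors: np.ndarray,
    contours: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Step (iii b): keep interiors whose boundary is backed by contour.

    The contour mask is dilated by ``contour_dilate_px`` (disk); for each
    interior component the support is the fraction of its Moore-traced
    boundary pixels lying inside the dilated contour.  Components with
    support >= ``min_support_fraction`` are kept; the rest are returned in
    the discarded mask.
    """
    cfg = cfg or SegmentationConfig()
    interiors = np.asarray(interiors, dtype=bool)
    contours = np.asarray(contours, dtype=bool)
    if interiors.shape != contours.shape:
        raise ValueError("interiors and contours must share one shape")
    dilated = _disk_dilate(contours, cfg.contour_dilate_px)
    labels, num = ndimage.label(interiors, structure=_STRUCT8)
    kept = np.zeros_like(interiors)
    discarded = np.zeros_like(interiors)
    for lab, sl in zip(range(1, num + 1), ndimage.find_objects(labels)):
        comp = labels[sl] == lab
        boundary = moore_trace(comp)
        rows = boundary[:, 0] + sl[0].start
        cols = boundary[:, 1] + sl[1].start
        support = float(np.mean(dilated[rows, cols])) if len(boundary) else 0.0
        target = kept if support >= cfg.min_support_fraction else discarded
        target[sl][comp] = True
    return kept, discarded


def _component_table(mask: np.ndarray) -> tuple[np.ndarray, list[dict]]:
    labels, num = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCT8)
    comps = []
    if num:
        centroids = ndimage.center_of_mass(mask, labels, range(1, num + 1))
        for lab, (cy, cx) in enumerate(centroids, start=1):
            comps.append({"label": lab, "centroid": np.array([cy, cx])})
    return labels, comps


def _shifted(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    out[ys0:ys1, xs0:xs1] = mask[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def _matches(
    comp_mask: np.ndarray,
    centroid: np.ndarray,
    other_labels: np.ndarray,
    other_comps: list[dict],
    offset: float,
) -> bool:
    """True if a component in the other slice matches: centroid within
    ``offset`` px and nonzero overlap once shifted onto this component."""
    for oc in other_comps:
        d = oc["centroid"] - centroid
        if np.hypot(*d) > offset:
            continue
        other_mask = other_labels == oc["label"]
        dy, dx = int(round(-d[0])), int(round(-d[1]))
        if np.any(comp_mask & _shifted(other_mask, dy, dx)):
            return True
    return False


def temporal_consistency(
    window: list[np.ndarray],
    cfg: SegmentationConfig | None = None,
) -> np.ndarray:
    """Step (iii c): edit the center mask of a window of co-registered
    interior masks from consecutive slices.

    A center component is kept iff a matching component (centroid within
    ``consistency_offset_px`` and overlapping after the centroid shift)
    exists in at least one neighbor slice.  A structure present in enough
    neighbors (both, for a 3-slice window) but absent from the center is
    copied in as the intersection of the neighbor components after aligning
    their centroids to the mean position.  The rule is symmetric under
    reversing the window.
    """
    cfg = cfg or SegmentationConfig()
    if len(window) != cfg.consistency_span:
        raise ValueError(
            f"window length {len(window)} != consistency_span {cfg.consistency_span}"
        )
    center_idx = len(window) // 2
    center = np.asarray(window[center_idx], dtype=bool)
    neighbors = [np.asarray(m, dtype=bool) for k, m in enumerate(window) if k != center_idx]
    kept = _keep_matching(center, neighbors, cfg)

    # addition: structures recurring in enough neighbors but absent in center
    need = (cfg.consistency_span - 1) // 2 + 1  # 2 of 3 for the default span
    added = _added_structures(center, neighbors, need, cfg)
    return kept | added


def _keep_matching(
    center: np.ndarray, neighbors: list[np.ndarray], cfg: SegmentationConfig
) -> np.ndarray:
    labels, comps = _component_table(center)
    ntables = [_component_table(n) for n in neighbors]
    kept = np.zeros_like(center)
    for c in comps:
        comp_mask = labels == c["label"]
        if any(
            _matches(comp_mask, c["centroid"], nl, ncs, cfg.consistency_offset_px)
            for nl, ncs in ntables
        ):
            kept |= comp_mask
    return kept


def _added_structures(
    center: np.ndarray,
    neighbors: list[np.ndarray],
    need: int,
    cfg: SegmentationConfig,
) -> np.ndarray:
    offset = cfg.consistency_offset_px
    # collect (slice id, mask, centroid) for every neighbor component
    entries = []
    tables = []
    for si, n in enumerate(neighbors):
        labels, comps = _component_table(n)
        tables.append((labels, comps))
        for c in comps:
            entries.append({"slice": si, "mask": labels == c["label"], "centroid": c["centroid"]})
    if not entries:
        return np.zeros_like(center)

    clabels, ccomps = _component_table(center)

    # greedy clustering of neighbor components by centroid proximity
    n_e = len(entries)
    parent = list(range(n_e))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n_e):
        for b in range(a + 1, n_e):
            if np.hypot(*(entries[a]["centroid"] - entries[b]["centroid"])) <= offset:
                parent[find(a)] = find(b)

    added = np.zeros_like(center)
    clusters: dict[int, list[int]] = {}
    for k in range(n_e):
        clusters.setdefault(find(k), []).append(k)
    for members in clusters.values():
        slices = {entries[k]["slice"] for k in members}
        if len(slices) < need:
            continue
        mean_centroid = np.mean([entries[k]["centroid"] for k in members], axis=0)
        # skip when the center already has a matching structure nearby
        if any(np.hypot(*(c["centroid"] - mean_centroid)) <= offset for c in ccomps):
            continue
        inter = None
        for k in members:
            e = entries[k]
            d = mean_centroid - e["centroid"]
            shifted = _shifted(e["mask"], int(round(d[0])), int(round(d[1])))
            inter = shifted if inter is None else (inter & shifted)
        if inter is not None and inter.any():
            added |= inter
    return added


def _temporal_keep_only(
    center: np.ndarray, neighbors: list[np.ndarray], cfg: SegmentationConfig
) -> np.ndarray:
    """One-sided window at the stack edges: keep-matching logic only."""
    return _keep_matching(np.asarray(center, dtype=bool), [np.asarray(n, bool) for n in neighbors], cfg)


# ---------------------------------------------------------------------------
# steps (iv) and (v)
# ---------------------------------------------------------------------------

def fuse(interiors: np.ndarray, contours: np.ndarray) -> np.ndarray:
    """Step (iv): pixelwise union of interiors and contours."""
    interiors = np.asarray(interiors, dtype=bool)
    contours = np.asarray(contours, dtype=bool)
    if interiors.shape != contours.shape:
        raise ValueError("masks must share one shape")
    return interiors | contours


def _close_fill_once(
    result: np.ndarray, radius: int, a_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """One gap-closing + filling round at a fixed disk radius.

    Morphological closing bridges contour gaps up to ~2*radius; every region
    thereby enclosed is a fill candidate.  A candidate larger than ``a_max``
    is rejected (returned in the second mask).  Closing residue (necks) is
    accepted only where it is adjacent to an accepted fill — a neck that
    encloses nothing closes no contour, it only welds separate structures
    together, so it is dropped.
    """
    closing = _disk_erode(_disk_dilate(result, radius), radius) if radius >= 1 else result
    closed_union = result | closing
    filled = ndimage.binary_fill_holes(closed_union)
    holes = filled & ~closed_union
    necks = closing & ~result

    accepted = np.zeros_like(result)
    rejected = np.zeros_like(result)
    hole_labels, n_holes = ndimage.label(holes, structure=_STRUCT8)
    if n_holes:
        areas = np.bincount(hole_labels.ravel())
        for lab in range(1, n_holes + 1):
            target = rejected if areas[lab] > a_max else accepted
            target |= hole_labels == lab
    if necks.any():
        neck_labels, n_necks = ndimage.label(necks, structure=_STRUCT8)
        support = ndimage.binary_dilation(accepted, structure=_STRUCT8)
        for lab in range(1, n_necks + 1):
            comp = neck_labels == lab
            if np.any(comp & support):
                accepted |= comp
    return accepted, rejected


def close_and_fill(
    fused: np.ndarray,
    a_max: float,
    cfg: SegmentationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Step (v): close open contour ends and fill the enclosed regions.

    Iterates :func:`_close_fill_once` with a disk radius starting at
    ``gap_disc_px`` that doubles per iteration until the first oversized fill
    is rejected, after which it grows by ``gap_escalation_px`` per iteration.
    Fills larger than ``a_max`` (the area of the biggest vessel in the
    slice) are reverted and recorded.  Ends when an iteration accepts and
    rejects nothing or after ``max_close_iters``.  A final density-adaptive
    pass closes residual gaps per tile, with the disk radius shrinking
    toward zero as the tile's vessel density approaches
    ``adaptive_density_cap`` (prevents clustering in vessel-dense areas).

    Returns (final mask, rejected additions mask).
    """
    cfg = cfg or SegmentationConfig()
    result = np.asarray(fused, dtype=bool).copy()
    rejected = np.zeros_like(result)
    if not result.any():
        return result, rejected
    if not np.isfinite(a_max) or a_max <= 0:
        a_max = np.inf

    radius = cfg.gap_disc_px
    had_rejection = False
    for _ in range(cfg.max_close_iters):
        accepted, rejected_now = _close_fill_once(result, radius, a_max)
        rejected |= rejected_now
        if not accepted.any() and not rejected_now.any():
            break
        result |= accepted
        if rejected_now.any():
            had_rejection = True
        radius = radius + cfg.gap_escalation_px if had_rejection else radius * 2

    if cfg.adaptive_dilate_px > 0:
        result, rej2 = _adaptive_close(result, a_max, cfg)
        rejected |= rej2
    return result, rejected


def _adaptive_close(
    mask: np.ndarray, a_max: float, cfg: SegmentationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile closing pass with a dilation radius that shrinks with the
    tile's vessel density."""
    h, w = mask.shape
    t = cfg.tile_px
    radii = np.zeros(((h + t - 1) // t, (w + t - 1) // t), dtype=int)
    for i, y0 in enumerate(range(0, h, t)):
        for j, x0 in enumerate(range(0, w, t)):
            density = float(mask[y0 : y0 + t, x0 : x0 + t].mean())
            frac = max(0.0, 1.0 - density / cfg.adaptive_density_cap)
            radii[i, j] = int(np.floor(cfg.adaptive_dilate_px * frac))
    out = mask.copy()
    rejected = np.zeros_like(mask)
    for r in np.unique(radii):
        if r < 1:
            continue
        accepted_r, rejected_r = _close_fill_once(mask, int(r), a_max)
        sel = np.zeros_like(mask)
        for i, y0 in enumerate(range(0, h, t)):
            for j, x0 in enumerate(range(0, w, t)):
                if radii[i, j] == r:
                    sel[y0 : y0 + t, x0 : x0 + t] = True
        out |= accepted_r & sel
        rejected |= rejected_r & sel
    return out, rejected


# ---------------------------------------------------------------------------
# whole-stack orchestration
# ---------------------------------------------------------------------------

def _segment_single(
    image: SliceImage | np.ndarray, cfg: SegmentationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-slice steps (prepare, i, ii, iii a, iii b); returns
    (interiors after support filter, contours, discarded)."""
    gray = prepare(image, cfg)
    interiors = despeckle(segment_interiors(gray, cfg), cfg.despeckle_n)
    contours = despeckle(segment_contours(gray, cfg), cfg.despeckle_n)
    interiors, discarded = contour_support_filter(interiors, contours, cfg)
    return interiors, contours, discarded


def segment_stack(
    stack: list[SliceImage] | list[np.ndarray],
    cfg: SegmentationConfig | None = None,
    workers: int = 1,
) -> list[SegmentedSlice]:
    """Run the full five-step segmentation over a registered stack.

    Per-slice stages parallelize over slices; the cross-slice temporal
    consistency stage runs after all per-slice results exist.  Output is
    deterministic for a fixed configuration regardless of worker count.
    """
    cfg = cfg or SegmentationConfig()
    if not stack:
        raise ValueError("segment_stack needs at least one slice")

    per_slice = Parallel(n_jobs=workers)(
        delayed(_segment_single)(img, cfg) for img in stack
    )
    interiors = [r[0] for r in per_slice]
    contours = [r[1] for r in per_slice]
    discarded = [r[2] for r in per_slice]

    # step (iii c): temporal consistency across slices
    half = cfg.consistency_span // 2
    n = len(stack)
    edited: list[np.ndarray] = []
    for i in range(n):
        if n < cfg.consistency_span or i < half or i >= n - half:
            nbrs = [interiors[j] for j in range(max(0, i - half), min(n, i + half + 1)) if j != i]
            edited.append(
                _temporal_keep_only(interiors[i], nbrs, cfg) if nbrs else interiors[i]
            )
        else:
            window = [interiors[j] for j in range(i - half, i + half + 1)]
            edited.append(temporal_consistency(window, cfg))

    def _finalize(i: int) -> SegmentedSlice:
        removed = interiors[i] & ~edited[i]
        fused = fuse(edited[i], contours[i])
        areas = _component_areas(edited[i])
        a_max = float(max(areas, default=0)) or float(max(_component_areas(contours[i]), default=0))
        final, rejected = close_and_fill(fused, a_max if a_max > 0 else np.inf, cfg)
        return SegmentedSlice(
            interiors=edited[i],
            contours=contours[i],
            fused=fused,
            final=final,
            discarded=discarded[i] | removed | rejected,
            index=i,
        )

    return Parallel(n_jobs=workers)(delayed(_finalize)(i) for i in range(n))


def _component_areas(mask: np.ndarray) -> list[int]:
    labels, num = ndimage.label(np.asarray(mask, bool), structure=_STRUCT8)
    if num == 0:
        return []
    return list(np.bincount(labels.ravel())[1:])


def render_overlay(seg: SegmentedSlice, background: np.ndarray | None = None) -> np.ndarray:
    """RGB overlay: interiors blue, contours black, discarded red."""
    h, w = seg.final.shape
    if background is not None:
        base = np.asarray(background)
        if base.ndim == 2:
            base = np.stack([base] * 3, axis=-1)
        out = base.astype(np.uint8).copy()
    else:
        out = np.full((h, w, 3), 255, dtype=np.uint8)
    out[seg.discarded] = (220, 30, 30)
    out[seg.interiors] = (40, 60, 220)
    out[seg.contours] = (0, 0, 0)
    return out
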
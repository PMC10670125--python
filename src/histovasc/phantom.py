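"""Synthetic serial-histology phantom with exact ground truth.

The phantom emulates what the pipeline sees in stained tumor sections:
vessels with bright, near-white lumina enclosed by darkly stained walls,
lying in a pinkish tissue background speckled with dark cell nuclei; a
per-slice rigid/similarity misalignment from manual slide preparation; and
slicing damage (dark fissure tears, white missing-tissue patches).

Vessels are smooth tubes spanning the z-range of the volume, with optional
branches.  Everything the pipeline is supposed to recover is recorded as
ground truth: per-slice vessel masks (in both the common reference frame and
the misaligned slice frame), the 3D truth volume, the true per-slice
transforms, a landmark grid with exact correspondences for registration
metrics, and per-slice artifact masks.  All output is a deterministic
function of (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage

from .image_io import LandmarkSet, SliceImage, VoxelVolume
from .reg_metrics import LandmarkPair
from .transforms import SliceTransform, warp_image

__all__ = ["PhantomConfig", "PhantomTruth", "generate_network", "render_stack", "truth_volume", "generate_phantom"]


@dataclass
class PhantomConfig:
    #: grid size (z, y, x): 50 slices of 512 x 512 px exercises every rule
    volume_vox: tuple[int, int, int] = (50, 512, 512)
    n_vessels: int = 8
    radius_range_vox: tuple[float, float] = (5.0, 30.0)
    #: lateral drift of a vessel centerline per slice step, px (std dev)
    tortuosity: float = 1.0
    branching_prob: float = 0.1
    contour_thickness_px: int = 3
    # appearance (means in [0,1] per RGB channel, plus one noise sd)
    lumen_intensity: tuple[float, float, float] = (0.97, 0.96, 0.97)
    contour_intensity: tuple[float, float, float] = (0.38, 0.26, 0.45)
    tissue_intensity: tuple[float, float, float] = (0.88, 0.64, 0.74)
    noise_sd: float = 0.025
    #: nucleus speckles per 1000 px^2
    nucleus_density: float = 0.8
    #: white slide background around the tissue block, as a fraction of the
    #: in-plane size; keeps the misaligned tissue clear of the image frame
    #: (a real slide shows the whole tissue piece surrounded by background,
    #: so no tissue edge is pinned to the frame)
    tissue_border_frac: float = 0.125
    # per-slice misalignment bounds (slice 0 is always the identity anchor)
    misalign_max_rotation_deg: float = 5.0
    misalign_max_translation_px: float = 10.0
    misalign_max_scale_dev: float = 0.02
    #: expected damage artifacts per slice (Poisson); 0 disables
    artifact_rate: float = 0.0
    landmark_grid_spacing_px: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range_vox[0] <= 0 or self.radius_range_vox[1] < self.radius_range_vox[0]:
            raise ValueError("radius range must be positive and ordered")
        if not (0.0 <= self.branching_prob <= 1.0):
            raise ValueError("branching_prob must be in [0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")


@dataclass
class PhantomTruth:
    #: per-slice vessel masks in the common reference frame (= truth volume slices)
    vessel_masks: list[np.ndarray]
    #: per-slice lumen-only masks, reference frame
    lumen_masks: list[np.ndarray]
    #: per-slice vessel masks in each rendered slice's own (misaligned) frame
    slice_masks: list[np.ndarray]
    volume_truth: VoxelVolume
    #: transform mapping slice i's coordinates into the reference frame
    true_transforms: list[SliceTransform]
    #: landmark grid in the reference frame
    landmarks_ref: LandmarkSet
    #: the grid carried into each slice's frame by the true misalignment
    landmarks_per_slice: list[LandmarkSet]
    #: consecutive-pair correspondences (moving i -> fixed i-1), warped=moving
    landmark_pairs: list[LandmarkPair]
    artifact_masks: list[np.ndarray]
    #: reference-frame tissue block (frame minus the white slide border)
    tissue_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# vessel network geometry
# ---------------------------------------------------------------------------

def _centerline(rng: np.random.Generator, cfg: PhantomConfig, start_yx: np.ndarray) -> np.ndarray:
    """Smooth lateral random walk over the full z-range; (Z, 2) of (y, x)."""
    nz = cfg.volume_vox[0]
    steps = rng.normal(0.0, cfg.tortuosity, size=(nz, 2))
    path = start_yx + np.cumsum(steps, axis=0)
    if cfg.tortuosity > 0:
        path = ndimage.gaussian_filter1d(path, sigma=3.0, axis=0, mode="nearest")
    return path


def _paths_collide(
    path_a: np.ndarray, r_a: float, path_b: np.ndarray, r_b: float, gap: float = 4.0
) -> bool:
    d = np.linalg.norm(path_a - path_b, axis=1)
    return bool(np.any(d < r_a + r_b + gap))


def generate_network(cfg: PhantomConfig | None = None) -> nx.Graph:
    """Random smooth tube centerlines spanning the z-range, with branches.

    Nodes are (vessel_id, z) carrying ``pos`` = (z, y, x) and ``radius``;
    consecutive z samples are joined by edges, and a branch's first node
    links to its parent so each vessel is one connected component.
    Deterministic for a fixed (seed, config); raises after bounded retries
    when the requested vessels cannot be packed into the volume.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx_ = cfg.volume_vox
    g = nx.Graph()
    if cfg.n_vessels == 0:
        return g

    placed: list[tuple[np.ndarray, float]] = []
    rmin, rmax = cfg.radius_range_vox
    margin = rmax + 8.0 + cfg.tissue_border_frac * min(ny, nx_)
    if 2 * margin >= min(ny, nx_):
        raise ValueError("volume too small for the requested vessel radii")

    vid = 0
    for _ in range(cfg.n_vessels):
        for attempt in range(60):
            radius = float(rng.uniform(rmin, rmax))
            start = rng.uniform([margin, margin], [ny - margin, nx_ - margin])
            path = _centerline(rng, cfg, start)
            lo = margin - 4.0
            path = np.clip(path, lo, [ny - lo, nx_ - lo])
            if not any(_paths_collide(path, radius, p, r) for p, r in placed):
                break
        else:
            raise RuntimeError(
                f"could not pack {cfg.n_vessels} vessels of radius <= {rmax} "
                f"into a {ny} x {nx_} plane after bounded retries"
            )
        placed.append((path, radius))
        _add_polyline(g, vid, path, radius, parent=None)
        root_vid = vid
        vid += 1

        if rng.uniform() < cfg.branching_prob:
            z0 = int(rng.integers(nz // 4, 3 * nz // 4))
            b_radius = max(rmin, radius * 0.6)
            direction = rng.normal(0, 1, 2)
            direction = direction / (np.linalg.norm(direction) + 1e-9)
            b_path = np.full((nz, 2), np.nan)
            pos = placed[-1][0][z0].copy()
            for z in range(z0, nz):
                pos = pos + direction * 1.5 + rng.normal(0, cfg.tortuosity, 2)
                b_path[z] = np.clip(pos, margin - 4.0, [ny - margin + 4.0, nx_ - margin + 4.0])
            _add_polyline(g, vid, b_path, b_radius, parent=(root_vid, z0))
            vid += 1
    return g


def _add_polyline(
    g: nx.Graph, vid: int, path: np.ndarray, radius: float, parent: tuple[int, int] | None
) -> None:
    prev = None
    for z, yx in enumerate(path):
        if np.any(np.isnan(yx)):
            continue
        node = (vid, z)
        g.add_node(node, pos=(float(z), float(yx[0]), float(yx[1])), radius=radius, vessel=vid)
        if prev is not None:
            g.add_edge(prev, node)
        prev = node
    if parent is not None and prev is not None:
        first_z = min(z for v, z in g.nodes if v == vid)
        g.add_edge((vid, first_z), parent)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _cross_sections(graph: nx.Graph, z: int) -> list[tuple[float, float, float]]:
    """(y, x, radius) of every tube passing through integer slice z."""
    out = []
    for node, data in graph.nodes(data=True):
        if node[1] == z:
            _, y, x = data["pos"]
            out.append((y, x, data["radius"]))
    return out


def _disc_mask(shape: tuple[int, int], y: float, x: float, r: float) -> np.ndarray:
    h, w = shape
    y0, y1 = max(0, int(y - r - 2)), min(h, int(y + r + 3))
    x0, x1 = max(0, int(x - r - 2)), min(w, int(x + r + 3))
    out = np.zeros(shape, dtype=bool)
    if y1 <= y0 or x1 <= x0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out[y0:y1, x0:x1] = (yy - y) ** 2 + (xx - x) ** 2 <= r**2
    return out


def _slice_masks(graph: nx.Graph, cfg: PhantomConfig, z: int) -> tuple[np.ndarray, np.ndarray]:
    """(full vessel mask, lumen mask) of slice z in the reference frame."""
    _, ny, nx_ = cfg.volume_vox
    full = np.zeros((ny, nx_), dtype=bool)
    lumen = np.zeros((ny, nx_), dtype=bool)
    for y, x, r in _cross_sections(graph, z):
        full |= _disc_mask((ny, nx_), y, x, r)
        lumen |= _disc_mask((ny, nx_), y, x, max(r - cfg.contour_thickness_px, 1.0))
    return full, lumen


def truth_volume(graph: nx.Graph, cfg: PhantomConfig | None = None) -> VoxelVolume:
    """3D binary rasterization of the tubes (lumen + wall), reference frame."""
    cfg = cfg or PhantomConfig()
    nz = cfg.volume_vox[0]
    slices = [_slice_masks(graph, cfg, z)[0] for z in range(nz)]
    return VoxelVolume(np.stack(slices))


def _tissue_region(cfg: PhantomConfig) -> np.ndarray:
    """Reference-frame tissue block: the frame minus the white slide border."""
    _, ny, nx_ = cfg.volume_vox
    b = int(round(cfg.tissue_border_frac * min(ny, nx_)))
    mask = np.zeros((ny, nx_), dtype=bool)
    mask[b : ny - b, b : nx_ - b] = True
    return mask


def _render_reference_slice(
    rng: np.random.Generator, cfg: PhantomConfig, full: np.ndarray, lumen: np.ndarray
) -> np.ndarray:
    """RGB float image of one slice in the reference frame."""
    _, ny, nx_ = cfg.volume_vox
    img = np.empty((ny, nx_, 3), dtype=float)
    for c in range(3):
        img[..., c] = cfg.tissue_intensity[c]
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)

    # stained cell nuclei: small dark speckles over the tissue
    n_nuclei = rng.poisson(cfg.nucleus_density * ny * nx_ / 1000.0)
    if n_nuclei:
        ys = rng.integers(0, ny, n_nuclei)
        xs = rng.integers(0, nx_, n_nuclei)
        radii = rng.integers(1, 3, n_nuclei)
        nuclei = np.zeros((ny, nx_), dtype=bool)
        nuclei[ys, xs] = True
        for r in (1, 2):
            sel = radii == r
            if sel.any():
                m = np.zeros((ny, nx_), dtype=bool)
                m[ys[sel], xs[sel]] = True
                nuclei |= ndimage.binary_dilation(m, iterations=r)
        for c in range(3):
            img[..., c][nuclei] = cfg.contour_intensity[c] + rng.normal(
                0.0, cfg.noise_sd, int(nuclei.sum())
            )

    ring = full & ~lumen
    for c in range(3):
        img[..., c][ring] = cfg.contour_intensity[c] + rng.normal(0.0, cfg.noise_sd, int(ring.sum()))
        img[..., c][lumen] = cfg.lumen_intensity[c] + rng.normal(
            0.0, cfg.noise_sd / 2, int(lumen.sum())
        )
    img[~_tissue_region(cfg)] = 1.0  # white slide background around the block
    return np.clip(img, 0.0, 1.0)


def _random_misalignment(
    rng: np.random.Generator, cfg: PhantomConfig, center: tuple[float, float]
) -> SliceTransform:
    rot = rng.uniform(-cfg.misalign_max_rotation_deg, cfg.misalign_max_rotation_deg)
    t = rng.uniform(-cfg.misalign_max_translation_px, cfg.misalign_max_translation_px, 2)
    sc = 1.0 + rng.uniform(-cfg.misalign_max_scale_dev, cfg.misalign_max_scale_dev)
    return SliceTransform.from_params(
        rotation_deg=rot, scale=sc, translation=(t[0], t[1]), center=center
    )


def _polyline_mask(
    rng: np.random.Generator, shape: tuple[int, int], width: int
) -> np.ndarray:
    """Random fissure: a jagged polyline of the given width, px."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pos = rng.uniform([0, 0], [h, w])
    direction = rng.normal(0, 1, 2)
    direction /= np.linalg.norm(direction) + 1e-9
    length = int(rng.uniform(0.2, 0.6) * min(h, w))
    for _ in range(length):
        pos = pos + direction + rng.normal(0, 0.4, 2)
        r, c = int(round(pos[0])), int(round(pos[1]))
        if 0 <= r < h and 0 <= c < w:
            mask[r, c] = True
    if width > 1:
        mask = ndimage.binary_dilation(mask, iterations=width - 1)
    return mask


def _inject_artifacts(
    rng: np.random.Generator,
    cfg: PhantomConfig,
    img: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fissures (dark tears) and dropout patches (white missing tissue)."""
    h, w = img.shape[:2]
    artifact = np.zeros((h, w), dtype=bool)
    n = rng.poisson(cfg.artifact_rate)
    out = img.copy()
    for _ in range(n):
        if rng.uniform() < 0.5:
            m = _polyline_mask(rng, (h, w), width=int(rng.integers(1, 4)))
            for c in range(3):
                out[..., c][m] = cfg.contour_intensity[c]
        else:
            y, x = rng.uniform([0, 0], [h, w])
            m = _disc_mask((h, w), y, x, float(rng.uniform(10, 30)))
            out[m] = 1.0
        artifact |= m
    return out, artifact


def render_stack(
    graph: nx.Graph, cfg: PhantomConfig | None = None
) -> tuple[list[SliceImage], PhantomTruth]:
    """Rasterize the network into a misaligned, noisy RGB slice stack.

    Slice 0 keeps the identity misalignment (it anchors the registration
    frame); every other slice receives a random similarity perturbation
    within the configured bounds.  Ground-truth masks, transforms, a
    landmark grid and artifact masks are returned alongside.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    nz, ny, nx_ = cfg.volume_vox
    center = ((nx_ - 1) / 2.0, (ny - 1) / 2.0)
    diag = float(np.hypot(ny, nx_))

    sp = cfg.landmark_grid_spacing_px
    gy, gx = np.mgrid[sp : ny - sp // 2 : sp, sp : nx_ - sp // 2 : sp]
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    landmarks_ref = LandmarkSet(grid, frame="reference")

    slices: list[SliceImage] = []
    ref_masks: list[np.ndarray] = []
    lumen_masks: list[np.ndarray] = []
    slice_masks: list[np.ndarray] = []
    transforms: list[SliceTransform] = []
    lm_per_slice: list[LandmarkSet] = []
    artifact_masks: list[np.ndarray] = []

    for z in range(nz):
        full, lumen = _slice_masks(graph, cfg, z)
        img = _render_reference_slice(rng, cfg, full, lumen)

        if z == 0:
            mis = SliceTransform.identity()
        else:
            mis = _random_misalignment(rng, cfg, center)
        # mis maps reference coords -> slice coords; its inverse is the
        # transform the registration is expected to recover (slice -> ref)
        img_slice = warp_image(img, mis, out_shape=(ny, nx_), order=1, cval=1.0)
        mask_slice = warp_image(full, mis, out_shape=(ny, nx_), order=0)
        img_slice, artifact = _inject_artifacts(rng, cfg, img_slice)

        true_t = mis.inverse()
        true_t.source_index, true_t.target_index = z, 0
        transforms.append(true_t)
        lm_per_slice.append(LandmarkSet(mis.transform_points(grid), frame=f"slice{z}"))

        slices.append(SliceImage(np.clip(img_slice * 255, 0, 255).astype(np.uint8), index=z))
        ref_masks.append(full)
        lumen_masks.append(lumen)
        slice_masks.append(mask_slice)
        artifact_masks.append(artifact)

    pairs = [
        LandmarkPair(
            fixed=lm_per_slice[z - 1],
            moving=lm_per_slice[z],
            warped=lm_per_slice[z],  # pre-registration: warped = moving
            diag_px=diag,
        )
        for z in range(1, nz)
    ]

    truth = PhantomTruth(
        vessel_masks=ref_masks,
        lumen_masks=lumen_masks,
        slice_masks=slice_masks,
        volume_truth=VoxelVolume(np.stack(ref_masks)),
        true_transforms=transforms,
        landmarks_ref=landmarks_ref,
        landmarks_per_slice=lm_per_slice,
        landmark_pairs=pairs,
        artifact_masks=artifact_masks,
        tissue_mask=_tissue_region(cfg),
    )
    return slices, truth


def generate_phantom(cfg: PhantomConfig | None = None) -> tuple[list[SliceImage], PhantomTruth]:
    """Convenience wrapper: generate the network and render the stack."""
    cfg = cfg or PhantomConfig()
    return render_stack(generate_network(cfg), cfg)
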
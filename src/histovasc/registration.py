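"""Two-step serial-section stack registration.

Step 1 estimates a transform between every consecutive slice pair
(2 onto 1, 3 onto 2, ...); each estimate is an independent task and its
result is serialized to a JSON file.  Step 2 aligns every slice to the first
one by composing the saved pairwise transforms along the chain
i -> i-1 -> ... -> 0; each composition is again independent, so both steps
parallelize over slices while remaining bit-deterministic for a fixed
configuration regardless of worker count.

A pairwise estimate is the similarity pre-alignment (rotation, scale,
translation, optional reflection) optionally refined by a free-form
deformation stage: per-node block matching on a coarse control lattice,
smoothed, and kept only when it improves the intensity metric by a
configured margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed
from scipy import ndimage
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation

from .image_io import SliceImage
from .preprocess import PreprocessConfig, _mse, _to_gray, prealign_similarity
from .transforms import (
    DeformationField,
    SliceTransform,
    TransformChain,
    compose,
    warp_image,
)

__all__ = [
    "RegistrationConfig",
    "SliceTransform",
    "TransformChain",
    "compose",
    "estimate_pairwise",
    "register_stack",
    "apply_transform",
]


@dataclass
class RegistrationConfig:
    #: resolution the estimation runs at; transforms are rescaled to full res
    working_scale: float = 0.25
    #: enable the free-form deformation refinement stage
    elastic: bool = True
    #: control-point lattice spacing at working resolution, px
    lattice_spacing_px: float = 64.0
    #: Gaussian smoothing (in lattice nodes) applied to the displacement field
    lattice_smooth_nodes: float = 1.0
    #: relative metric improvement required to keep the deformation
    elastic_margin: float = 0.05
    #: displacement cap, as a fraction of the lattice spacing
    max_displacement_frac: float = 0.5
    prealign: PreprocessConfig = field(default_factory=PreprocessConfig)


def _rescaled_similarity(t: SliceTransform, f: float) -> SliceTransform:
    """Conjugate the similarity part by a uniform coordinate scaling."""
    S = np.diag([f, f, 1.0])
    return SliceTransform(S @ t.matrix @ np.linalg.inv(S))


def _block_match_deformation(
    fixed: np.ndarray,
    warped: np.ndarray,
    cfg: RegistrationConfig,
) -> DeformationField | None:
    """Residual displacement per lattice node by local phase correlation.

    Returns the field such that warped(q - D(q)) ~= fixed(q); nodes whose
    patches carry no structure (near-constant) get zero displacement.
    """
    h, w = fixed.shape
    sp = cfg.lattice_spacing_px
    ny = int(np.floor((h - 1) / sp)) + 2
    nx = int(np.floor((w - 1) / sp)) + 2
    dx = np.zeros((ny, nx))
    dy = np.zeros((ny, nx))
    half = int(round(sp))
    cap = cfg.max_displacement_frac * sp
    for i in range(ny):
        for j in range(nx):
            cy, cx = int(round(i * sp)), int(round(j * sp))
            y0, y1 = max(0, cy - half), min(h, cy + half + 1)
            x0, x1 = max(0, cx - half), min(w, cx + half + 1)
            fp = fixed[y0:y1, x0:x1]
            wp = warped[y0:y1, x0:x1]
            if fp.size < 64 or fp.std() < 1e-3 or wp.std() < 1e-3:
                continue
            shift, _, _ = phase_cross_correlation(
                fp, wp, upsample_factor=4, normalization=None
            )
            if np.hypot(*shift) > cap:
                continue
            dy[i, j] = shift[0]
            dx[i, j] = shift[1]
    if cfg.lattice_smooth_nodes > 0:
        dx = ndimage.gaussian_filter(dx, cfg.lattice_smooth_nodes)
        dy = ndimage.gaussian_filter(dy, cfg.lattice_smooth_nodes)
    if max(np.abs(dx).max(), np.abs(dy).max()) < 1e-3:
        return None
    return DeformationField(sp, dx, dy)


def estimate_pairwise(
    fixed: SliceImage | np.ndarray,
    moving: SliceImage | np.ndarray,
    cfg: RegistrationConfig | None = None,
) -> SliceTransform:
    """Estimate the transform mapping ``moving`` onto ``fixed``.

    Similarity pre-alignment first; if the elastic stage is enabled, a
    residual deformation lattice is estimated on the similarity-warped image
    and kept only when it improves the mean-squared-intensity metric by at
    least ``elastic_margin`` (relative).  Both slices are expected to be
    preprocessed (white background, margin).
    """
    cfg = cfg or RegistrationConfig()
    fixed_gray = _to_gray(fixed)
    moving_gray = _to_gray(moving)

    sim = prealign_similarity(fixed_gray, moving_gray, cfg.prealign)
    if isinstance(moving, SliceImage):
        sim.source_index = moving.index
    if isinstance(fixed, SliceImage):
        sim.target_index = fixed.index
    if not cfg.elastic or sim.low_confidence:
        return sim

    # residual deformation is estimated at a reduced working resolution
    f = cfg.working_scale
    fixed_w = sktransform.rescale(fixed_gray, f, anti_aliasing=True)
    moving_w = sktransform.rescale(moving_gray, f, anti_aliasing=True)
    sim_w = _rescaled_similarity(sim, f)
    warped_w = warp_image(moving_w, sim_w, out_shape=fixed_w.shape, order=1, cval=1.0)
    mse_sim = _mse(fixed_w, warped_w)
    deform_w = _block_match_deformation(fixed_w, warped_w, cfg)
    if deform_w is None:
        return sim

    # lift the working-resolution field to full resolution
    deform = DeformationField(
        deform_w.spacing / f, deform_w.dx / f, deform_w.dy / f
    )
    candidate = SliceTransform(
        sim.matrix, deform, source_index=sim.source_index, target_index=sim.target_index
    )
    candidate_w = SliceTransform(sim_w.matrix, deform_w)
    warped_def = warp_image(moving_w, candidate_w, out_shape=fixed_w.shape, order=1, cval=1.0)
    mse_def = _mse(fixed_w, warped_def)
    if mse_def < (1.0 - cfg.elastic_margin) * mse_sim:
        return candidate
    return sim


def _safe_pairwise(
    fixed: SliceImage, moving: SliceImage, cfg: RegistrationConfig
) -> SliceTransform:
    try:
        return estimate_pairwise(fixed, moving, cfg)
    except Exception as exc:  # noqa: BLE001 - chain must survive a bad pair
        warnings.warn(
            f"pairwise registration {moving.index}->{fixed.index} failed ({exc}); "
            "using identity stand-in",
            stacklevel=2,
        )
        ident = SliceTransform.identity(moving.index, fixed.index)
        ident.low_confidence = True
        return ident


def register_stack(
    stack: list[SliceImage],
    cfg: RegistrationConfig | None = None,
    workers: int = 1,
    transforms_dir: str | Path | None = None,
) -> list[SliceTransform]:
    """Align every slice to the first one (slice 0 is the untransformed
    reference).  Returns one transform per slice, element i mapping slice i's
    coordinates into slice 0's frame; element 0 is the identity.

    If ``transforms_dir`` is given, the step-1 pairwise transforms are saved
    there as ``pairwise_{i:04d}_to_{i-1:04d}.json`` before composition.
    """
    cfg = cfg or RegistrationConfig()
    if len(stack) < 2:
        raise ValueError("register_stack needs at least 2 slices")

    pairs = [(stack[i - 1], stack[i]) for i in range(1, len(stack))]
    pairwise = Parallel(n_jobs=workers)(
        delayed(_safe_pairwise)(f, m, cfg) for f, m in pairs
    )

    if transforms_dir is not None:
        d = Path(transforms_dir)
        d.mkdir(parents=True, exist_ok=True)
        for t in pairwise:
            t.save(d / f"pairwise_{t.source_index:04d}_to_{t.target_index:04d}.json")

    shape = stack[0].shape

    def _compose_chain(i: int) -> SliceTransform:
        # chain ordered target-first: [T_{1->0}, T_{2->1}, ..., T_{i->i-1}]
        chain = TransformChain(pairwise[:i])
        return compose(chain, lattice_shape=shape)

    composed = Parallel(n_jobs=workers)(
        delayed(_compose_chain)(i) for i in range(1, len(stack))
    )
    result = [SliceTransform.identity(0, 0)] + list(composed)
    for i, t in enumerate(result):
        t.source_index = i
        t.target_index = 0
    return result


def apply_transform(
    image: SliceImage | np.ndarray,
    t: SliceTransform,
    out_shape: tuple[int, int] | None = None,
) -> SliceImage | np.ndarray:
    """Warp an image or mask into the transform's target frame.

    Intensity rasters get bilinear interpolation with white fill; boolean
    masks get nearest-neighbor with zero (background) fill.
    """
    if isinstance(image, SliceImage):
        warped = warp_image(image.pixels, t, out_shape=out_shape, order=1, cval=255.0)
        return SliceImage(warped, index=image.index, pixel_size_um=image.pixel_size_um)
    arr = np.asarray(image)
    if arr.dtype == bool:
        return warp_image(arr, t, out_shape=out_shape, order=0, cval=0.0)
    cval = 255.0 if np.issubdtype(arr.dtype, np.integer) else 1.0
    return warp_image(arr, t, out_shape=out_shape, order=1, cval=cval)
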
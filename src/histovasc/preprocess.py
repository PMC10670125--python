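"""Slice preparation for registration.

Three operations, applied in order per slice:

1. ``whiten_background`` — replace every pixel that is not tissue with pure
   white.  Non-tissue is detected as near-white pixels connected to the image
   border, so bright vessel lumina *inside* tissue are never touched (they
   are the segmentation signal).
2. ``add_margin`` — pad each side with a white margin (default 12.5% of the
   image size per side) so that rotation during registration cannot push
   tissue out of frame.
3. ``prealign_similarity`` — estimate a similarity transform (rotation,
   isotropic scale, translation, optional reflection) between consecutive
   slices by multi-start, multi-resolution optimization of a
   gradient-magnitude dissimilarity.  No elastic deformation is estimated
   here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage import color, measure, transform as sktransform
from skimage.registration import phase_cross_correlation

from .image_io import SliceImage
from .transforms import SliceTransform, warp_image

__all__ = ["PreprocessConfig", "whiten_background", "add_margin", "prealign_similarity", "preprocess_slice"]

WHITE = np.uint8(255)


@dataclass
class PreprocessConfig:
    #: white margin added on EACH side, as a fraction of that dimension
    margin_fraction: float = 0.125
    #: min-channel intensity fraction above which a pixel counts as near-white
    background_threshold: float = 0.88
    #: tissue specks in the background smaller than this are whitened too
    min_tissue_component_px: int = 64
    # similarity pre-alignment search
    prealign_scales: tuple[float, ...] = (0.25, 0.5)
    rotation_search_deg: float = 20.0
    rotation_search_step: float = 2.0
    try_reflection: bool = True
    #: coarse candidates refined before committing to one basin
    multi_start: int = 3
    max_opt_iter: int = 30
    max_opt_iter_final: int = 6

    def __post_init__(self) -> None:
        if not (0.0 <= self.margin_fraction <= 0.5):
            raise ValueError("margin_fraction must be in [0, 0.5]")
        if not (0.0 < self.background_threshold < 1.0):
            raise ValueError("background_threshold must be in (0, 1)")


def _near_white(pixels: np.ndarray, threshold: float) -> np.ndarray:
    # min over channels: stained (pink/gray) tissue always dips in one channel
    return pixels.min(axis=2) >= threshold * 255.0


def whiten_background(image: SliceImage, cfg: PreprocessConfig | None = None) -> SliceImage:
    """Replace the non-tissue area (near-white, border-connected) with pure white.

    Idempotent; interior bright regions such as vessel lumina are preserved
    because they are not connected to the image border.
    """
    cfg = cfg or PreprocessConfig()
    bright = _near_white(image.pixels, cfg.background_threshold)
    labels = measure.label(bright, connectivity=2)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    background = np.isin(labels, border_labels)

    # whiten small tissue debris floating in the background
    if cfg.min_tissue_component_px > 0:
        tissue_labels = measure.label(~background, connectivity=2)
        counts = np.bincount(tissue_labels.ravel())
        small = np.flatnonzero(counts < cfg.min_tissue_component_px)
        small = small[small != 0]
        if small.size:
            background |= np.isin(tissue_labels, small)

    out = image.pixels.copy()
    out[background] = WHITE
    return SliceImage(out, index=image.index, pixel_size_um=image.pixel_size_um)


def add_margin(
    image: SliceImage, cfg: PreprocessConfig | None = None
) -> tuple[SliceImage, tuple[int, int]]:
    """Pad the slice with a white margin on each side.

    Output size per axis is ceil(dim * (1 + 2*margin_fraction)); the original
    content is centered and the returned (offset_x, offset_y) maps original
    coordinates into the padded frame.
    """
    cfg = cfg or PreprocessConfig()
    h, w = image.shape
    if cfg.margin_fraction == 0:
        return image, (0, 0)
    new_h = int(np.ceil(h * (1.0 + 2.0 * cfg.margin_fraction)))
    new_w = int(np.ceil(w * (1.0 + 2.0 * cfg.margin_fraction)))
    off_y = (new_h - h) // 2
    off_x = (new_w - w) // 2
    out = np.full((new_h, new_w, 3), WHITE, dtype=np.uint8)
    out[off_y : off_y + h, off_x : off_x + w] = image.pixels
    return (
        SliceImage(out, index=image.index, pixel_size_um=image.pixel_size_um),
        (off_x, off_y),
    )


def preprocess_slice(
    image: SliceImage, cfg: PreprocessConfig | None = None
) -> tuple[SliceImage, tuple[int, int]]:
    """whiten_background followed by add_margin."""
    cfg = cfg or PreprocessConfig()
    return add_margin(whiten_background(image, cfg), cfg)


# ---------------------------------------------------------------------------
# similarity pre-alignment
# ---------------------------------------------------------------------------

def _to_gray(image: SliceImage | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, SliceImage) else np.asarray(image)
    if arr.ndim == 3:
        gray = color.rgb2gray(arr)
    else:
        gray = arr.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    return gray


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _grad_mag(gray: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(gray)
    return np.hypot(gy, gx)


def _gradient_mse(fixed_grad: np.ndarray, warped: np.ndarray) -> float:
    """Mean squared difference of gradient magnitudes.

    The alignment signal lives in edges (vessel walls, the tissue boundary);
    a plain intensity MSE is dominated by the large uniform white frame and
    tissue block and can prefer a visibly wrong pose, while the gradient
    metric ranks poses by how well those edges coincide.
    """
    return _mse(fixed_grad, _grad_mag(warped))


def _warp_gray(moving: np.ndarray, t: SliceTransform, out_shape: tuple[int, int]) -> np.ndarray:
    return warp_image(moving, t, out_shape=out_shape, order=1, cval=1.0)


def _make_t(params: np.ndarray, reflection: bool, center: tuple[float, float]) -> SliceTransform:
    # parameters are scaled to comparable magnitudes for the optimizer:
    # [rotation deg, 100*log(scale), tx px, ty px]
    rot, scaled_log_scale, tx, ty = params
    return SliceTransform.from_params(
        rotation_deg=rot,
        scale=float(np.exp(scaled_log_scale / 100.0)),
        reflection=reflection,
        translation=(tx, ty),
        center=center,
    )


def _tissue_centroid(gray: np.ndarray, white_cut: float = 0.95) -> np.ndarray | None:
    """(x, y) centroid of non-white (tissue) pixels, or None if none."""
    tissue = gray < white_cut
    if not tissue.any():
        return None
    ys, xs = np.nonzero(tissue)
    return np.array([xs.mean(), ys.mean()])


def _coarse_candidates(
    fixed: np.ndarray,
    moving: np.ndarray,
    cfg: PreprocessConfig,
) -> list[tuple[float, np.ndarray, bool]]:
    """Scored (mse, params, reflection) candidates from a grid search over
    rotation (and reflection) at the coarsest pyramid level; sorted
    best-first.

    The translation for each rotation candidate comes from the difference of
    tissue centroids (fixed vs rotated moving): with a mostly white frame a
    phase correlation locks onto the white margin instead of the tissue, so
    the centroid shift is the more reliable initializer.
    """
    h, w = fixed.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    rots = np.arange(-cfg.rotation_search_deg, cfg.rotation_search_deg + 1e-9, cfg.rotation_search_step)
    reflections = (False, True) if cfg.try_reflection else (False,)
    c_fixed = _tissue_centroid(fixed)
    fixed_grad = _grad_mag(fixed)
    cands: list[tuple[float, np.ndarray, bool]] = []
    for refl in reflections:
        for rot in rots:
            t0 = _make_t(np.array([rot, 0.0, 0.0, 0.0]), refl, center)
            rotated = _warp_gray(moving, t0, fixed.shape)
            c_rot = _tissue_centroid(rotated)
            if c_fixed is not None and c_rot is not None:
                shift_xy = c_fixed - c_rot
            else:
                shift, _, _ = phase_cross_correlation(fixed, rotated, normalization=None)
                shift_xy = np.array([shift[1], shift[0]])
            params = np.array([rot, 0.0, shift_xy[0], shift_xy[1]])
            score = _gradient_mse(
                fixed_grad, _warp_gray(moving, _make_t(params, refl, center), fixed.shape)
            )
            cands.append((score, params, refl))
    cands.sort(key=lambda c: c[0])
    return cands


def prealign_similarity(
    fixed: SliceImage | np.ndarray,
    moving: SliceImage | np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> SliceTransform:
    """Estimate the similarity transform mapping ``moving`` onto ``fixed``.

    Multi-resolution pyramid; at the coarsest level rotation (and optional
    reflection) are grid-searched with tissue-centroid translation, then a
    gradient-free local optimizer (Powell) refines (rotation, log-scale,
    translation) against a gradient-magnitude dissimilarity at each finer
    level, with several candidate basins carried upward before committing.
    If the optimum does not beat the identity map the identity is returned
    flagged ``low_confidence``.
    """
    cfg = cfg or PreprocessConfig()
    fixed_gray = _to_gray(fixed)
    moving_gray = _to_gray(moving)
    if fixed_gray.shape != moving_gray.shape:
        raise ValueError("fixed and moving slices must share dimensions")

    h, w = fixed_gray.shape
    center_full = ((w - 1) / 2.0, (h - 1) / 2.0)

    # candidate basins carried up the pyramid: the intensity metric has local
    # minima when distinct vessels overlap under a wrong pose, and the wrong
    # basin can even win at coarse resolution, so the commitment to a single
    # candidate is deferred to the finest level
    survivors: list[tuple[np.ndarray, bool]] = []
    prev_scale = None
    for li, scale in enumerate(cfg.prealign_scales):
        f = sktransform.rescale(fixed_gray, scale, anti_aliasing=True)
        m = sktransform.rescale(moving_gray, scale, anti_aliasing=True)
        hs, ws = f.shape
        center = ((ws - 1) / 2.0, (hs - 1) / 2.0)
        f_grad = _grad_mag(f)
        last = li == len(cfg.prealign_scales) - 1
        # the finest level starts from a near-converged pose: few iterations
        maxiter = cfg.max_opt_iter_final if last else cfg.max_opt_iter

        def score_of(p: np.ndarray, refl: bool) -> float:
            return _gradient_mse(f_grad, _warp_gray(m, _make_t(p, refl, center), f.shape))

        def refine(p0: np.ndarray, refl: bool) -> tuple[float, np.ndarray]:
            res = optimize.minimize(
                lambda p: score_of(p, refl),
                p0,
                method="Powell",
                options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-8},
            )
            return float(res.fun), res.x

        if li == 0:
            cands = _coarse_candidates(f, m, cfg)
            starts: list[tuple[np.ndarray, bool]] = []
            for _, p0, refl in cands:
                if len(starts) >= max(1, cfg.multi_start):
                    break
                if any(
                    r == refl and abs(p0[0] - q[0]) < 1.5 * cfg.rotation_search_step
                    for q, r in starts
                ):
                    continue
                starts.append((p0, refl))
        else:
            factor = scale / prev_scale
            rescaled = [
                (p * np.array([1.0, 1.0, factor, factor]), r) for p, r in survivors
            ]
            rescaled.sort(key=lambda s: score_of(*s))
            # narrow the field as levels get costlier; the last level
            # refines only the winner of the full-resolution scoring
            n_keep = 1 if last else 2
            starts = rescaled[:n_keep]

        survivors = [(refine(p0, refl)[1], refl) for p0, refl in starts]
        prev_scale = scale

    params, reflection = min(survivors, key=lambda s: score_of(*s))

    # rescale translation to full resolution
    factor = 1.0 / cfg.prealign_scales[-1]
    params_full = params * np.array([1.0, 1.0, factor, factor])
    result = _make_t(params_full, reflection, center_full)

    full_grad = _grad_mag(fixed_gray)
    final_score = _gradient_mse(full_grad, _warp_gray(moving_gray, result, fixed_gray.shape))
    identity_score = _gradient_mse(full_grad, moving_gray)
    if not np.isfinite(final_score) or final_score > identity_score:
        warnings.warn(
            "similarity pre-alignment did not improve on identity; returning identity",
            stacklevel=2,
        )
        ident = SliceTransform.identity()
        ident.low_confidence = True
        return ident

    if isinstance(moving, SliceImage):
        result.source_index = moving.index
    if isinstance(fixed, SliceImage):
        result.target_index = fixed.index
    return result
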
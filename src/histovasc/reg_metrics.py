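"""Registration validation metrics.

For an image pair (i, j) with annotated corresponding features, three
quantities describe registration quality:

* relative target registration error, per feature l:
      rTRE_l = ||x̂_l - x_l^j||_2 / d_j
  the distance between the registered (warped) feature position x̂_l and its
  true position x_l^j in the fixed image j, normalized by the diagonal d_j of
  the fixed image;
* relative initial registration error rIRE_l — the same distance measured
  before registration, i.e. between the raw moving position and x_l^j;
* robustness R = (1/L) Σ_l k_l with k_l = 1 iff rTRE_l < rIRE_l (strictly):
  the fraction of features the registration actually improved.

Stack-level summaries are the average over pairs of the per-pair median rTRE
and the average per-pair robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import LandmarkSet

__all__ = ["LandmarkPair", "PairScore", "rtre", "rire", "robustness", "score_pair", "summarize"]


@dataclass
class LandmarkPair:
    """Corresponding features for one image pair (moving i -> fixed j)."""

    fixed: LandmarkSet    # true positions x_l in the fixed image j
    moving: LandmarkSet   # positions x_l in the moving image i (pre-registration)
    warped: LandmarkSet   # registered positions x̂_l, in the fixed frame
    diag_px: float        # diagonal d_j of the fixed image, pixels

    def __post_init__(self) -> None:
        n = len(self.fixed)
        if len(self.moving) != n or len(self.warped) != n:
            raise ValueError("fixed, moving and warped landmark sets must have equal length")
        if not self.diag_px > 0:
            raise ValueError("diag_px must be positive")


@dataclass
class PairScore:
    rtre_per_feature: np.ndarray
    rire_per_feature: np.ndarray
    median_rtre: float
    robustness: float


def _relative_errors(a: np.ndarray, b: np.ndarray, diag: float) -> np.ndarray:
    return np.linalg.norm(a - b, axis=1) / diag


def rtre(pair: LandmarkPair) -> np.ndarray:
    """Per-feature relative target registration error."""
    return _relative_errors(pair.warped.points, pair.fixed.points, pair.diag_px)


def rire(pair: LandmarkPair) -> np.ndarray:
    """Per-feature relative initial registration error (uses the raw moving
    positions; the warped positions play no role)."""
    return _relative_errors(pair.moving.points, pair.fixed.points, pair.diag_px)


def robustness(pair: LandmarkPair) -> float:
    """Fraction of features strictly improved by registration.

    A feature counts as improved only when rTRE < rIRE; ties (including the
    identity registration, where every feature is unchanged) do not count.
    """
    if len(pair.fixed) == 0:
        raise ValueError("robustness undefined for an empty feature set")
    return float(np.mean(rtre(pair) < rire(pair)))


def score_pair(pair: LandmarkPair) -> PairScore:
    t = rtre(pair)
    i = rire(pair)
    return PairScore(
        rtre_per_feature=t,
        rire_per_feature=i,
        median_rtre=float(np.median(t)),
        robustness=float(np.mean(t < i)),
    )


def summarize(scores: list[PairScore]) -> tuple[float, float]:
    """(average of per-pair median rTRE, average per-pair robustness)."""
    if not scores:
        raise ValueError("summarize requires at least one pair score")
    return (
        float(np.mean([s.median_rtre for s in scores])),
        float(np.mean([s.robustness for s in scores])),
    )
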
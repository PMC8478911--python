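"""Underwater color balancing for photoquadrats.

Water absorbs red light first, leaving shallow-reef imagery with a
green/blue cast.  The corrector here (i) raises every pixel's red value
by a constant additive offset proportional to the image-average green and
blue values, then (ii) scales all channels down by a brightness fraction
to tame overexposure.  Both steps round half-up and clip to 8-bit range;
the operator is deliberately simple so a chosen correction is exactly
reproducible from its two parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .rectify import _validate_image


@dataclass(frozen=True)
class BalanceParams:
    """alpha: red gain against the mean green/blue level (>= 0);
    beta: fraction of overall brightness removed (0 <= beta < 1)."""

    alpha: float = 0.3
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must lie in [0, 1)")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def balance(img: np.ndarray, params: BalanceParams | None = None) -> np.ndarray:
    """Apply the red-raise / brightness-reduction operator.

    Step 1: ``R' = R + alpha * (mean(G) + mean(B)) / 2`` per pixel (green
    and blue unchanged).  Step 2: every channel multiplied by
    ``1 - beta``.  Rounding half-up and clipping to [0, 255] after each
    step; output shape equals input shape.
    """
    img = _validate_image(img)
    params = params or BalanceParams()
    g_mean = float(img[:, :, 1].mean())
    b_mean = float(img[:, :, 2].mean())
    out = img.astype(float).copy()
    out[:, :, 0] = np.clip(
        _round_half_up(out[:, :, 0] + params.alpha * (g_mean + b_mean) / 2.0), 0, 255
    )
    out = np.clip(_round_half_up(out * (1.0 - params.beta)), 0, 255)
    return out.astype(np.uint8)


def cast_reduction_score(before: np.ndarray, after: np.ndarray) -> float:
    """Change in the red-vs-green/blue imbalance ``|mean(R) - (mean(G) +
    mean(B))/2|`` from ``before`` to ``after``; negative means the cast
    was reduced."""
    before = _validate_image(before)
    after = _validate_image(after)
    if before.shape != after.shape:
        raise ValueError("images must share dimensions")

    def cast(im: np.ndarray) -> float:
        r, g, b = (float(im[:, :, c].mean()) for c in range(3))
        return abs(r - (g + b) / 2.0)

    return cast(after) - cast(before)


def auto_alpha(img: np.ndarray) -> float:
    """Red gain that would equalize the red mean with the mean green/blue
    level in one additive step: ``(mean(G)+mean(B)-2*mean(R)) / (mean(G)+mean(B))``,
    floored at 0 (a red-dominant image needs no raise)."""
    img = _validate_image(img)
    r = float(img[:, :, 0].mean())
    gb = float(img[:, :, 1].mean()) + float(img[:, :, 2].mean())
    if gb == 0:
        return 0.0
    return max(0.0, (gb - 2.0 * r) / gb)


class ColorBalancer(BaseEstimator):
    """Stateless transformer applying :func:`balance` with fixed
    parameters; composes with the other image-stage estimators."""

    def __init__(self, alpha: float = 0.3, beta: float = 0.1):
        self.alpha = alpha
        self.beta = beta

    def fit(self, img: np.ndarray = None, y=None) -> "ColorBalancer":
        self.params_ = BalanceParams(self.alpha, self.beta)
        return self

    def transform(self, img: np.ndarray) -> np.ndarray:
        return balance(img, BalanceParams(self.alpha, self.beta))

    def fit_transform(self, img: np.ndarray, y=None) -> np.ndarray:
        return self.fit(img).transform(img)
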
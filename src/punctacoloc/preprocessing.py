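"""Optional per-channel noise reduction and brightness normalisation.

Applied after RGB conversion and before thresholding, in a fixed order:
rolling-ball background subtraction, then Gaussian blur, then (optionally)
brightness normalisation.  Preprocessing modifies the data the analysis
sees, so it is off by default and the applied configuration is logged per
image to keep analyses replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Preprocessing switches and parameters.

    Defaults: rolling-ball radius 50 px and blur sigma 1 px comfortably
    exceed typical punctum diameters, so puncta survive the background
    estimate; saturated_fraction 0.0035 follows the common enhance-contrast
    convention.  All are tunable.
    """

    enable_noise_reduction: bool = False
    rolling_ball_radius: float = 50.0
    blur_sigma: float = 1.0
    enable_brightness_norm: bool = False
    saturated_fraction: float = 0.0035

    def __post_init__(self) -> None:
        if self.rolling_ball_radius <= 0:
            raise ValueError("rolling_ball_radius must be > 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0 <= self.saturated_fraction < 1:
            raise ValueError("saturated_fraction must be in [0, 1)")


def _check_plane(plane: np.ndarray) -> None:
    if plane.ndim != 2 or plane.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) 2D plane")


def subtract_background(plane: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Subtract a rolling-ball background estimate from a plane.

    A ball of the given radius is rolled under the intensity surface; the
    resulting smooth background is subtracted and the output clipped to
    [0, 255].  A spatially constant plane maps to (near-)zero, and output
    never exceeds input pixelwise.
    """
    _check_plane(plane)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if radius >= min(plane.shape):
        logger.warning(
            "rolling-ball radius %g >= smallest image dimension %d; the "
            "background estimate will be nearly global",
            radius,
            min(plane.shape),
        )
    background = rolling_ball(plane, radius=radius)
    out = plane.astype(np.int16) - np.ceil(background).astype(np.int16)
    return np.clip(out, 0, 255).astype(np.uint8)


def gaussian_blur(plane: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Standard Gaussian convolution with reflecting boundaries.

    ``sigma=0`` is the identity.  Total intensity is conserved to within
    rounding for signals supported in the image interior.
    """
    _check_plane(plane)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return plane.copy()
    blurred = ndimage.gaussian_filter(plane.astype(np.float64), sigma=sigma, mode="reflect")
    return np.clip(np.floor(blurred + 0.5), 0, 255).astype(np.uint8)


def normalize_brightness(plane: np.ndarray, saturated_fraction: float = 0.0035) -> np.ndarray:
    """Linearly rescale so a fixed fraction of pixels saturates at 255.

    The (1 - saturated_fraction) intensity quantile is mapped to 255 and the
    minimum to 0, clipping above; afterwards the fraction of pixels at 255 is
    at least ``saturated_fraction`` (intensity ties can push it higher).
    Normalising every image of an experiment this way equalises the
    percentage of saturated pixels across images.
    """
    _check_plane(plane)
    if not 0 <= saturated_fraction < 1:
        raise ValueError("saturated_fraction must be in [0, 1)")
    lo = int(plane.min())
    hi = int(plane.max())
    if hi == lo:
        logger.warning("constant plane has no dynamic range; brightness left unchanged")
        return plane.copy()
    if saturated_fraction > 0:
        # 'lower' interpolation guarantees >= saturated_fraction of pixels
        # sit at or above the chosen quantile value.
        q = int(np.quantile(plane, 1.0 - saturated_fraction, method="lower"))
        hi = max(q, lo + 1)
    scale = 255.0 / (hi - lo)
    out = np.floor((plane.astype(np.float64) - lo) * scale + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def preprocess_plane(plane: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Apply the configured preprocessing chain to one channel plane."""
    out = plane
    if config.enable_noise_reduction:
        out = subtract_background(out, config.rolling_ball_radius)
        out = gaussian_blur(out, config.blur_sigma)
    if config.enable_brightness_norm:
        out = normalize_brightness(out, config.saturated_fraction)
    return out if out is not plane else plane.copy()
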
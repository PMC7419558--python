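"""Space-variant adaptive Wiener denoising of projection images.

The filter shrinks each pixel toward its local window mean by a factor set
by the local excess variance over an assumed additive noise floor:

    out = m + max(s2 - n2, 0) / max(s2, n2) * (in - m)

with m the local mean, s2 the local (unbiased) variance and n2 the noise
variance.  A zero noise variance makes the filter the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from tomotex.errors import ParameterError


@dataclass(frozen=True)
class WienerConfig:
    window: int = 5
    noise_variance: Union[float, str] = "auto"

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ParameterError(f"window must be odd and >= 3; got {self.window}")
        if not isinstance(self.noise_variance, str) and self.noise_variance < 0:
            raise ParameterError("noise_variance must be nonnegative")


def _local_moments(image: np.ndarray, window: int) -> tuple:
    """Local mean and unbiased variance over a window, symmetric-reflect edges."""
    n = window * window
    mean = ndimage.uniform_filter(image, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(image * image, size=window, mode="reflect")
    var = (mean_sq - mean * mean) * (n / (n - 1))
    return mean, np.maximum(var, 0.0)


def adaptive_wiener(image: np.ndarray, config: WienerConfig = WienerConfig()) -> np.ndarray:
    """Apply the space-variant Wiener filter to one 2D projection."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("adaptive_wiener expects a 2D image")
    if not np.all(np.isfinite(image)):
        raise ParameterError("image must be finite-valued")
    if config.window >= min(image.shape):
        raise ParameterError(
            f"window {config.window} must be smaller than the image {image.shape}"
        )

    if isinstance(config.noise_variance, str):
        if config.noise_variance != "auto":
            raise ParameterError(f"unknown noise_variance mode {config.noise_variance!r}")
        n2 = estimate_noise_variance(image, window=config.window)
    else:
        n2 = float(config.noise_variance)

    if n2 == 0.0:
        return image.copy()

    mean, var = _local_moments(image, config.window)
    gain = np.maximum(var - n2, 0.0) / np.maximum(var, n2)
    return mean + gain * (image - mean)


def estimate_noise_variance(image: np.ndarray, window: int = 5) -> float:
    """Robust noise-floor estimate: median of local window variances."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("estimate_noise_variance expects a 2D image")
    if window >= min(image.shape):
        raise ParameterError("image must be larger than the estimation window")
    _, var = _local_moments(image, window)
    return float(np.median(var))


def filter_projection_set(pset, config: WienerConfig = WienerConfig()):
    """Filter every view of a ProjectionSet, preserving geometry and metadata."""
    from dataclasses import replace

    filtered = np.stack([adaptive_wiener(im, config) for im in pset.images])
    meta = dict(pset.noise_meta)
    meta["wiener"] = {"window": config.window, "noise_variance": config.noise_variance}
    return replace(pset, images=filtered, noise_meta=meta)
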
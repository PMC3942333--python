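"""Per-pixel texture descriptors from an undecimated Haar wavelet frame.

The analysis uses the unnormalized Haar pair H(z) = (1 + z)/2 (moving
average) and G(z) = (z - 1)/2 (half difference), applied along the axial
(row) direction where OCT layer texture varies most, and repeated for
four levels with the a-trous scheme: at level l the two taps are spread
2^(l-1) samples apart, so every subband keeps the input's size and the
transform is shift-invariant.  The per-pixel descriptor is the local
energy (windowed mean of squared coefficients) of the four detail
subbands plus the level-4 approximation -- a 5-vector per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .core import BScanImage

__all__ = [
    "HaarFilterPair",
    "SubbandStack",
    "FeatureStack",
    "wavelet_frame_decompose",
    "energy_features",
    "extract_descriptors",
]


@dataclass(frozen=True)
class HaarFilterPair:
    """Level-1 analysis filters of the unnormalized Haar frame."""

    lowpass: tuple[float, float] = (0.5, 0.5)
    highpass: tuple[float, float] = (-0.5, 0.5)


@dataclass
class SubbandStack:
    """Undecimated wavelet subbands, all with the input image's shape."""

    details: list[np.ndarray]
    approximation: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError("one detail plane per level expected")
        shape = self.approximation.shape
        if any(d.shape != shape for d in self.details):
            raise ValueError("all subband planes must share one shape")


@dataclass
class FeatureStack:
    """Per-pixel texture-energy descriptors.

    ``features`` has shape ``(n_features, n_rows, n_cols)`` ordered as
    detail energies of levels 1..L followed by the level-L approximation
    energy; with the default 4 levels this is the 5-dimensional
    descriptor the mixture model consumes.
    """

    features: np.ndarray
    window: int = 9

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 3:
            raise ValueError("feature stack must be (n_features, rows, cols)")
        if np.any(self.features < 0):
            raise ValueError("energy features must be non-negative")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.features.shape[1:]

    def descriptors(self) -> np.ndarray:
        """Pixel-major view: shape ``(n_pixels, n_features)``."""
        n = self.n_features
        return self.features.reshape(n, -1).T


def _analysis_step(approx: np.ndarray, spacing: int) -> tuple[np.ndarray, np.ndarray]:
    """One a-trous Haar step along rows with symmetric extension.

    low[n]  = (a[n] + a[n + s]) / 2
    high[n] = (a[n + s] - a[n]) / 2
    """
    padded = np.pad(approx, ((0, spacing), (0, 0)), mode="symmetric")
    shifted = padded[spacing : spacing + approx.shape[0]]
    return (approx + shifted) / 2.0, (shifted - approx) / 2.0


def wavelet_frame_decompose(image: BScanImage, levels: int = 4) -> SubbandStack:
    """Four-level (by default) undecimated Haar decomposition along rows."""
    if levels < 1:
        raise ValueError("levels must be at least 1")
    if 2 ** (levels - 1) >= image.n_rows:
        raise ValueError(
            f"level-{levels} filter spans {2 ** (levels - 1) + 1} rows, "
            f"more than the image's {image.n_rows}"
        )
    approx = image.pixels.astype(float)
    details: list[np.ndarray] = []
    for level in range(1, levels + 1):
        approx, detail = _analysis_step(approx, 2 ** (level - 1))
        details.append(detail)
    return SubbandStack(details=details, approximation=approx, levels=levels)


def energy_features(subbands: SubbandStack, window: int = 9) -> FeatureStack:
    """Windowed mean of squared coefficients for every subband.

    ``window`` is the side of the square averaging neighborhood and must
    be odd; ``window=1`` degenerates to element-wise squaring.  Borders
    are handled by symmetric extension.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("energy window must be odd and >= 1")
    planes = [*subbands.details, subbands.approximation]
    energies = [
        uniform_filter(p * p, size=window, mode="reflect") for p in planes
    ]
    # uniform_filter can round slightly below zero on all-zero planes
    stack = np.maximum(np.stack(energies), 0.0)
    return FeatureStack(features=stack, window=window)


def extract_descriptors(
    image: BScanImage, levels: int = 4, window: int = 9
) -> FeatureStack:
    """Full descriptor extraction: wavelet frame then local energies."""
    return energy_features(wavelet_frame_decompose(image, levels=levels), window=window)
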
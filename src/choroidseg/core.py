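"""Core containers for EDI-OCT B-scans and layer boundary curves.

Conventions used throughout the package:

* images are stored rows x columns, with row 0 at the top (inner retina)
  and rows increasing with depth; each column is one A-scan;
* boundary curves store one axial row coordinate per image column,
  0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BScanImage", "BoundaryCurve"]


@dataclass
class BScanImage:
    """A single grayscale EDI-OCT B-scan.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (arbitrary units),
        shape ``(n_rows, n_cols)``.
    axial_res_um
        Axial (depth) pixel size in micrometers. The Spectralis EDI
        protocol this package targets samples at 3.9 um/pixel.
    transversal_res_um
        Transversal pixel size in micrometers (14 um/pixel on the same
        protocol).
    """

    pixels: np.ndarray
    axial_res_um: float = 3.9
    transversal_res_um: float = 14.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("B-scan pixels must be a 2-D array")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("B-scan must be at least 2x2 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("B-scan intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("B-scan intensities must be non-negative")
        if self.axial_res_um <= 0 or self.transversal_res_um <= 0:
            raise ValueError("pixel resolutions must be positive")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BoundaryCurve:
    """A layer boundary: one axial row index per image column."""

    rows: np.ndarray = field()

    def __post_init__(self) -> None:
        self.rows = np.atleast_1d(np.asarray(self.rows))
        if self.rows.ndim != 1:
            raise ValueError("boundary rows must be 1-D")
        if self.rows.size < 1:
            raise ValueError("boundary curve must cover at least one column")
        if not np.all(np.isfinite(self.rows.astype(float))):
            raise ValueError("boundary rows must be finite")

    @property
    def n_cols(self) -> int:
        return self.rows.size

    def validate_for(self, image: BScanImage) -> None:
        """Check that the curve is consistent with ``image``."""
        if self.n_cols != image.n_cols:
            raise ValueError(
                f"boundary covers {self.n_cols} columns but image has "
                f"{image.n_cols}"
            )
        if np.any(self.rows < 0) or np.any(self.rows > image.n_rows - 1):
            raise ValueError("boundary rows fall outside the image")
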
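"""Normalized Difference Vegetation Index band arithmetic.

NDVI = (NIR - RED) / (NIR + RED) elementwise over two co-registered
reflectance arrays, bounded in [-1, 1] and invariant to a common
positive rescaling of both bands.  Elements where NIR + RED = 0 (no
signal) are masked invalid, as are elements masked on input.  This is
pure array computation: no georeferencing and no raster file parsing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandPair", "compute_ndvi", "mean_ndvi"]


@dataclass(frozen=True)
class BandPair:
    """Co-registered NIR and RED reflectance arrays with an optional validity mask.

    ``mask`` follows the numpy.ma convention: True marks INVALID elements.
    """

    nir: np.ndarray
    red: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        nir = np.asarray(self.nir, dtype=float)
        red = np.asarray(self.red, dtype=float)
        if nir.shape != red.shape:
            raise ValueError(f"band shapes differ: {nir.shape} vs {red.shape}")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != nir.shape:
                raise ValueError(f"mask shape {mask.shape} does not match bands {nir.shape}")
            object.__setattr__(self, "mask", mask)
        valid = ~self.mask if self.mask is not None else np.ones(nir.shape, dtype=bool)
        if np.any(nir[valid] < 0) or np.any(red[valid] < 0):
            raise ValueError("reflectances must be non-negative")
        object.__setattr__(self, "nir", nir)
        object.__setattr__(self, "red", red)


def compute_ndvi(bands: BandPair) -> np.ma.MaskedArray:
    """Elementwise (NIR - RED)/(NIR + RED); zero-sum elements come back masked."""
    total = bands.nir + bands.red
    invalid = total == 0.0
    if bands.mask is not None:
        invalid = invalid | bands.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(invalid, 0.0, (bands.nir - bands.red) / np.where(invalid, 1.0, total))
    return np.ma.MaskedArray(values, mask=invalid)


def mean_ndvi(values: np.ndarray | np.ma.MaskedArray, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean over valid elements; errors if nothing is valid."""
    if mask is not None:
        values = np.ma.MaskedArray(np.asarray(values, dtype=float), mask=np.asarray(mask, bool))
    elif not isinstance(values, np.ma.MaskedArray):
        values = np.ma.MaskedArray(np.asarray(values, dtype=float))
    if values.count() == 0:
        raise ValueError("no valid NDVI elements to average")
    return float(values.mean())
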
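"""1-D intensity profiles and discrete derivatives.

The defocus metric lives entirely in one dimension: a field image is
reduced to a per-column profile (mean over a centered band of rows), and
edges are found on its forward differences

    G[i] = p[i+1] - p[i]            (first order)
    S[i] = p[i+2] - 2 p[i+1] + p[i] (second order)

The forward difference of sample i straddles pixels i and i+1, so it is
assigned coordinate x0 + i + 0.5; a symmetric edge then yields a symmetric
gradient extremum.  Second-order sample i is centered at x0 + i + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .optics import FieldImage


@dataclass
class IntensityProfile:
    """Per-column intensity values with provenance of the row band used."""

    values: np.ndarray
    x0: float = 0.0
    band_rows: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 3:
            raise ValueError("profile must be 1-D with at least 3 samples")
        if self.band_rows < 1:
            raise ValueError("band_rows must be >= 1")

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + np.arange(self.values.size, dtype=np.float64)


@dataclass
class GradientProfile:
    """Finite differences of an intensity profile (order 1 or 2)."""

    values: np.ndarray
    x_coords: np.ndarray
    order: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.x_coords = np.asarray(self.x_coords, dtype=np.float64)
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.values.shape != self.x_coords.shape:
            raise ValueError("values and x_coords must have identical shape")


def extract_profile(image: FieldImage, band_fraction: float = 0.5) -> IntensityProfile:
    """Average a centered band of rows into a per-column profile.

    ``band_fraction`` in (0, 1] selects the central fraction of rows (at
    least one).  ``band_fraction`` small enough to round to a single row
    reproduces the single line-cut reading.
    """
    if not (0.0 < band_fraction <= 1.0):
        raise ValueError("band_fraction must be in (0, 1]")
    pixels = image.pixels
    if pixels.size == 0:
        raise ValueError("empty image")
    n_rows = pixels.shape[0]
    band = max(1, int(round(band_fraction * n_rows)))
    lo = (n_rows - band) // 2
    values = pixels[lo : lo + band].mean(axis=0, dtype=np.float64)
    return IntensityProfile(values=values, x0=0.0, band_rows=band)


def smooth_profile(profile: IntensityProfile, sigma: float) -> IntensityProfile:
    """Gaussian pre-smoothing of the profile (noise-robustness step).

    Plays the role that image interpolation/resampling plays on the real
    instrument: it suppresses pixel noise before differencing without
    shifting symmetric edges.  ``sigma <= 0`` returns the profile unchanged.
    """
    if sigma <= 0:
        return profile
    return IntensityProfile(
        values=gaussian_filter1d(profile.values, sigma, mode="nearest"),
        x0=profile.x0,
        band_rows=profile.band_rows,
    )


def gradient_1d(profile: IntensityProfile) -> GradientProfile:
    """First-order forward difference, sample i at x0 + i + 0.5."""
    v = profile.values
    if v.size < 2:
        raise ValueError("profile must have at least 2 samples")
    return GradientProfile(
        values=np.diff(v),
        x_coords=profile.x0 + np.arange(v.size - 1) + 0.5,
        order=1,
    )


def second_derivative_1d(profile: IntensityProfile) -> GradientProfile:
    """Second-order forward difference, sample i at x0 + i + 1."""
    v = profile.values
    if v.size < 3:
        raise ValueError("profile must have at least 3 samples")
    return GradientProfile(
        values=v[2:] - 2.0 * v[1:-1] + v[:-2],
        x_coords=profile.x0 + np.arange(v.size - 2) + 1.0,
        order=2,
    )


def gradient_magnitude(image: FieldImage) -> np.ndarray:
    """Per-pixel gradient magnitude sqrt(Gx^2 + Gy^2), forward differences.

    Provided for completeness/visualization; the autofocus path itself uses
    only the 1-D profile gradient.  Output shape is (H-1, W-1).
    """
    g = np.asarray(image.pixels, dtype=np.float64)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    gx = g[:-1, 1:] - g[:-1, :-1]
    gy = g[1:, :-1] - g[:-1, :-1]
    return np.hypot(gx, gy)


def profile_to_csv(profile: IntensityProfile | GradientProfile, path) -> None:
    """Export a profile or gradient as two-column CSV (x, value)."""
    import pandas as pd

    x = profile.x_coords if isinstance(profile, GradientProfile) else profile.x_coords
    pd.DataFrame({"x_px": x, "value": profile.values}).to_csv(path, index=False)
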
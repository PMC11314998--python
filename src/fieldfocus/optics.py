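"""Synthetic generator of defocused critical-illumination field images.

A critical-illumination system images a square source (a multimode fiber
end-face) onto the specimen plane; the light reflected off the chip forms a
conjugate image of that square on the detector.  When the specimen defocuses
by ``z`` the conjugate image changes magnification and its edges blur, but
the square plateau survives.  This module emulates that with a paraxial /
phenomenological model:

* plateau width  ``w(z) = w0 * (1 + alpha*z + gamma*z**2)``  [px]
* edge blur      ``sigma(z) = sigma0 + beta*|z|``            [px]
* plateau level  ``peak_intensity * intensity_scale`` over ``background``
* additive Gaussian detector noise with standard deviation ``noise_sd``
  (optional Poisson shot noise on the signal)

The in-focus width ``w0`` follows from the paraxial magnification chain:
the collimator (f_col) and objective (f_obj) demagnify the source onto the
chip by f_obj/f_col, and the objective plus tube lens (f_tube) relay the
chip onto the detector at f_tube/f_obj, for a total of f_tube/f_col.

All images are deterministic functions of (config, z, offset, scale, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.special import erf

from .errors import FieldOutOfBoundsError

#: Full-scale value of the emulated 16-bit detector, counts.
SATURATION = 65535.0

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry and response of the simulated instrument.

    Defaults reproduce the reference instrument: a 1 x 1 mm square source,
    an f = 8 mm infinity objective with an f = 12 mm collimator and an
    f = 200 mm tube lens, imaged onto a 20 x 20 mm, 4000 x 4000 px detector
    (5 um pixel pitch), giving an in-focus field width w0 ~ 3333 px.

    Parameters
    ----------
    f_obj, f_col, f_tube:
        Objective, collimator and tube-lens focal lengths, mm.
    source_width:
        Side of the square source, mm.
    detector_side, detector_pixels:
        Detector size (mm) and pixel count per axis.
    w0:
        In-focus field width on the detector, px.  ``None`` derives it from
        the paraxial chain ``source_width * f_tube / f_col / pixel_pitch``.
    alpha:
        Fractional width change per um of defocus, 1/um.  Negative: the
        field shrinks as z moves from negative (toward the lens) to
        positive defocus.
    gamma:
        Quadratic width-nonlinearity coefficient, 1/um^2; emulates the mild
        departure from linearity seen at large defocus.
    sigma0, beta:
        In-focus edge blur (px) and blur growth (px per um of |z|).
    peak_intensity, background:
        Plateau level and offset, detector counts.
    noise_sd:
        Additive Gaussian noise standard deviation, counts.
    shot_noise:
        If True, add Poisson shot noise on the noiseless signal as well.
    z_range:
        Declared simulation range (z_min, z_max), um; the field must stay
        on the detector (with a 3-sigma blur margin) over this range.
    """

    f_obj: float = 8.0
    f_col: float = 12.0
    f_tube: float = 200.0
    source_width: float = 1.0
    detector_side: float = 20.0
    detector_pixels: int = 4000
    w0: Optional[float] = None
    alpha: float = -1.0e-3
    gamma: float = 1.0e-8
    sigma0: float = 2.0
    beta: float = 0.5
    peak_intensity: float = 60000.0
    background: float = 500.0
    noise_sd: float = 10.0
    shot_noise: bool = False
    z_range: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("f_obj", "f_col", "f_tube", "source_width",
                     "detector_side", "detector_pixels", "peak_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.w0 is None:
            object.__setattr__(self, "w0", self.nominal_width_px)
        if self.w0 <= 0:
            raise ValueError("w0 must be strictly positive")
        if self.sigma0 < 0 or self.beta < 0 or self.noise_sd < 0:
            raise ValueError("sigma0, beta and noise_sd must be non-negative")
        if self.z_range[0] >= self.z_range[1]:
            raise ValueError("z_range must satisfy z_min < z_max")
        # Field must fit the detector over the declared range.  Width is
        # quadratic in z, so checking the endpoints and interior vertex of
        # w(z)/2 + 3*sigma(z) suffices.
        for z in self._width_extrema():
            if not self._fits(z, 0.0):
                raise FieldOutOfBoundsError(
                    f"field exceeds detector at z = {z:+.1f} um for the "
                    f"declared z_range {self.z_range}"
                )

    # ---- derived geometry -------------------------------------------------

    @property
    def pixel_pitch(self) -> float:
        """Detector pixel pitch, um/px."""
        return self.detector_side * 1000.0 / self.detector_pixels

    @property
    def magnification(self) -> float:
        """Nominal source-to-detector magnification f_tube / f_col."""
        return self.f_tube / self.f_col

    @property
    def nominal_width_px(self) -> float:
        """Paraxial in-focus field width on the detector, px."""
        return self.source_width * 1000.0 * self.magnification / self.pixel_pitch

    def width_px(self, z: float) -> float:
        """Plateau width at defocus ``z`` um, px."""
        return float(self.w0 * (1.0 + self.alpha * z + self.gamma * z * z))

    def blur_px(self, z: float) -> float:
        """Gaussian edge-blur scale at defocus ``z`` um, px."""
        return float(self.sigma0 + self.beta * abs(z))

    def _width_extrema(self) -> list[float]:
        zs = [self.z_range[0], self.z_range[1], 0.0]
        if self.gamma != 0.0:
            vertex = -self.alpha / (2.0 * self.gamma)
            if self.z_range[0] < vertex < self.z_range[1]:
                zs.append(vertex)
        return zs

    def _fits(self, z: float, offset: float) -> bool:
        half = self.width_px(z) / 2.0 + 3.0 * self.blur_px(z) + abs(offset)
        return half <= self.detector_pixels / 2.0

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["z_range"] = list(self.z_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        if "z_range" in d:
            d["z_range"] = tuple(d["z_range"])
        return cls(**d)


@dataclass
class FieldImage:
    """A 2-D raster of the (possibly defocused) illumination field.

    ``true_z`` is simulation metadata and is absent (None) for real
    captures; ``lateral_offset`` records the commanded field-center shift.
    """

    pixels: np.ndarray
    pixel_pitch: float
    true_z: Optional[float] = None
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _edge_profile(n: int, center: float, width: float, sigma: float) -> np.ndarray:
    """1-D blurred-box profile: a unit plateau of ``width`` px around
    ``center``, each edge an erf of scale ``sigma`` px."""
    x = np.arange(n, dtype=np.float64)
    left = center - width / 2.0
    right = center + width / 2.0
    if sigma <= 1e-9:
        return ((x >= left) & (x <= right)).astype(np.float64)
    s = sigma * _SQRT2
    return 0.5 * (erf((x - left) / s) - erf((x - right) / s))


def render_field(
    config: OpticsConfig,
    z: float,
    offset: float = 0.0,
    intensity_scale: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> FieldImage:
    """Render one defocused field image.

    The square plateau of width ``w(z)`` is separable, so the image is the
    outer product of two 1-D blurred-box profiles (x shifted by ``offset``),
    scaled to ``peak_intensity * intensity_scale`` over ``background``, with
    seeded additive Gaussian noise, clipped to [0, saturation].

    Raises
    ------
    FieldOutOfBoundsError
        If ``z`` is outside the declared range or the shifted field (with a
        3-sigma blur margin) would leave the detector.
    ValueError
        If ``intensity_scale`` is not strictly positive.
    """
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be strictly positive")
    if not (config.z_range[0] <= z <= config.z_range[1]):
        raise FieldOutOfBoundsError(
            f"z = {z:+.3f} um outside declared range {config.z_range}"
        )
    if not config._fits(z, offset):
        raise FieldOutOfBoundsError(
            f"field at z = {z:+.3f} um with offset {offset:+.1f} px exceeds detector"
        )

    n = config.detector_pixels
    center = (n - 1) / 2.0
    w = config.width_px(z)
    sig = config.blur_px(z)
    px = _edge_profile(n, center + offset, w, sig).astype(np.float32)
    py = _edge_profile(n, center, w, sig).astype(np.float32)

    amplitude = np.float32(config.peak_intensity * intensity_scale)
    img = np.outer(py, px)
    img *= amplitude
    img += np.float32(config.background)

    rng = np.random.default_rng(seed)
    if config.shot_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(np.float32)
    if config.noise_sd > 0:
        img += rng.standard_normal(img.shape, dtype=np.float32) * np.float32(
            config.noise_sd
        )
    np.clip(img, 0.0, SATURATION, out=img)
    return FieldImage(
        pixels=img,
        pixel_pitch=config.pixel_pitch,
        true_z=float(z),
        lateral_offset=float(offset),
    )


def iter_stack(
    config: OpticsConfig,
    z_values: Sequence[float],
    frames_per_z: int = 1,
    seed: int = 0,
    offset: float = 0.0,
    intensity_scale: float = 1.0,
) -> Iterator[FieldImage]:
    """Lazily yield one seeded frame per (z, frame index).

    Frame seeds are derived deterministically from the master ``seed`` via
    ``numpy.random.SeedSequence([seed, index])``, so the full stack is
    reproducible from (config, seed).  Prefer this over :func:`render_stack`
    for full-size detectors, where a materialized stack would be very large.
    """
    z_values = list(z_values)
    if not z_values:
        raise ValueError("z_values must be nonempty")
    if frames_per_z < 1:
        raise ValueError("frames_per_z must be >= 1")
    lo, hi = config.z_range
    for z in z_values:
        if not (lo <= z <= hi):
            raise FieldOutOfBoundsError(
                f"z = {z:+.3f} um outside declared range {config.z_range}"
            )
    index = 0
    for z in z_values:
        for _ in range(frames_per_z):
            yield render_field(
                config,
                z,
                offset=offset,
                intensity_scale=intensity_scale,
                seed=np.random.SeedSequence([seed, index]),
            )
            index += 1


def render_stack(
    config: OpticsConfig,
    z_values: Sequence[float],
    frames_per_z: int = 1,
    seed: int = 0,
    offset: float = 0.0,
    intensity_scale: float = 1.0,
) -> list[FieldImage]:
    """Render a calibration stack as a list (see :func:`iter_stack`).

    Note: a full-size 4000 x 4000 float32 frame is 64 MB; materializing a
    201-frame stack needs ~13 GB.  Use :func:`iter_stack` for streaming.
    """
    return list(
        iter_stack(config, z_values, frames_per_z, seed, offset, intensity_scale)
    )


def write_stack(
    config: OpticsConfig,
    z_values: Sequence[float],
    out_dir: str | Path,
    frames_per_z: int = 1,
    seed: int = 0,
) -> "Path":
    """Write a seeded stack as 16-bit TIFFs plus a CSV manifest.

    Manifest columns: filename, true_z_um, frame_index, seed (master seed;
    per-frame seeds derive from it by frame index).  Returns the manifest
    path.
    """
    import pandas as pd
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for img in iter_stack(config, z_values, frames_per_z, seed):
        name = f"field_{index:05d}.tif"
        tifffile.imwrite(
            out_dir / name, np.round(img.pixels).astype(np.uint16)
        )
        rows.append(
            {
                "filename": name,
                "true_z_um": img.true_z,
                "frame_index": index,
                "seed": seed,
            }
        )
        index += 1
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
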
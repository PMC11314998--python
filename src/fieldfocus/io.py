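"""Image, manifest and configuration I/O.

Formats: 16-bit grayscale TIFF/PNG for images, CSV for manifests and metric
tables (columns fixed: true_z_um, d_px, t_px, ...), JSON for curves and
focus logs, YAML or TOML for configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .edges import MeasurementSettings
from .errors import ImageFormatError
from .optics import FieldImage, OpticsConfig

logger = logging.getLogger("fieldfocus")


def load_image(
    path: str | Path,
    pixel_pitch: Optional[float] = None,
    true_z: Optional[float] = None,
) -> FieldImage:
    """Load a grayscale 8/16-bit TIFF or PNG as a FieldImage.

    ``pixel_pitch`` (um/px) comes from the caller's config when given,
    otherwise from TIFF resolution metadata, otherwise defaults to 1.0.
    ``true_z`` is optional ground-truth metadata (e.g. from a manifest).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            if pixel_pitch is None:
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and unit is not None:
                    num, den = res.value
                    if num > 0:
                        per_px = den / num  # unit per pixel
                        scale = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
                        if scale:
                            pixel_pitch = per_px * scale
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise ImageFormatError(
            f"{path}: expected single-channel 2-D image, got shape {data.shape}"
        )
    if data.dtype not in (np.uint8, np.uint16):
        raise ImageFormatError(f"{path}: expected 8/16-bit data, got {data.dtype}")
    return FieldImage(
        pixels=data.astype(np.float32),
        pixel_pitch=1.0 if pixel_pitch is None else float(pixel_pitch),
        true_z=true_z,
    )


def save_image(image: FieldImage, path: str | Path) -> None:
    """Write a FieldImage as 16-bit grayscale TIFF (round-trips bit-exactly
    for integral-valued rasters)."""
    import tifffile

    tifffile.imwrite(Path(path), np.round(image.pixels).astype(np.uint16))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a stack manifest CSV (filename, true_z_um, frame_index, seed)."""
    df = pd.read_csv(path)
    missing = {"filename", "true_z_um"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Everything a CLI run needs: optics, measurement settings, protocol."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    settings: MeasurementSettings = field(default_factory=MeasurementSettings)
    curve_family: str = "linear"
    schedule: tuple[int, ...] = (1, 1, 16)
    seed: int = 0
    output_dir: str = "."

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for manifests."""
        payload = json.dumps(
            {
                "optics": self.optics.to_dict(),
                "settings": [
                    self.settings.band_fraction,
                    self.settings.smooth_sigma,
                    self.settings.refine,
                ],
                "curve_family": self.curve_family,
                "schedule": list(self.schedule),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (.yml/.yaml) or TOML (.toml).

    Recognized top-level keys: ``optics`` (OpticsConfig field names),
    ``band_fraction``, ``smooth_sigma``, ``refine``, ``curve_family``,
    ``schedule``, ``seed``, ``output_dir``.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        import yaml

        raw = yaml.safe_load(path.read_text()) or {}
    optics = OpticsConfig.from_dict(raw.get("optics", {}))
    settings = MeasurementSettings(
        band_fraction=raw.get("band_fraction", 0.5),
        smooth_sigma=raw.get("smooth_sigma", 5.0),
        refine=raw.get("refine", True),
    )
    return RunConfig(
        optics=optics,
        settings=settings,
        curve_family=raw.get("curve_family", "linear"),
        schedule=tuple(raw.get("schedule", (1, 1, 16))),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "."),
    )
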
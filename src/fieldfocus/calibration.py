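"""The standard evaluation curve: fit, sensitivity, inversion.

Calibration measures the edge separation d over a stack of images with
known stage positions z and fits

    d(z) = k*z + d0            (linear, default)
    d(z) = c2*z^2 + k*z + d0   (optional quadratic, for wide ranges)

by ordinary least squares.  The evaluation value t = d - d0 then satisfies
t = k*z (+ c2*z^2), so a measured t inverts to a defocus estimate.  The
slope k (px/um) is the focus sensitivity; 1/|k| is the defocus change that
moves the metric by one pixel — the detection limit at native pixel
resolution.

The reference separation d0 is the *fitted* separation at z = 0 (not a
single in-focus frame), which is more noise-robust and makes t(0) = 0 exact
by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .edges import MeasurementSettings, measure_separation
from .errors import DegenerateCurveError
from .optics import OpticsConfig, iter_stack

#: Curves with |k| below this are unusable for inversion, px/um.
DEFAULT_K_FLOOR = 1e-2


def fine_z_grid() -> np.ndarray:
    """Default fine calibration grid: 1 um steps over +/-50 um."""
    return np.arange(-50.0, 51.0, 1.0)


def coarse_z_grid() -> np.ndarray:
    """Default coarse calibration grid: 5 um steps over +/-100 um."""
    return np.arange(-100.0, 101.0, 5.0)


@dataclass(frozen=True)
class EvaluationCurve:
    """Fitted evaluation curve t(z) and its provenance.

    ``samples`` stores the calibration points as (z um, t px) with
    t = d - d0, so the stored curve has zero intercept in t-space.
    """

    k: float
    b: float
    d0: float
    r_squared: float
    z_min: float
    z_max: float
    samples: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    family: str = "linear"
    c2: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.z_min >= self.z_max:
            raise ValueError("z_min must be < z_max")
        if self.family not in ("linear", "quadratic"):
            raise ValueError("family must be 'linear' or 'quadratic'")

    def predict_t(self, z: float) -> float:
        return self.c2 * z * z + self.k * z

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "b": self.b,
            "d0": self.d0,
            "r_squared": self.r_squared,
            "z_min": self.z_min,
            "z_max": self.z_max,
            "family": self.family,
            "c2": self.c2,
            "samples": [list(s) for s in self.samples],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationCurve":
        payload = json.loads(Path(path).read_text())
        payload["samples"] = tuple(tuple(s) for s in payload["samples"])
        return cls(**payload)

    def samples_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        z, t = zip(*self.samples) if self.samples else ((), ())
        pd.DataFrame({"true_z_um": z, "t_px": t}).to_csv(path, index=False)


def fit_evaluation_curve(
    samples: Sequence[tuple[float, float]],
    family: str = "linear",
    k_floor: float = DEFAULT_K_FLOOR,
) -> EvaluationCurve:
    """Least-squares fit of the evaluation curve from (z um, d px) samples.

    Raises ``ValueError`` for fewer than 3 samples or zero z-variance, and
    ``DegenerateCurveError`` when the fitted |k| falls below ``k_floor``.
    """
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (z, d) samples")
    z, d = arr[:, 0], arr[:, 1]
    if np.ptp(z) == 0.0:
        raise ValueError("samples must span a nonzero z range")

    deg = 2 if family == "quadratic" else 1
    coeffs = np.polyfit(z, d, deg)
    pred = np.polyval(coeffs, z)
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)

    if family == "quadratic":
        c2, k, b = (float(c) for c in coeffs)
    else:
        c2 = 0.0
        k, b = (float(c) for c in coeffs)
    if abs(k) < k_floor:
        raise DegenerateCurveError(
            f"|k| = {abs(k):.3g} px/um below usability floor {k_floor}"
        )
    d0 = b  # fitted separation at z = 0
    t = d - d0
    return EvaluationCurve(
        k=k,
        b=b,
        d0=d0,
        r_squared=min(r2, 1.0),
        z_min=float(z.min()),
        z_max=float(z.max()),
        samples=tuple((float(zz), float(tt)) for zz, tt in zip(z, t)),
        family=family,
        c2=c2,
    )


def sensitivity(curve: EvaluationCurve, k_floor: float = DEFAULT_K_FLOOR) -> float:
    """Detection limit 1/|k|: defocus (um) per one-pixel change in t."""
    if abs(curve.k) < k_floor:
        raise DegenerateCurveError("curve slope below usability floor")
    return 1.0 / abs(curve.k)


class ZEstimate(NamedTuple):
    """A defocus estimate with its out-of-validity-range flag."""

    z: float
    extrapolated: bool


def invert_curve(
    curve: EvaluationCurve, t: float, k_floor: float = DEFAULT_K_FLOOR
) -> ZEstimate:
    """Invert the evaluation curve: t -> defocus estimate z (um).

    Linear curves give z = t/k.  Quadratic curves solve
    c2*z^2 + k*z = t picking the root continuous with the linear solution.
    The ``extrapolated`` flag is set when z falls outside the calibrated
    [z_min, z_max].
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if abs(curve.k) < k_floor:
        raise DegenerateCurveError("curve slope below usability floor")
    if curve.c2 == 0.0:
        z = t / curve.k
    else:
        disc = curve.k * curve.k + 4.0 * curve.c2 * t
        if disc < 0.0:
            raise ValueError("t outside the representable range of the curve")
        # Root that tends to t/k as c2 -> 0 (numerically stable form).
        denom = curve.k + np.sign(curve.k) * np.sqrt(disc)
        if denom == 0.0:
            raise ValueError("degenerate quadratic inversion")
        z = 2.0 * t / denom
    return ZEstimate(float(z), bool(z < curve.z_min or z > curve.z_max))


def calibrate_simulated(
    config: OpticsConfig,
    z_values: Optional[Sequence[float]] = None,
    frames_per_z: int = 1,
    seed: int = 0,
    settings: MeasurementSettings = MeasurementSettings(),
    family: str = "linear",
    k_floor: float = DEFAULT_K_FLOOR,
) -> EvaluationCurve:
    """Render a seeded calibration stack and fit the evaluation curve.

    Streams one frame at a time (full-size frames are large), measuring the
    edge separation of each.  Defaults to the fine protocol: 1 um steps over
    +/-50 um, one frame per position.
    """
    if z_values is None:
        z_values = fine_z_grid()
    samples = []
    z_list = [z for z in z_values for _ in range(frames_per_z)]
    for z, img in zip(
        z_list, iter_stack(config, z_values, frames_per_z=frames_per_z, seed=seed)
    ):
        pair = measure_separation(img, settings)
        samples.append((z, pair.d))
    return fit_evaluation_curve(samples, family=family, k_floor=k_floor)


def measure_simulated_stack(
    config: OpticsConfig,
    z_values: Sequence[float],
    frames_per_z: int = 1,
    seed: int = 0,
    settings: MeasurementSettings = MeasurementSettings(),
) -> list[tuple[float, float]]:
    """(z, d) samples from a seeded simulated stack, streaming."""
    z_list = [z for z in z_values for _ in range(frames_per_z)]
    out = []
    for z, img in zip(
        z_list, iter_stack(config, z_values, frames_per_z=frames_per_z, seed=seed)
    ):
        out.append((float(z), measure_separation(img, settings).d))
    return out
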
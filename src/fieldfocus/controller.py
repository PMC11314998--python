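"""Closed-loop focusing against a virtual stage.

Converts per-image defocus estimates into quantized stage moves.  The
default protocol mirrors the instrument's three-iteration scheme: two
single-frame iterations bring an arbitrary defocus within the fine range,
then one multi-frame averaged iteration lands within the actuator's
quantization floor.  The commanded move is the full negative estimate
(proportional gain 1 — justified by the linearity of the evaluation curve),
rounded to an integer number of minimum actuator steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .calibration import EvaluationCurve, ZEstimate, invert_curve
from .edges import MeasurementSettings, evaluation_value, measure_separation
from .errors import FocusError, TravelExceededError
from .optics import FieldImage, OpticsConfig, render_field


@dataclass(frozen=True)
class ActuatorModel:
    """Z-stage actuator: executed moves are integer multiples of min_step.

    Defaults follow the prototype's one-dimensional linear stage: 78 nm
    minimum step over 10 cm of travel.  ``latency_ms`` is informational
    metadata only and never enters any computation.
    """

    min_step: float = 0.078
    travel: float = 1.0e5
    latency_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.min_step <= 0 or self.travel <= 0:
            raise ValueError("min_step and travel must be strictly positive")

    def quantize(self, move: float) -> float:
        """Nearest integer multiple of min_step (half-to-even rounding)."""
        return float(np.rint(move / self.min_step)) * self.min_step


@dataclass
class VirtualStage:
    """Simulated stage + camera: holds the (hidden) true defocus.

    ``capture`` renders frames at the current true defocus with seeds drawn
    deterministically from the stage's seed stream; ``command`` applies a
    quantized move.  Optional per-frame lateral-offset and intensity jitter
    emulate vibration and laser power fluctuation.
    """

    optics: OpticsConfig
    actuator: ActuatorModel = field(default_factory=ActuatorModel)
    true_z: float = 0.0
    seed: int = 0
    offset_jitter_px: float = 0.0
    intensity_jitter: float = 0.0
    _frame_index: int = field(default=0, repr=False)

    def capture(self, n_frames: int = 1) -> list[FieldImage]:
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        frames = []
        for _ in range(n_frames):
            ss = np.random.SeedSequence([self.seed, self._frame_index])
            self._frame_index += 1
            rng = np.random.default_rng(ss)
            offset = (
                rng.normal(0.0, self.offset_jitter_px)
                if self.offset_jitter_px > 0
                else 0.0
            )
            scale = (
                max(1e-6, rng.normal(1.0, self.intensity_jitter))
                if self.intensity_jitter > 0
                else 1.0
            )
            frames.append(
                render_field(
                    self.optics,
                    self.true_z,
                    offset=offset,
                    intensity_scale=scale,
                    seed=ss.spawn(1)[0],
                )
            )
        return frames

    def command(self, move: float) -> float:
        """Execute a quantized move; returns the move actually executed."""
        if abs(move) > self.actuator.travel:
            raise TravelExceededError(
                f"requested move {move:+.3f} um exceeds travel "
                f"{self.actuator.travel} um"
            )
        executed = self.actuator.quantize(move)
        self.true_z += executed
        return executed


@dataclass(frozen=True)
class IterationRecord:
    """One closed-loop iteration: estimate, frames used, executed move."""

    z_estimate: float
    frames_used: int
    move_commanded: float
    estimate_sd: float = 0.0
    extrapolated: bool = False
    true_z_after: Optional[float] = None  # simulation metadata


@dataclass(frozen=True)
class FocusResult:
    """Trajectory and outcome of a closed-loop focusing run."""

    iterations: tuple[IterationRecord, ...]
    final_residual: float
    converged: bool

    def to_jsonl(self, path: str | Path) -> None:
        """Log the run as JSON-lines, one record per iteration."""
        with open(path, "w") as fh:
            for i, rec in enumerate(self.iterations):
                fh.write(
                    json.dumps(
                        {
                            "iteration": i,
                            "frames_used": rec.frames_used,
                            "z_estimate_um": rec.z_estimate,
                            "move_commanded_um": rec.move_commanded,
                            "estimate_sd_um": rec.estimate_sd,
                            "extrapolated": rec.extrapolated,
                            "true_z_after_um": rec.true_z_after,
                        }
                    )
                    + "\n"
                )
            fh.write(
                json.dumps(
                    {
                        "final_residual_um": self.final_residual,
                        "converged": self.converged,
                    }
                )
                + "\n"
            )


def single_shot_estimate(
    image: FieldImage,
    curve: EvaluationCurve,
    settings: MeasurementSettings = MeasurementSettings(),
) -> ZEstimate:
    """Defocus estimate from one image: profile -> gradient -> edge pair ->
    t = d - d0 -> curve inversion.  Detection errors propagate."""
    pair = measure_separation(image, settings)
    t = evaluation_value(pair.d, curve.d0)
    return invert_curve(curve, t)


def multi_frame_estimate(
    images: Sequence[FieldImage],
    curve: EvaluationCurve,
    settings: MeasurementSettings = MeasurementSettings(),
) -> tuple[float, float, int]:
    """Mean and standard deviation of per-frame single-shot estimates.

    Frames raising detection errors are dropped (and reflected in the
    returned count); if every frame fails, the last error re-raises.
    Returns (mean um, sd um, n_used).
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    estimates = []
    last_err: Optional[FocusError] = None
    for img in images:
        try:
            estimates.append(single_shot_estimate(img, curve, settings).z)
        except FocusError as err:  # noqa: PERF203 - per-frame robustness
            last_err = err
    if not estimates:
        assert last_err is not None
        raise last_err
    arr = np.asarray(estimates)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def closed_loop_focus(
    stage: VirtualStage,
    curve: EvaluationCurve,
    schedule: Sequence[int] = (1, 1, 16),
    max_iter: Optional[int] = None,
    stop_tol: Optional[float] = None,
    settings: MeasurementSettings = MeasurementSettings(),
) -> FocusResult:
    """Iterative focusing: capture, estimate, move, repeat.

    Each iteration captures ``schedule[i]`` frames, estimates defocus
    (multi-frame averaged), commands the quantized negative of the estimate
    and stops early once |estimate| <= stop_tol (default: one actuator
    step).  A detection failure is retried once with fresh frames; a second
    failure aborts the run (converged=False).
    """
    if max_iter is None:
        max_iter = len(schedule)
    if not (1 <= max_iter <= len(schedule)):
        raise ValueError("need schedule length >= max_iter >= 1")
    if stop_tol is None:
        stop_tol = stage.actuator.min_step

    records: list[IterationRecord] = []
    converged = False
    for i in range(max_iter):
        n_frames = int(schedule[i])
        est = sd = None
        extrapolated = False
        for attempt in range(2):
            try:
                frames = stage.capture(n_frames)
                mean, sd, n_used = multi_frame_estimate(frames, curve, settings)
                est = mean
                extrapolated = not (curve.z_min <= est <= curve.z_max)
                break
            except FocusError:
                if attempt == 1:
                    return FocusResult(
                        iterations=tuple(records),
                        final_residual=abs(stage.true_z),
                        converged=False,
                    )
        assert est is not None and sd is not None
        executed = stage.command(-est)
        records.append(
            IterationRecord(
                z_estimate=est,
                frames_used=n_frames,
                move_commanded=executed,
                estimate_sd=sd,
                extrapolated=extrapolated,
                true_z_after=stage.true_z,
            )
        )
        if abs(est) <= stop_tol:
            converged = True
            break
    return FocusResult(
        iterations=tuple(records),
        final_residual=abs(stage.true_z),
        converged=converged,
    )
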
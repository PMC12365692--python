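"""Head-motion handling: parameter filtering, framewise displacement, censoring,
and duration/volume bookkeeping.

Framewise displacement (FD) follows the Power convention: the sum of absolute
backward differences of the six rigid-body parameters, with rotations converted
to arc length on a sphere (default radius 50 mm). Volumes whose FD exceeds a
threshold (default 0.15 mm) are censored; everything downstream operates on the
retained ("post-censored") volumes, and scan-duration planning is expressed in
post-censored minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

#: Column order for rigid-body motion parameters: translations in mm,
#: rotations in radians.
MOTION_AXES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: Sentinel returned when a post-censored target duration cannot be reached.
INSUFFICIENT_DATA = math.inf


@dataclass(frozen=True)
class MotionParams:
    """Per-volume rigid-body realignment parameters for one run.

    ``values`` is a (volumes, 6) array ordered as :data:`MOTION_AXES`;
    ``tr_seconds`` is the sampling interval.
    """

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValueError(f"motion parameters must be (volumes, 6), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("motion parameters contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FDTrace:
    """Framewise displacement in mm per volume; the first volume's FD is 0."""

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("FD trace must be one-dimensional")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("FD values must be finite and nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CensorMask:
    """Per-volume retention flags (True = retained) at a stated FD threshold."""

    kept: np.ndarray
    threshold_mm: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kept, dtype=bool)
        if k.ndim != 1:
            raise ValueError("censor mask must be one-dimensional")
        object.__setattr__(self, "kept", k)

    @property
    def n_volumes(self) -> int:
        return self.kept.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.kept.sum())


def filter_motion_params(
    params: MotionParams,
    cutoff_hz: float = 0.1,
    axes: Sequence[str] = ("trans_y",),
    order: int = 4,
) -> MotionParams:
    """Zero-phase low-pass filter of selected motion parameters.

    Removes high-frequency (pseudo-)motion, typically respiratory, above
    ``cutoff_hz`` from the listed axes; unselected axes pass through unchanged.
    The default filters only the anterior-posterior translation (the phase-
    encoding direction in an AP acquisition). A 4th-order Butterworth is applied
    forward and backward (``filtfilt``), so the output has no temporal shift.
    """
    fs = 1.0 / params.tr_seconds
    nyquist = fs / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:g} Hz)"
        )
    unknown = set(axes) - set(MOTION_AXES)
    if unknown:
        raise ValueError(f"unknown motion axes: {sorted(unknown)}")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    out = params.values.copy()
    for name in axes:
        j = MOTION_AXES.index(name)
        out[:, j] = signal.sosfiltfilt(sos, params.values[:, j])
    return MotionParams(out, params.tr_seconds)


def compute_fd(params: MotionParams, head_radius_mm: float = 50.0) -> FDTrace:
    """Power-style framewise displacement.

    FD_t = sum |delta translations| + head_radius * sum |delta rotations| for
    t >= 2, and FD_1 = 0. Rotations are in radians, so the radius converts them
    to arc length in mm.
    """
    if head_radius_mm <= 0:
        raise ValueError("head radius must be positive")
    d = np.abs(np.diff(params.values, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return FDTrace(np.concatenate([[0.0], fd]), params.tr_seconds)


def censor(fd: FDTrace, threshold_mm: float = 0.15) -> CensorMask:
    """Censor volumes with FD strictly above ``threshold_mm``.

    The boundary is retained: FD exactly equal to the threshold passes.
    """
    if threshold_mm <= 0:
        raise ValueError("FD threshold must be positive")
    return CensorMask(fd.values <= threshold_mm, threshold_mm)


def retention_percent(mask: CensorMask, total_collected: int) -> float:
    """Percentage of collected volumes that survive censoring."""
    if total_collected <= 0:
        raise ValueError("total_collected must be a positive integer")
    if mask.n_retained > total_collected:
        raise ValueError("retained volumes exceed total collected")
    return 100.0 * mask.n_retained / total_collected


def minutes_to_volumes(minutes: float, tr_seconds: float) -> int:
    """Number of whole volumes acquired in ``minutes`` at the given TR."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if minutes < 0:
        raise ValueError("minutes must be nonnegative")
    return int(math.floor(60.0 * minutes / tr_seconds))


def volumes_to_minutes(volumes: int, tr_seconds: float) -> float:
    """Scan minutes corresponding to a volume count at the given TR."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if volumes < 0:
        raise ValueError("volumes must be nonnegative")
    return volumes * tr_seconds / 60.0


def pre_censored_time_to_reach(
    masks: Sequence[CensorMask], target_minutes: float, tr_seconds: float
) -> float:
    """Acquisition minutes needed to accumulate a post-censored target duration.

    Walks the concatenated censor masks in acquisition order and returns the
    scanned time at which the cumulative retained volume count first reaches
    the target. Returns :data:`INSUFFICIENT_DATA` (``inf``) when the target is
    never reached.
    """
    if target_minutes <= 0:
        raise ValueError("target_minutes must be positive")
    target_volumes = minutes_to_volumes(target_minutes, tr_seconds)
    if target_volumes == 0:
        return 0.0
    kept = np.concatenate([m.kept for m in masks]) if masks else np.zeros(0, bool)
    cum = np.cumsum(kept)
    hit = np.nonzero(cum >= target_volumes)[0]
    if hit.size == 0:
        return INSUFFICIENT_DATA
    return volumes_to_minutes(int(hit[0]) + 1, tr_seconds)
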
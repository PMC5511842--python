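"""Frame schedules, time-activity curves, static averaging and SUV."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-frame boundaries in minutes."""

    start_min: np.ndarray
    end_min: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.start_min, dtype=float)
        e = np.asarray(self.end_min, dtype=float)
        object.__setattr__(self, "start_min", s)
        object.__setattr__(self, "end_min", e)
        if s.size != e.size or s.size == 0:
            raise ValueError("start/end arrays must be equal-length and non-empty")
        if s[0] != 0:
            raise ValueError("first frame must start at 0")
        if np.any(e <= s):
            raise ValueError("frames must have positive duration")
        if not np.allclose(s[1:], e[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.start_min.size

    @property
    def durations_min(self) -> np.ndarray:
        return self.end_min - self.start_min

    @property
    def mid_min(self) -> np.ndarray:
        return 0.5 * (self.start_min + self.end_min)

    @property
    def total_min(self) -> float:
        return float(self.end_min[-1])


def default_frame_schedule() -> FrameSchedule:
    """The 18-frame, 40 min dynamic sequence: 8×15 s, 3×60 s, 5×3 min, 2×10 min."""
    durations = np.concatenate([
        np.full(8, 0.25),
        np.full(3, 1.0),
        np.full(5, 3.0),
        np.full(2, 10.0),
    ])
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameSchedule(start_min=edges[:-1], end_min=edges[1:])


@dataclass(frozen=True)
class TACSet:
    """Per-region mean concentration (kBq/mL) per frame."""

    schedule: FrameSchedule
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for region, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.size != self.schedule.n_frames:
                raise ValueError(f"region {region!r}: expected one value per frame")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"region {region!r}: non-finite TAC values")
            self.values[region] = v

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: region, frame_start_min, frame_end_min, mean_kBq_per_mL."""
        rows = []
        for region, v in self.values.items():
            for i in range(self.schedule.n_frames):
                rows.append(dict(
                    region=region,
                    frame_start_min=self.schedule.start_min[i],
                    frame_end_min=self.schedule.end_min[i],
                    mean_kBq_per_mL=v[i],
                ))
        return pd.DataFrame(rows)


def extract_tacs(frames: np.ndarray, voi_masks: dict[str, np.ndarray], schedule: FrameSchedule) -> TACSet:
    """Mean concentration per VOI and frame.

    ``frames`` is (n_frames, ny, nx); each mask must be non-empty and aligned
    with the frame grid.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] != schedule.n_frames:
        raise ValueError("frame count does not match schedule")
    values = {}
    for region, mask in voi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frames.shape[1:]:
            raise ValueError(f"region {region!r}: mask not aligned with frames")
        if not mask.any():
            raise ValueError(f"region {region!r}: empty VOI")
        values[region] = frames[:, mask].mean(axis=1)
    return TACSet(schedule=schedule, values=values)


def static_average(frames: np.ndarray, schedule: FrameSchedule, window: tuple[float, float] = (10.0, 40.0)) -> np.ndarray:
    """Duration-weighted mean image over a time window.

    Each frame contributes with the duration of its overlap with the window,
    so a window cutting through a frame weights that frame by the covered
    part only.  The window must lie inside the schedule.
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive duration")
    if w0 < schedule.start_min[0] - 1e-9 or w1 > schedule.end_min[-1] + 1e-9:
        raise ValueError(f"window {window} is not covered by the frame schedule")
    overlap = np.clip(np.minimum(schedule.end_min, w1) - np.maximum(schedule.start_min, w0), 0.0, None)
    if overlap.sum() <= 0:
        raise ValueError("window contains no frames")
    return np.tensordot(overlap, np.asarray(frames, dtype=float), axes=(0, 0)) / overlap.sum()


def compute_suv(concentration_kbq_ml, injected_dose_mbq: float, body_weight_kg: float):
    """Standardized uptake value.

    SUV = C[kBq/mL] × body weight[g] / injected dose[kBq]; with the MBq/kg
    inputs used here the unit factors cancel to C × weight / dose.
    """
    if injected_dose_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    return np.asarray(concentration_kbq_ml, dtype=float) * body_weight_kg / injected_dose_mbq
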
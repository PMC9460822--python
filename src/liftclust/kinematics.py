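"""Joint range-of-motion feature extraction.

A lifting trial carries five sagittal-plane angular-displacement traces
(trunk, left/right hip, left/right knee).  Each trace is reduced to its range
of motion, ``max(theta) - min(theta)``; hip and knee use the between-side
average of the per-side ROMs.  The resulting three-feature vector
(trunk, hip, knee) is the sole input to every clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import LiftTrial

__all__ = [
    "JOINTS",
    "AngleTrace",
    "FeatureVector",
    "range_of_motion",
    "side_average",
    "extract_features",
    "features_table",
]

JOINTS = ("trunk", "hip_left", "hip_right", "knee_left", "knee_right")


@dataclass
class AngleTrace:
    """Sagittal angular displacement of one joint over a trial, in degrees."""

    joint: str
    samples: np.ndarray
    rate: float = 120.0

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}; expected one of {JOINTS}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")


@dataclass(frozen=True)
class FeatureVector:
    """Trunk/hip/knee range of motion in degrees."""

    trunk_rom: float
    hip_rom: float
    knee_rom: float

    def __post_init__(self) -> None:
        for name in ("trunk_rom", "hip_rom", "knee_rom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.trunk_rom, self.hip_rom, self.knee_rom], dtype=float)


def range_of_motion(trace: AngleTrace) -> float:
    """Max minus min of the angular displacement.

    Invariant to sample order and to any constant offset added to the trace.
    """
    samples = trace.samples
    if samples.size == 0:
        raise ValueError("empty trace")
    return float(np.max(samples) - np.min(samples))


def side_average(left: float, right: float) -> float:
    """Between-side average of two per-side ROM values."""
    if left < 0 or right < 0:
        raise ValueError("ROM values must be non-negative")
    return (left + right) / 2.0


def extract_features(trial: "LiftTrial") -> FeatureVector:
    """Three-feature ROM vector for one trial.

    Per-side ROMs are computed first and then averaged (ROM-then-average, not
    average-traces-then-ROM: averaging traces with a phase lag between sides
    would shrink the apparent range).
    """
    traces = trial.traces
    missing = [j for j in JOINTS if j not in traces]
    if missing:
        raise ValueError(f"trial missing traces for joints: {missing}")
    trunk = range_of_motion(traces["trunk"])
    hip = side_average(
        range_of_motion(traces["hip_left"]), range_of_motion(traces["hip_right"])
    )
    knee = side_average(
        range_of_motion(traces["knee_left"]), range_of_motion(traces["knee_right"])
    )
    return FeatureVector(trunk_rom=trunk, hip_rom=hip, knee_rom=knee)


def features_table(trials) -> pd.DataFrame:
    """Feature table for a cohort, one row per trial."""
    rows = []
    for trial in trials:
        fv = extract_features(trial)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "trial_index": trial.trial_index,
                "trunk_rom": fv.trunk_rom,
                "hip_rom": fv.hip_rom,
                "knee_rom": fv.knee_rom,
            }
        )
    return pd.DataFrame(rows)
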
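"""In-memory containers for intensity and FRET trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scheme import Condition

__all__ = ["IntensityTrace", "FretTrace"]


@dataclass
class IntensityTrace:
    """Two-channel (donor/acceptor) fluorescence intensity trajectory.

    donor and acceptor hold the per-frame Cy3 and Cy5 intensities in camera
    units; time_s holds per-frame timestamps uniformly spaced by
    frame_interval.
    """

    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    trace_id: str = ""
    condition: Optional[Condition] = None
    bleach_frame: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = len(self.time_s)
        if n < 1:
            raise ValueError("trace must have at least one frame")
        if len(self.donor) != n or len(self.acceptor) != n:
            raise ValueError("time, donor and acceptor must have equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(np.abs(dt - self.frame_interval) > 1e-9):
                raise ValueError(
                    "timestamps must be uniformly spaced by frame_interval"
                )

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    def copy(self) -> "IntensityTrace":
        return IntensityTrace(
            time_s=self.time_s.copy(),
            donor=self.donor.copy(),
            acceptor=self.acceptor.copy(),
            frame_interval=self.frame_interval,
            trace_id=self.trace_id,
            condition=self.condition,
            bleach_frame=self.bleach_frame,
            provenance=dict(self.provenance),
        )


@dataclass
class FretTrace:
    """Per-frame FRET efficiency E = I_A / (I_A + I_D) with a validity mask.

    Frames are masked (valid_mask False) when post-bleach, when total
    intensity falls below the floor, or when E lies outside the artifact
    window; masked frames are excluded from all downstream statistics.
    """

    time_s: np.ndarray
    efret: np.ndarray
    valid_mask: np.ndarray
    frame_interval: float
    trace_id: str = ""
    condition: Optional[Condition] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.efret = np.asarray(self.efret, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = len(self.time_s)
        if len(self.efret) != n or len(self.valid_mask) != n:
            raise ValueError("time, efret and valid_mask must have equal length")
        if np.any(~np.isfinite(self.efret[self.valid_mask])):
            raise ValueError("efret must be finite wherever valid_mask is True")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.efret[self.valid_mask]

    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.valid_mask)
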
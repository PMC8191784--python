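"""SHAPE gel quantification: background subtraction and normalization.

Band intensities (gel "volumes") are normalized in three steps per lane:
(1) subtract the lane's gel background measured on an empty region of the
gel; (2) divide every band by the same lane's band at an invariant
reference position (position 59 by default, chosen because its reactivity
does not change across conditions); (3) scale each position by its value in
the reference condition (0 mM MgCl2 by default), which is thereby reported
as exactly 1.  Replicate experiments are combined as per-cell mean and
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["BandTable", "ReactivityTable", "normalize_shape", "replicate_stats"]

DEFAULT_REFERENCE_POSITION = 59
DEFAULT_REFERENCE_CONDITION = "0 mM MgCl2"


@dataclass
class BandTable:
    """Raw band-intensity table: positions x lanes, plus per-lane background.

    ``intensity`` is a DataFrame indexed by nucleotide position with one
    column per lane; ``gel_background`` maps each lane to the intensity of
    an empty gel region; ``lane_conditions`` maps lanes to condition labels
    (identity by default, i.e. one lane per condition).
    """

    intensity: pd.DataFrame
    gel_background: Dict[str, float]
    lane_conditions: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.intensity.index.duplicated().any():
            raise ValueError("positions must be unique")
        missing = set(self.intensity.columns) - set(self.gel_background)
        if missing:
            raise ValueError(f"lanes missing gel_background: {sorted(missing)}")
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("raw band intensities must be >= 0")
        if self.lane_conditions is None:
            self.lane_conditions = {c: c for c in self.intensity.columns}
        conds = [self.lane_conditions[c] for c in self.intensity.columns]
        if len(set(conds)) != len(conds):
            raise ValueError(
                "duplicate condition labels within one table; keep replicate "
                "lanes in separate tables and combine with replicate_stats"
            )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "BandTable":
        """Build from long-format CSV columns: position, lane, intensity,
        background."""
        wide = df.pivot(index="position", columns="lane", values="intensity")
        bg = df.groupby("lane")["background"].first().to_dict()
        return cls(intensity=wide, gel_background=bg)


@dataclass
class ReactivityTable:
    """Normalized reactivity: positions x conditions.

    The reference-condition column equals 1 for every position by
    construction; ``flags`` marks cells whose post-background intensity was
    negative and clamped to 0.
    """

    reactivity: pd.DataFrame
    reference_position: int
    reference_condition: str
    flags: Optional[pd.DataFrame] = None
    stderr: Optional[pd.DataFrame] = None
    n: Optional[pd.DataFrame] = None


def normalize_shape(
    table: BandTable,
    reference_position: int = DEFAULT_REFERENCE_POSITION,
    reference_condition: str = DEFAULT_REFERENCE_CONDITION,
    control_lane: Optional[str] = None,
) -> ReactivityTable:
    """Normalize a band table to reactivities.

    Raises if the reference-position band of any lane is at or below
    background (the normalization would be undefined), naming the lane.
    Negative post-background intensities at other positions are clamped to
    0 and flagged, since faint bands near background are expected.
    ``control_lane`` optionally subtracts a no-reagent control lane
    band-wise after background subtraction (off by default).
    """
    intensity = table.intensity
    if reference_position not in intensity.index:
        raise ValueError(
            f"reference position {reference_position} absent from table"
        )
    cond_of = table.lane_conditions
    lanes = [c for c in intensity.columns if c != control_lane]
    conditions = [cond_of[l] for l in lanes]
    if reference_condition not in conditions:
        raise ValueError(
            f"reference condition {reference_condition!r} not among lanes"
        )

    corrected = {}
    flags = {}
    control = None
    if control_lane is not None:
        control = intensity[control_lane] - table.gel_background[control_lane]
        control = control.clip(lower=0.0)
    for lane in lanes:
        vals = intensity[lane] - table.gel_background[lane]
        if control is not None:
            vals = vals - control
        ref_val = vals.loc[reference_position]
        if ref_val <= 0:
            raise ValueError(
                f"lane {lane!r}: reference band at position "
                f"{reference_position} is at or below background"
            )
        flagged = vals < 0
        vals = vals.clip(lower=0.0)
        corrected[cond_of[lane]] = vals / ref_val
        flags[cond_of[lane]] = flagged

    norm = pd.DataFrame(corrected)
    ref_col = norm[reference_condition]
    if (ref_col <= 0).any():
        bad = norm.index[ref_col <= 0].tolist()
        raise ValueError(
            f"reference condition has zero intensity at positions {bad}; "
            "cannot scale"
        )
    reactivity = norm.div(ref_col, axis=0)
    return ReactivityTable(
        reactivity=reactivity,
        reference_position=reference_position,
        reference_condition=reference_condition,
        flags=pd.DataFrame(flags),
    )


def replicate_stats(tables: Sequence[ReactivityTable]) -> ReactivityTable:
    """Per-cell mean and standard error over >= 2 replicate tables."""
    if len(tables) < 2:
        raise ValueError("need at least 2 replicate tables")
    ref = tables[0]
    for t in tables[1:]:
        if not t.reactivity.index.equals(ref.reactivity.index) or not t.reactivity.columns.equals(ref.reactivity.columns):
            diff_pos = set(t.reactivity.index) ^ set(ref.reactivity.index)
            diff_cond = set(t.reactivity.columns) ^ set(ref.reactivity.columns)
            raise ValueError(
                f"replicate tables differ: positions {sorted(diff_pos)}, "
                f"conditions {sorted(diff_cond)}"
            )
        if (
            t.reference_position != ref.reference_position
            or t.reference_condition != ref.reference_condition
        ):
            raise ValueError("replicates normalized with different references")
    stack = np.stack([t.reactivity.to_numpy() for t in tables])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    idx, cols = ref.reactivity.index, ref.reactivity.columns
    return ReactivityTable(
        reactivity=pd.DataFrame(mean, index=idx, columns=cols),
        reference_position=ref.reference_position,
        reference_condition=ref.reference_condition,
        stderr=pd.DataFrame(se, index=idx, columns=cols),
        n=pd.DataFrame(np.full(mean.shape, n), index=idx, columns=cols),
    )
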
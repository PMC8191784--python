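"""Per-molecule preprocessing: background correction, FRET efficiency and QC.

FRET efficiency is the uncorrected proximity ratio E = I_A / (I_A + I_D)
(no gamma correction), computed after per-channel background subtraction.
Frames after photobleaching, frames whose total intensity falls below a
floor, and frames whose E lies outside the artifact window [-0.2, 1.2] are
masked rather than clipped, so they never enter downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .traces import FretTrace, IntensityTrace

__all__ = [
    "correct_background",
    "compute_fret",
    "detect_bleach",
    "detect_bleach_steps",
    "QCRules",
    "QCResult",
    "qc_select",
]

ARTIFACT_WINDOW = (-0.2, 1.2)


# ---------------------------------------------------------------------------
# background correction

def correct_background(
    trace: IntensityTrace,
    method: str = "constant",
    params: Optional[dict] = None,
) -> IntensityTrace:
    """Subtract per-channel background offsets.

    method="constant": params must carry ``donor_offset`` and
    ``acceptor_offset``.

    method="post_bleach_mean": offsets are the mean post-bleach intensities
    of each channel; the trace must have ``bleach_frame`` set with at least
    10 frames after it.

    The applied offsets are recorded in the returned trace's provenance.
    """
    params = params or {}
    if method == "constant":
        d_off = float(params.get("donor_offset", 0.0))
        a_off = float(params.get("acceptor_offset", 0.0))
    elif method == "post_bleach_mean":
        bf = trace.bleach_frame
        if bf is None:
            raise ValueError(
                "post_bleach_mean background correction requires a bleach_frame"
            )
        post = slice(bf + 1, None)
        n_post = trace.n_frames - (bf + 1)
        if n_post < 10:
            raise ValueError(
                f"post_bleach_mean needs >= 10 post-bleach frames, got {n_post}"
            )
        d_off = float(trace.donor[post].mean())
        a_off = float(trace.acceptor[post].mean())
    else:
        raise ValueError(f"unknown background method {method!r}")

    out = trace.copy()
    out.donor = out.donor - d_off
    out.acceptor = out.acceptor - a_off
    out.provenance["background"] = {
        "method": method,
        "donor_offset": d_off,
        "acceptor_offset": a_off,
    }
    return out


# ---------------------------------------------------------------------------
# FRET efficiency

def compute_fret(
    trace: IntensityTrace,
    total_floor: float = 0.0,
    artifact_window: Tuple[float, float] = ARTIFACT_WINDOW,
) -> FretTrace:
    """Compute E = I_A / (I_A + I_D) per frame with validity masking.

    Frames with total intensity <= ``total_floor`` are masked, not clipped;
    frames with E outside ``artifact_window`` are masked as artifacts;
    frames at or after the trace's bleach_frame are masked as post-bleach.
    """
    total = trace.donor + trace.acceptor
    with np.errstate(divide="ignore", invalid="ignore"):
        efret = np.where(total > total_floor, trace.acceptor / total, np.nan)
    valid = total > total_floor
    lo, hi = artifact_window
    valid &= np.isfinite(efret) & (efret >= lo) & (efret <= hi)
    if trace.bleach_frame is not None:
        valid[trace.bleach_frame :] = False
    efret = np.where(valid, efret, np.nan)
    return FretTrace(
        time_s=trace.time_s,
        efret=efret,
        valid_mask=valid,
        frame_interval=trace.frame_interval,
        trace_id=trace.trace_id,
        condition=trace.condition,
        provenance=dict(trace.provenance),
    )


# ---------------------------------------------------------------------------
# photobleaching detection

def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise sd from the median absolute first difference (step-insensitive)."""
    if len(x) < 2:
        return 0.0
    mad = np.median(np.abs(np.diff(x)))
    return float(mad / (np.sqrt(2.0) * 0.6745)) if mad > 0 else 0.0


def _best_split(x: np.ndarray) -> Tuple[int, float]:
    """Two-segment change-point by SSE minimization.

    Returns (split index c, drop mean(x[:c]) - mean(x[c:])); the split is
    the first frame of the second segment.
    """
    n = len(x)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x**2)
    total1, total2 = c1[-1], c2[-1]
    cs = np.arange(1, n)
    left1 = c1[:-1]
    left2 = c2[:-1]
    sse_left = left2 - left1**2 / cs
    right_n = n - cs
    sse_right = (total2 - left2) - (total1 - left1) ** 2 / right_n
    cost = sse_left + sse_right
    c = int(np.argmin(cost)) + 1
    drop = x[:c].mean() - x[c:].mean()
    return c, float(drop)


def detect_bleach_steps(
    trace: IntensityTrace,
    threshold: float = 5.0,
    min_segment: int = 5,
) -> List[int]:
    """All significant downward steps in total intensity, in frame order.

    A step is significant when its drop exceeds ``threshold`` times the
    robust noise sd of the total-intensity channel.  Binary segmentation
    (depth 2) is enough to distinguish single from multi-step bleaching.
    """
    total = trace.total
    sd = _robust_noise_sd(total)
    steps: List[int] = []

    def visit(lo: int, hi: int, depth: int) -> None:
        if hi - lo < 2 * min_segment or depth > 2:
            return
        seg = total[lo:hi]
        c, drop = _best_split(seg)
        if c < min_segment or (hi - lo) - c < min_segment:
            return
        floor = threshold * sd if sd > 0 else 0.0
        if drop > max(floor, 1e-12):
            steps.append(lo + c)
            visit(lo, lo + c, depth + 1)
            visit(lo + c, hi, depth + 1)

    if trace.n_frames >= 20:
        visit(0, trace.n_frames, 0)
    return sorted(steps)


def detect_bleach(
    trace: IntensityTrace, threshold: float = 5.0
) -> Optional[int]:
    """Single-step photobleach frame (first frame at background), or None.

    Requires >= 20 frames; returns the first significant downward step in
    total intensity.  Multi-step traces still return the first step — use
    :func:`detect_bleach_steps` (as QC does) to flag them.
    """
    if trace.n_frames < 20:
        raise ValueError("bleach detection requires >= 20 frames")
    steps = detect_bleach_steps(trace, threshold=threshold)
    return steps[0] if steps else None


# ---------------------------------------------------------------------------
# quality control

@dataclass
class QCRules:
    """Single-molecule selection rules.

    A trace passes when it has enough valid pre-bleach frames, shows at most
    one bleaching step, and — if its channels are dynamic beyond noise —
    donor and acceptor are anticorrelated (Pearson r <= max_channel_corr),
    the signature of genuine FRET fluctuations rather than common-mode
    drift.
    """

    min_valid_frames: int = 100
    allow_multi_bleach: bool = False
    max_channel_corr: float = 0.0
    dynamic_factor: float = 2.0  # channel sd must exceed this x noise sd
    bleach_threshold: float = 5.0
    total_floor: float = 0.0


@dataclass
class QCResult:
    accepted: List[IntensityTrace]
    rejected: List[IntensityTrace]
    reasons: Dict[str, str]  # trace_id -> reason ("" for accepted)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def _is_dynamic(x: np.ndarray, factor: float) -> bool:
    sd = float(np.std(x))
    if sd == 0:
        return False
    noise = _robust_noise_sd(x)
    if noise == 0:
        return True  # varies but no high-frequency noise: deterministic drift
    return sd > factor * noise


def qc_select(
    traces: Sequence[IntensityTrace], rules: Optional[QCRules] = None
) -> QCResult:
    """Partition traces into accepted/rejected with a labeled reason each.

    Idempotent: running QC on its own accepted set accepts everything again.
    """
    rules = rules or QCRules()
    accepted, rejected, reasons = [], [], {}
    for trace in traces:
        reason = ""
        steps = (
            detect_bleach_steps(trace, threshold=rules.bleach_threshold)
            if trace.n_frames >= 20
            else []
        )
        bleach = steps[0] if steps else None
        work = trace.copy()
        work.bleach_frame = bleach if work.bleach_frame is None else work.bleach_frame
        ft = compute_fret(work, total_floor=rules.total_floor)

        if len(steps) > 1 and not rules.allow_multi_bleach:
            reason = "multi_bleach"
        elif ft.n_valid < rules.min_valid_frames:
            reason = "too_short"
        else:
            pre = slice(0, bleach) if bleach is not None else slice(None)
            d, a = trace.donor[pre], trace.acceptor[pre]
            if (
                len(d) >= 3
                and _is_dynamic(d, rules.dynamic_factor)
                and _is_dynamic(a, rules.dynamic_factor)
                and np.std(d) > 0
                and np.std(a) > 0
            ):
                r = float(np.corrcoef(d, a)[0, 1])
                if r > rules.max_channel_corr:
                    reason = "not_anticorrelated"
        if reason:
            rejected.append(trace)
        else:
            accepted.append(trace)
        reasons[trace.trace_id] = reason
    return QCResult(accepted=accepted, rejected=rejected, reasons=reasons)
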
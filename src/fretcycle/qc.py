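"""FRET efficiency computation and trace quality control.

Selection criteria applied to each trace, in order:

1. single-step donor photobleaching (exactly one sustained intensity drop),
2. signal-to-background ratio SNR_bg >= 8,
3. fewer than 4 donor blinking events,
4. FRET efficiency above 0.1 for at least 15 valid frames.

Frames after the photobleaching step are excluded from all downstream
analysis; QC never modifies intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

from .simulate import Trace, TraceSet

__all__ = [
    "FRETTrajectory",
    "QCCriteria",
    "QCReport",
    "BleachDetection",
    "compute_fret",
    "detect_bleach",
    "count_blinks",
    "snr_background",
    "filter_traces",
]


@dataclass
class FRETTrajectory:
    """Per-frame FRET efficiency E = I_A / (I_D + I_A) with validity mask.

    ``efficiency`` covers every frame of the parent trace; only frames
    before ``bleach_frame`` with ``valid`` True carry information (frames
    whose total intensity falls below the denominator floor — blinks,
    post-bleach background — are flagged invalid rather than divided).
    """

    molecule_id: str
    frame_interval: float
    efficiency: np.ndarray
    valid: np.ndarray  # bool, denominator above floor
    bleach_frame: int

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid[: self.bleach_frame]))

    def values(self) -> np.ndarray:
        """E at valid pre-bleach frames (downstream analysis input)."""
        return self.efficiency[: self.bleach_frame][self.valid[: self.bleach_frame]]

    def prebleach(self) -> tuple[np.ndarray, np.ndarray]:
        """(E, valid) over the pre-bleach segment, frame-aligned."""
        return self.efficiency[: self.bleach_frame], self.valid[: self.bleach_frame]


@dataclass
class QCCriteria:
    """Thresholds of the trace filter (defaults follow the published filter)."""

    min_snr: float = 8.0
    max_blinks: int = 3  # "< 4 donor blinking events"
    min_fret_frames: int = 15
    fret_floor: float = 0.1
    min_length: int = 20
    denominator_floor_frac: float = 0.1  # of the trace's median total intensity
    step_sigma: float = 4.0  # bleach step threshold, in background sigmas
    blink_sigma: float = 3.0  # blink threshold above background
    median_window: int = 5


@dataclass
class QCReport:
    """Per-trace QC outcome table plus the dataset pass fraction."""

    table: pd.DataFrame  # molecule_id, bleach_frame, step_count, snr, n_blinks, ...

    @property
    def pass_fraction(self) -> float:
        return float(self.table["passed"].mean()) if len(self.table) else 0.0

    def reasons(self) -> pd.Series:
        return self.table.loc[~self.table["passed"], "reason"]


@dataclass
class BleachDetection:
    bleach_frame: int
    step_count: int
    background_mean: float
    background_sigma: float


def compute_fret(trace: Trace, bleach_frame: Optional[int] = None,
                 denominator_floor_frac: float = 0.1) -> FRETTrajectory:
    """E = I_A / (I_D + I_A), with low-denominator frames flagged invalid.

    Frames whose total intensity is below ``denominator_floor_frac`` times
    the median pre-bleach total are marked invalid instead of divided, so
    blinks and background never produce ratio blow-ups.  An all-zero trace
    yields an all-invalid trajectory, not an exception.
    """
    total = trace.total
    n = trace.n_frames
    if bleach_frame is None:
        bleach_frame = n
    ref = np.median(total[:bleach_frame]) if bleach_frame > 0 else 0.0
    floor = denominator_floor_frac * max(ref, 0.0)
    valid = total > max(floor, 1e-12)
    e = np.zeros(n)
    np.divide(trace.acceptor, total, out=e, where=valid)
    return FRETTrajectory(trace.molecule_id, trace.frame_interval, e, valid, int(bleach_frame))


def _noise_sigma(x: np.ndarray) -> float:
    """Robust per-frame noise estimate from first differences."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0)) or 1e-12


def detect_bleach(trace: Trace, *, window: int = 5, step_sigma: float = 4.0,
                  background_sigma: Optional[float] = None) -> BleachDetection:
    """Locate the photobleaching step on the median-filtered total intensity.

    A change point qualifies as a bleaching-type step when the local drop
    (mean of the next ``window`` frames minus mean of the previous
    ``window``) exceeds ``step_sigma`` background widths and the signal
    never recovers above the post-step level afterwards.  ``bleach_frame``
    is the step that leaves the trace at its final background level;
    ``step_count`` counts all sustained steps (a two-step acceptor-then-
    donor bleach therefore reports 2 and fails the single-step criterion).
    With no qualifying step the whole trace is considered pre-bleach.
    """
    total = trace.total
    n = len(total)
    if n < 4 * window:
        return BleachDetection(n, 0, float("nan"), float("nan"))
    filt = median_filter(total, size=window, mode="nearest")
    sigma = background_sigma if background_sigma is not None else _noise_sigma(total)

    fwd = uniform_filter1d(filt, window, origin=-(window // 2), mode="nearest")
    bwd = uniform_filter1d(filt, window, origin=(window - 1) // 2, mode="nearest")
    # step signal at i: mean of [i, i+w) minus mean of [i-w, i)
    step = np.full(n, 0.0)
    step[window:n - window] = fwd[window:n - window] - bwd[window - 1:n - window - 1]

    threshold = -step_sigma * sigma
    cand = np.flatnonzero(step < threshold)
    # non-maximum suppression: keep local minima separated by >= window
    steps: list[int] = []
    for i in sorted(cand, key=lambda j: step[j]):
        if all(abs(i - j) >= window for j in steps):
            steps.append(i)
    # qualify: sustained — the plateau between this step and the next
    # candidate is never exceeded again (blinks recover, so they fail here)
    qualified = []
    ordered = sorted(steps)
    for idx, i in enumerate(ordered):
        nxt = ordered[idx + 1] if idx + 1 < len(ordered) else n
        seg = filt[min(i + window, n - 1):nxt]
        if seg.size == 0:
            seg = filt[i:nxt]
        level = np.median(seg)
        if np.all(filt[min(i + window, n - 1):] < level + step_sigma * sigma):
            qualified.append((i, level))
    final_level = np.median(filt[-window:])
    bleach_frame = n
    for i, level in qualified:
        if level < final_level + 3.0 * sigma:
            bleach_frame = i
            break
    bg = total[bleach_frame:] if bleach_frame < n else np.array([])
    return BleachDetection(
        bleach_frame=int(bleach_frame),
        step_count=len(qualified),
        background_mean=float(np.mean(bg)) if bg.size else float("nan"),
        background_sigma=float(np.std(bg)) if bg.size > 1 else float("nan"),
    )


def count_blinks(trace: Trace, bleach_frame: int, *, blink_sigma: float = 3.0,
                 background_mean: Optional[float] = None,
                 background_sigma: Optional[float] = None) -> int:
    """Count donor blinking events before photobleaching.

    A blink is a maximal run of >= 2 consecutive pre-bleach frames whose
    total intensity falls below background + ``blink_sigma`` sigmas and that
    recovers afterwards (runs abutting the bleach step belong to the bleach,
    not to blinking).  Background statistics default to the post-bleach
    segment when one exists.
    """
    total = trace.total
    n = len(total)
    if background_mean is None or background_sigma is None:
        if bleach_frame < n - 1:
            bg = total[bleach_frame:]
            background_mean = float(np.mean(bg))
            background_sigma = float(np.std(bg))
        else:
            background_mean, background_sigma = 0.0, _noise_sigma(total)
    low = total[:bleach_frame] < background_mean + blink_sigma * background_sigma
    count = 0
    run = 0
    for i, flag in enumerate(low):
        if flag:
            run += 1
        else:
            if run >= 2:
                count += 1  # recovered: a genuine blink
            run = 0
    # a trailing low run touches the bleach step -> not counted
    return count


def snr_background(trace: Trace, bleach_frame: int) -> float:
    """Mean pre-bleach total intensity over the post-bleach background width.

    Returns NaN when the trace never bleaches (no background segment), which
    downstream QC treats as a failure.
    """
    total = trace.total
    if bleach_frame >= len(total) - 4 or bleach_frame < 1:
        return float("nan")
    bg_sigma = float(np.std(total[bleach_frame:]))
    if bg_sigma == 0:
        return float("inf")
    return float(np.mean(total[:bleach_frame]) / bg_sigma)


def filter_traces(
    traceset: TraceSet | Sequence[Trace],
    criteria: Optional[QCCriteria] = None,
) -> tuple[list[FRETTrajectory], QCReport]:
    """Apply the full trace-selection filter; returns survivors and a report.

    Criteria are applied in order (single bleach step, SNR, blinks, FRET
    frames); the first violated criterion is recorded as the failure reason.
    """
    criteria = criteria or QCCriteria()
    traces = list(traceset)
    rows = []
    passing: list[FRETTrajectory] = []
    for tr in traces:
        reason = ""
        det = BleachDetection(tr.n_frames, 0, float("nan"), float("nan"))
        snr = float("nan")
        blinks = -1
        fret_frames = -1
        if tr.n_frames < criteria.min_length:
            reason = "too short"
        else:
            det = detect_bleach(tr, window=criteria.median_window,
                                step_sigma=criteria.step_sigma)
            if det.step_count != 1:
                reason = "no single bleach step" if det.step_count == 0 else "multi-step bleach"
            else:
                snr = snr_background(tr, det.bleach_frame)
                if np.isnan(snr):
                    reason = "no background segment"
                elif snr < criteria.min_snr:
                    reason = "low SNR"
                else:
                    blinks = count_blinks(
                        tr, det.bleach_frame, blink_sigma=criteria.blink_sigma,
                        background_mean=det.background_mean,
                        background_sigma=det.background_sigma,
                    )
                    if blinks > criteria.max_blinks:
                        reason = "too many blinks"
                    else:
                        traj = compute_fret(
                            tr, det.bleach_frame,
                            denominator_floor_frac=criteria.denominator_floor_frac,
                        )
                        fret_frames = int(np.count_nonzero(
                            traj.values() > criteria.fret_floor))
                        if fret_frames < criteria.min_fret_frames:
                            reason = "insufficient FRET frames"
                        else:
                            passing.append(traj)
        rows.append(dict(
            molecule_id=tr.molecule_id, bleach_frame=det.bleach_frame,
            step_count=det.step_count, snr_background=snr, n_blinks=blinks,
            fret_frames=fret_frames, passed=(reason == ""), reason=reason,
        ))
    return passing, QCReport(pd.DataFrame(rows))
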
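"""Body score and segmentation of the ECTS into variable-length actions.

Action boundaries are placed where the dynamics of the coefficient series
changes.  A scalar *body score* — the eigenvalue-weighted sum of absolute
coefficients — peaks at the most bent posture; an action is a local maximum
of the body score bounded by the adjacent minima.  Periods of low activity
(browsing worms pausing in food) are detected separately from the body-score
derivative and added to the action collection before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .eigenshape import ECTS

DEFAULT_MASTER = 0.1
DEFAULT_LOW_FRAC = 0.5
DEFAULT_LOW_MIN_DUR_S = 0.5
MIN_SEGMENT_FRAMES = 2

__all__ = [
    "BodyScore",
    "ActionSegment",
    "body_score",
    "find_extrema",
    "segment_actions",
    "detect_low_activity",
    "segment_recording",
    "write_segment_csv",
    "read_segment_csv",
]


@dataclass
class BodyScore:
    """Non-negative bending score per frame; masked where the ECTS is."""

    score: np.ndarray  # (T,), NaN on masked frames
    frame_rate: float
    mask: np.ndarray  # (T,) bool
    derived_from: ECTS | None = None

    @property
    def n_frames(self) -> int:
        return self.score.shape[0]


@dataclass
class ActionSegment:
    """Half-open frame interval [start, end) holding one candidate action."""

    start: int
    end: int
    peak: int
    kind: Literal["active", "low_activity"]
    curve: np.ndarray | None = None  # (end-start, n_dims) ECTS slice

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment needs start < end")
        if not self.start <= self.peak < self.end:
            raise ValueError("peak must lie inside [start, end)")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def body_score(ects: ECTS) -> BodyScore:
    """score(t) = Σ_i w_i · |α_i(t)| with w the normalized eigenvalue weights.

    Absolute values are essential: bends of opposite sign would otherwise
    cancel, and the score maximum must mark the most bent posture
    (α = (0, 0, 0) is a flat body, score 0).
    """
    score = np.abs(ects.alpha) @ ects.eigenvalue_weights
    score = np.where(ects.missing_mask, np.nan, score)
    return BodyScore(score, ects.frame_rate, ects.missing_mask.copy(), ects)


def _unmasked_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of consecutive unmasked frames."""
    runs = []
    T = mask.shape[0]
    t = 0
    while t < T:
        if mask[t]:
            t += 1
            continue
        start = t
        while t < T and not mask[t]:
            t += 1
        runs.append((start, t))
    return runs


def _robust_amplitude(score: np.ndarray, mask: np.ndarray) -> float:
    vals = score[~mask]
    if vals.size == 0:
        return 0.0
    lo, hi = np.percentile(vals, [5.0, 95.0])
    return float(hi - lo)


def find_extrema(
    bs: BodyScore, master: float = DEFAULT_MASTER
) -> list[tuple[int, str]]:
    """Alternating minima/maxima of the body score.

    A maximum is retained if its topographic prominence is at least
    ``master`` times the robust (5th–95th percentile) amplitude of the
    score.  Between retained maxima the lowest frame is a minimum, and the
    endpoints of each unmasked run are padded as minima, so the list starts
    and ends with a minimum.  Runs without a retained maximum contribute no
    extrema.  ``master`` is the single tunable of the segmentation; results
    are insensitive to ±25% changes.
    """
    if master <= 0:
        raise ValueError("master must be positive")
    amp = _robust_amplitude(bs.score, bs.mask)
    out: list[tuple[int, str]] = []
    if amp == 0.0:
        return out
    threshold = master * amp
    for start, end in _unmasked_runs(bs.mask):
        run = bs.score[start:end]
        if run.size < 3:
            continue
        peaks, _ = find_peaks(run, prominence=threshold)
        if peaks.size == 0:
            continue
        extrema: list[tuple[int, str]] = [(start + int(np.argmin(run[: peaks[0] + 1])), "min")]
        for i, p in enumerate(peaks):
            extrema.append((start + int(p), "max"))
            if i + 1 < peaks.size:
                seg = run[p : peaks[i + 1] + 1]
                extrema.append((start + int(p) + int(np.argmin(seg)), "min"))
        last = peaks[-1]
        extrema.append((start + int(last) + int(np.argmin(run[last:])), "min"))
        out.extend(extrema)
    return out


def segment_actions(
    bs: BodyScore,
    ects: ECTS | None = None,
    master: float = DEFAULT_MASTER,
) -> list[ActionSegment]:
    """One active segment per retained body-score maximum.

    Segment boundaries are the bounding minima (the run endpoints at the
    edges); consecutive segments share a boundary frame, kept disjoint by
    the half-open convention.  Masked gaps split segments.
    """
    if ects is None:
        ects = bs.derived_from
    segments: list[ActionSegment] = []
    amp = _robust_amplitude(bs.score, bs.mask)
    if amp == 0.0:
        return segments
    threshold = master * amp
    for start, end in _unmasked_runs(bs.mask):
        run = bs.score[start:end]
        if run.size < 3:
            continue
        peaks, _ = find_peaks(run, prominence=threshold)
        if peaks.size == 0:
            continue
        bounds = [0]
        for i in range(peaks.size - 1):
            seg = run[peaks[i] : peaks[i + 1] + 1]
            bounds.append(int(peaks[i]) + int(np.argmin(seg)))
        bounds.append(run.size)
        for i, p in enumerate(peaks):
            s, e = start + bounds[i], start + bounds[i + 1]
            if e - s < MIN_SEGMENT_FRAMES:
                continue
            curve = ects.alpha[s:e].copy() if ects is not None else None
            segments.append(ActionSegment(s, e, start + int(p), "active", curve))
    return segments


def detect_low_activity(
    bs: BodyScore,
    ects: ECTS | None = None,
    frac: float = DEFAULT_LOW_FRAC,
    min_dur_s: float = DEFAULT_LOW_MIN_DUR_S,
) -> list[ActionSegment]:
    """Maximal intervals where the body score barely changes.

    An interval qualifies when |d(score)/dt| stays below ``frac`` times its
    mean (over unmasked frames) for more than ``min_dur_s`` seconds.  With a
    perfectly constant score the mean derivative is zero, and the criterion
    degenerates to |d| = 0.
    """
    if ects is None:
        ects = bs.derived_from
    out: list[ActionSegment] = []
    deriv = np.full_like(bs.score, np.nan)
    for start, end in _unmasked_runs(bs.mask):
        if end - start >= 2:
            deriv[start:end] = np.abs(np.gradient(bs.score[start:end]))
    valid = ~np.isnan(deriv)
    if not valid.any():
        return out
    mean_d = float(np.mean(deriv[valid]))
    threshold = frac * mean_d
    if threshold > 0:
        low = valid & (deriv < threshold)
    else:
        low = valid & (deriv == 0.0)
    min_frames = int(np.floor(min_dur_s * bs.frame_rate))
    for start, end in _unmasked_runs(~low):
        dur_s = (end - start) / bs.frame_rate
        if dur_s > min_dur_s and end - start >= MIN_SEGMENT_FRAMES:
            run = bs.score[start:end]
            peak = start + int(np.nanargmax(run))
            curve = ects.alpha[start:end].copy() if ects is not None else None
            out.append(ActionSegment(start, end, peak, "low_activity", curve))
    return out


def _subtract_intervals(
    seg: ActionSegment,
    holes: Sequence[tuple[int, int]],
    bs: BodyScore,
    ects: ECTS | None,
) -> list[ActionSegment]:
    """Remove [start, end) holes from an active segment, re-deriving peaks."""
    pieces: list[tuple[int, int]] = []
    cur = seg.start
    for h0, h1 in sorted(holes):
        h0, h1 = max(h0, seg.start), min(h1, seg.end)
        if h1 <= cur:
            continue
        if h0 > cur:
            pieces.append((cur, h0))
        cur = max(cur, h1)
    if cur < seg.end:
        pieces.append((cur, seg.end))
    out = []
    for s, e in pieces:
        if e - s < MIN_SEGMENT_FRAMES:
            continue
        if s <= seg.peak < e:
            peak = seg.peak
        else:
            peak = s + int(np.nanargmax(bs.score[s:e]))
        curve = ects.alpha[s:e].copy() if ects is not None else None
        out.append(ActionSegment(s, e, peak, "active", curve))
    return out


def segment_recording(
    ects: ECTS,
    master: float = DEFAULT_MASTER,
    low_frac: float = DEFAULT_LOW_FRAC,
    low_min_dur_s: float = DEFAULT_LOW_MIN_DUR_S,
    detect_low: bool = True,
    drop_edge: bool = True,
    curve_ects: ECTS | None = None,
) -> list[ActionSegment]:
    """Full segmentation: active actions plus low-activity intervals.

    Low-activity segments win ties: overlapping active segments are
    truncated so that the returned collection is disjoint and sorted.
    With ``drop_edge`` (default), active segments that abut the series
    start/end or a masked gap are discarded: such segments lack a true
    bounding minimum, so their action may be an arbitrarily truncated
    observation.  ``curve_ects`` lets the stored curve slices come from a
    different (e.g. unsmoothed) series than the one segmented: the smoothed
    score gives stable boundaries while the raw coefficients keep the
    clustering noise white.
    """
    bs = body_score(ects)
    src_ects = curve_ects if curve_ects is not None else ects
    active = segment_actions(bs, src_ects, master)
    if drop_edge:
        edges = set()
        for r0, r1 in _unmasked_runs(bs.mask):
            edges.add(r0)
            edges.add(r1)
        active = [s for s in active if s.start not in edges and s.end not in edges]
    if not detect_low:
        return sorted(active, key=lambda s: s.start)
    low = detect_low_activity(bs, src_ects, low_frac, low_min_dur_s)
    holes = [(s.start, s.end) for s in low]
    merged: list[ActionSegment] = list(low)
    for seg in active:
        overlapping = [h for h in holes if h[0] < seg.end and h[1] > seg.start]
        if overlapping:
            merged.extend(_subtract_intervals(seg, overlapping, bs, src_ects))
        else:
            merged.append(seg)
    return sorted(merged, key=lambda s: s.start)


# ---------------------------------------------------------------------------
# I/O


def write_segment_csv(
    path: str | Path, segments: Sequence[ActionSegment], recording_id: str = "rec0"
) -> None:
    df = pd.DataFrame(
        {
            "recording_id": recording_id,
            "start_frame": [s.start for s in segments],
            "end_frame": [s.end for s in segments],
            "peak_frame": [s.peak for s in segments],
            "kind": [s.kind for s in segments],
        }
    )
    df.to_csv(path, index=False)


def read_segment_csv(
    path: str | Path, ects: ECTS | None = None
) -> list[ActionSegment]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples():
        curve = (
            ects.alpha[int(row.start_frame) : int(row.end_frame)].copy()
            if ects is not None
            else None
        )
        out.append(
            ActionSegment(
                int(row.start_frame),
                int(row.end_frame),
                int(row.peak_frame),
                str(row.kind),
                curve,
            )
        )
    return out
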
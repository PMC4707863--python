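"""Benchmarking behavioural annotations against ground truth.

A behavioural *event* is a maximal run of consecutive frames tagged with the
same behaviour.  A predicted event counts as a true positive when at least
50% of its frames carry the same (mapped) label in the ground-truth
annotation; otherwise it is a false positive, and a truth event missing
matching coverage is a false negative.  Precision P, sensitivity S and the
F-score F = 2PS/(P+S) summarize agreement per behaviour and pooled.

Utilities here also repair "flickering" frame-wise annotations (single-frame
dropouts inside an event), map between annotators' label vocabularies, and
stratify annotator agreement by classification entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import MembershipPosterior

DEFAULT_MAX_GAP = 3
DEFAULT_MIN_OVERLAP = 0.5
UNKNOWN = "unknown"

__all__ = [
    "EventAnnotation",
    "MatchCounts",
    "ScoreReport",
    "fix_flicker",
    "events_from_frames",
    "frames_from_events",
    "map_labels",
    "apply_exclusion",
    "match_events",
    "scores",
    "f_score",
    "round_half_up",
    "uncertainty_stratified_agreement",
    "read_annotation_csv",
    "write_report",
]


@dataclass
class EventAnnotation:
    """Sorted list of labelled behavioural events on one frame timeline."""

    events: list[tuple[int, int, str]]  # (start incl., end excl., label)
    source_name: str = ""

    def __post_init__(self) -> None:
        for s, e, _ in self.events:
            if not s < e:
                raise ValueError("event needs start < end")
        self.events = sorted(self.events, key=lambda ev: (ev[0], ev[1]))

    @property
    def labels(self) -> set[str]:
        return {lab for _, _, lab in self.events}

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class MatchCounts:
    """Per-label and pooled TP/FP/FN event counts."""

    per_label: dict[str, tuple[int, int, int]]  # label -> (tp, fp, fn)

    @property
    def pooled(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.per_label.values())
        fp = sum(v[1] for v in self.per_label.values())
        fn = sum(v[2] for v in self.per_label.values())
        return tp, fp, fn


@dataclass
class ScoreReport:
    """Precision / sensitivity / F-score per label and pooled."""

    per_label: dict[str, tuple[float, float, float]]
    pooled: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"behaviour": lab, "precision": p, "sensitivity": s, "f_score": f}
            for lab, (p, s, f) in self.per_label.items()
        ]
        p, s, f = self.pooled
        rows.append(
            {
                "behaviour": "all behaviours",
                "precision": p,
                "sensitivity": s,
                "f_score": f,
            }
        )
        return pd.DataFrame(rows)

    def pretty(self, decimals: int = 2) -> str:
        df = self.to_frame()
        for c in ("precision", "sensitivity", "f_score"):
            df[c] = [round_half_up(v, decimals) for v in df[c]]
        return df.to_string(index=False)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding matching printed tables (0.005 rounds up)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Frame-level utilities


def fix_flicker(indicator: Sequence[int], max_gap: int = DEFAULT_MAX_GAP) -> np.ndarray:
    """Bridge sub-threshold gaps in a binary behaviour indicator.

    Gaps of 0s strictly shorter than ``max_gap`` frames between two 1-runs
    are filled, e.g. 0011011100 → 0011111100.  Idempotent and monotone.
    """
    x = np.asarray(indicator, dtype=int).copy()
    ones = np.nonzero(x)[0]
    if ones.size < 2:
        return x
    for idx, g in zip(ones[:-1], np.diff(ones)):
        gap_len = g - 1  # zeros between consecutive 1s
        if 0 < gap_len < max_gap:
            x[idx + 1 : idx + g] = 1
    return x


def events_from_frames(
    frame_labels: Sequence[str], source_name: str = ""
) -> EventAnnotation:
    """Maximal constant-label runs become events; unknown frames break runs."""
    labels = list(frame_labels)
    events = []
    t, T = 0, len(labels)
    while t < T:
        lab = labels[t]
        start = t
        while t < T and labels[t] == lab:
            t += 1
        if lab is not None and str(lab) not in {UNKNOWN, "nan", ""}:
            events.append((start, t, str(lab)))
    return EventAnnotation(events, source_name)


def frames_from_events(ann: EventAnnotation, n_frames: int) -> np.ndarray:
    """Rasterize events to a per-frame label array (unknown elsewhere)."""
    out = np.array([UNKNOWN] * n_frames, dtype=object)
    for s, e, lab in ann.events:
        out[s:e] = lab
    return out


def map_labels(a: EventAnnotation, mapping: Mapping[str, str]) -> EventAnnotation:
    """Apply a many-to-one label map and merge adjacent same-label events.

    Raises on any label present in the annotation but absent from the map
    (identity entries must be listed explicitly for unaffected labels).
    """
    missing = a.labels - set(mapping)
    if missing:
        raise KeyError(f"labels without mapping: {sorted(missing)}")
    mapped = [(s, e, mapping[lab]) for s, e, lab in a.events]
    merged: list[tuple[int, int, str]] = []
    for s, e, lab in sorted(mapped):
        if merged and merged[-1][2] == lab and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return EventAnnotation(merged, a.source_name)


def apply_exclusion(
    frame_labels: Sequence[str], excluded: Sequence[bool]
) -> list[str]:
    """Mark excluded frames unknown so they contribute no events."""
    return [
        UNKNOWN if ex else lab for lab, ex in zip(frame_labels, excluded)
    ]


# ---------------------------------------------------------------------------
# Event matching and scores


def match_events(
    pred: EventAnnotation,
    truth: EventAnnotation,
    n_frames: int | None = None,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> MatchCounts:
    """Count TP/FP/FN events under the fractional-overlap rule.

    A predicted event is a true positive iff at least ``min_overlap`` of its
    frames carry the same label in the truth's frame timeline (coverage may
    come from several truth events); a truth event with less than
    ``min_overlap`` same-label coverage in the prediction is a false
    negative.  Each event is judged exactly once.  Construction makes the
    rule symmetric: swapping pred and truth swaps FP and FN.
    """
    ends = [e for _, e, _ in pred.events] + [e for _, e, _ in truth.events]
    needed = max(ends) if ends else 0
    if n_frames is None:
        n_frames = needed
    elif needed > n_frames:
        raise ValueError("events extend beyond the stated timeline length")
    pred_frames = frames_from_events(pred, n_frames)
    truth_frames = frames_from_events(truth, n_frames)
    labels = sorted(pred.labels | truth.labels)
    per_label: dict[str, tuple[int, int, int]] = {}
    for lab in labels:
        tp = fp = fn = 0
        for s, e, evlab in pred.events:
            if evlab != lab:
                continue
            cover = np.mean(truth_frames[s:e] == lab)
            if cover >= min_overlap:
                tp += 1
            else:
                fp += 1
        for s, e, evlab in truth.events:
            if evlab != lab:
                continue
            cover = np.mean(pred_frames[s:e] == lab)
            if cover < min_overlap:
                fn += 1
        per_label[lab] = (tp, fp, fn)
    return MatchCounts(per_label)


def f_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _psf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn("no predicted events; precision set to 0", stacklevel=3)
        p = 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no truth events; sensitivity set to 0", stacklevel=3)
        s = 0.0
    else:
        s = tp / (tp + fn)
    return p, s, f_score(p, s)


def scores(counts: MatchCounts) -> ScoreReport:
    """Precision, sensitivity and F per behaviour; pooled counts for "all"."""
    per_label = {lab: _psf(*c) for lab, c in counts.per_label.items()}
    return ScoreReport(per_label, _psf(*counts.pooled))


# ---------------------------------------------------------------------------
# Entropy-stratified agreement


def uncertainty_stratified_agreement(
    posteriors: Sequence[MembershipPosterior],
    pred_labels: Sequence[str],
    truth_frames: Sequence[str],
    action_intervals: Sequence[tuple[int, int]],
    K: int,
    h_frac: float = 0.25,
) -> dict[str, float]:
    """Annotator agreement split by classification entropy.

    Actions with H < h_frac · H_max (H_max = log2 K) form the
    low-uncertainty bucket; agreement is the fraction whose mapped hard
    label equals the truth's majority label over the action's frames.
    Empty buckets report NaN.
    """
    truth_frames = np.asarray(truth_frames, dtype=object)
    h_max = np.log2(K) if K > 1 else 1.0
    agree_low, agree_high = [], []
    for post, lab, (s, e) in zip(posteriors, pred_labels, action_intervals):
        span = truth_frames[s:e]
        span = span[span != UNKNOWN]
        if span.size == 0:
            continue
        vals, cnt = np.unique(span, return_counts=True)
        majority = vals[np.argmax(cnt)]
        hit = float(lab == majority)
        if post.entropy < h_frac * h_max:
            agree_low.append(hit)
        else:
            agree_high.append(hit)
    return {
        "low_uncertainty_agreement": float(np.mean(agree_low)) if agree_low else float("nan"),
        "high_uncertainty_agreement": float(np.mean(agree_high)) if agree_high else float("nan"),
        "n_low": len(agree_low),
        "n_high": len(agree_high),
    }


# ---------------------------------------------------------------------------
# I/O


def read_annotation_csv(path: str | Path, source_name: str = "") -> EventAnnotation:
    """Read per-frame (frame, label) or event (start, end, label) CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if {"start", "end", "label"}.issubset(cols):
        events = [
            (int(r.start), int(r.end), str(r.label)) for r in df.itertuples()
        ]
        return EventAnnotation(events, source_name)
    if {"frame", "label"}.issubset(cols):
        df = df.sort_values("frame")
        return events_from_frames(df["label"].astype(str).tolist(), source_name)
    raise ValueError("annotation CSV needs (frame, label) or (start, end, label)")


def write_report(path: str | Path, report: ScoreReport) -> None:
    report.to_frame().to_csv(path, index=False)
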
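"""Midline extraction and angle-vector representation of posture.

A single video frame of a crawling animal (larva or worm) is reduced to its
morphological skeleton, the *midline*, which serves as a proxy for posture.
Midlines are normalized to 71 equidistant points with the head–tail axis
rotated onto the x-axis, and converted to a 70-dimensional vector of
per-segment orientation angles θ_i ∈ (−π, π].  A straight animal is the
zero vector; mirror-imaged postures have negated angles.

Coordinates follow the image convention (origin top-left, x rightward,
y downward); frame indices are 0-based and intervals half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

N_MIDLINE_POINTS = 71
N_ANGLES = N_MIDLINE_POINTS - 1

__all__ = [
    "BinaryFrame",
    "Midline",
    "AngleVector",
    "DroppedFrame",
    "EmptyFrameError",
    "DegenerateMidlineError",
    "extract_midline",
    "extract_midlines",
    "normalize_midline",
    "midline_to_angles",
    "angles_to_midline",
    "orient_like",
    "read_midline_csv",
    "read_wcon",
    "write_angle_matrix",
    "read_angle_matrix",
]


class EmptyFrameError(ValueError):
    """Raised when a frame contains no foreground pixels."""


class DegenerateMidlineError(ValueError):
    """Raised when a midline collapses to a single point."""


@dataclass(frozen=True)
class BinaryFrame:
    """A thresholded video frame: foreground = animal."""

    pixels: np.ndarray  # 2-D boolean grid
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass(frozen=True)
class DroppedFrame:
    """Marker for a frame whose posture could not be recovered.

    Emitted for self-intersecting ("doughnut") postures whose skeleton
    contains a cycle and therefore has no meaningful head–tail path.
    Distinct from :class:`EmptyFrameError`, which signals absent input.
    """

    frame_index: int
    reason: str = "self-intersecting skeleton"


@dataclass
class Midline:
    """Ordered chain of (x, y) points tracing the animal's body axis."""

    points: np.ndarray  # (N, 2) float
    frame_index: int = 0
    head_first: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("midline needs >= 2 (x, y) points")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive midline points must be distinct")
        self.points = pts

    @property
    def length(self) -> float:
        """Total arc length of the polyline (pixels)."""
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def reversed(self) -> "Midline":
        return Midline(self.points[::-1].copy(), self.frame_index, not self.head_first)


@dataclass(frozen=True)
class AngleVector:
    """70 per-segment orientation angles θ_i (radians) in (−π, π]."""

    theta: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (N_ANGLES,):
            raise ValueError(f"theta must have length {N_ANGLES}")
        if np.any(th <= -np.pi) or np.any(th > np.pi):
            raise ValueError("angles must lie in (-pi, pi]")
        object.__setattr__(self, "theta", th)


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval (−π, π]."""
    wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    # mod maps π to −π; restore the closed upper endpoint
    return np.where(wrapped == -np.pi, np.pi, wrapped)


# ---------------------------------------------------------------------------
# Skeleton → midline


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pix:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _tree_diameter_path(g: nx.Graph) -> list[tuple[int, int]]:
    """Longest geodesic path of a tree via two Dijkstra sweeps."""
    start = next(iter(g.nodes))
    dist = nx.single_source_dijkstra_path_length(g, start)
    far1 = max(dist, key=dist.get)
    dist2, paths = nx.single_source_dijkstra(g, far1)
    far2 = max(dist2, key=dist2.get)
    return paths[far2]


def extract_midline(frame: BinaryFrame) -> Midline | DroppedFrame:
    """Skeletonize a binary frame and return the longest path as a midline.

    The longest geodesic path between skeleton endpoints is taken as the
    midline; short spurs produced by raster noise are never on this path,
    which subsumes explicit branch pruning.  Skeletons containing a cycle
    (the animal curled on itself) yield a :class:`DroppedFrame` marker.

    Raises
    ------
    EmptyFrameError
        if the frame has no foreground pixels.
    """
    px = frame.pixels
    if not px.any():
        raise EmptyFrameError(f"frame {frame.frame_index} has no foreground")
    labels, n_comp = cc_label(px, connectivity=2, return_num=True)
    if n_comp > 1:
        # keep the largest component; specks are segmentation noise
        sizes = np.bincount(labels.ravel())[1:]
        px = labels == (int(np.argmax(sizes)) + 1)
    skel = skeletonize(px)
    if not skel.any():
        raise EmptyFrameError(f"frame {frame.frame_index} skeletonized to nothing")
    g = _skeleton_graph(skel)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    sub = g.subgraph(comps[0])
    if sub.number_of_edges() >= sub.number_of_nodes():
        return DroppedFrame(frame.frame_index)
    if sub.number_of_nodes() < 2:
        return DroppedFrame(frame.frame_index, reason="skeleton collapsed to a point")
    path = _tree_diameter_path(sub)
    pts = np.array([(c, r) for r, c in path], dtype=float)  # (x, y) image order
    return Midline(pts, frame.frame_index)


def orient_like(m: Midline, prev: Midline | None) -> Midline:
    """Fix head/tail orientation by consistency with the previous frame.

    Chooses the orientation that minimizes the summed displacement of the
    two endpoints relative to ``prev``.  Head identity is never detected;
    the eigenshape analysis is sign-symmetric, so only frame-to-frame
    consistency matters.
    """
    if prev is None:
        return m
    a, b = m.points[0], m.points[-1]
    pa, pb = prev.points[0], prev.points[-1]
    keep = np.linalg.norm(a - pa) + np.linalg.norm(b - pb)
    flip = np.linalg.norm(b - pa) + np.linalg.norm(a - pb)
    return m.reversed() if flip < keep else m


def extract_midlines(
    frames: Iterable[BinaryFrame],
) -> list[Midline | DroppedFrame]:
    """Extract midlines for a frame sequence with consistent orientation."""
    out: list[Midline | DroppedFrame] = []
    prev: Midline | None = None
    for frame in frames:
        res = extract_midline(frame)
        if isinstance(res, Midline):
            res = orient_like(res, prev)
            prev = res
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Normalization and angles


def normalize_midline(m: Midline, n_points: int = N_MIDLINE_POINTS) -> Midline:
    """Resample to ``n_points`` equidistant points and rotate onto the x-axis.

    The output midline starts at the origin with its endpoints on the
    x-axis (equal y-coordinates), removing the animal's overall rotation
    relative to the plate.  Spacing is uniform in arc length along the
    input polyline.  Body length is preserved — it is recorded but plays
    no role downstream.
    """
    pts = m.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0.0])
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise DegenerateMidlineError("all midline points coincide")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n_points)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    new = np.column_stack([x, y])
    new -= new[0]
    chord = new[-1]
    angle = np.arctan2(chord[1], chord[0])
    c, sn = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -sn], [sn, c]])
    new = new @ rot.T
    # numerical zero of final y
    new[-1, 1] = 0.0
    return Midline(new, m.frame_index, m.head_first)


def midline_to_angles(m: Midline) -> AngleVector:
    """Per-segment orientation angles of a normalized 71-point midline."""
    pts = m.points
    if pts.shape[0] != N_MIDLINE_POINTS:
        raise ValueError(
            f"expected {N_MIDLINE_POINTS} points, got {pts.shape[0]}; "
            "run normalize_midline first"
        )
    d = np.diff(pts, axis=0)
    theta = _wrap_angle(np.arctan2(d[:, 1], d[:, 0]))
    return AngleVector(theta, m.frame_index)


def angles_to_midline(
    theta: np.ndarray | AngleVector,
    segment_length: float = 1.0,
    frame_index: int = 0,
) -> Midline:
    """Rebuild a point chain from orientation angles with equal segments."""
    th = theta.theta if isinstance(theta, AngleVector) else np.asarray(theta, float)
    dx = segment_length * np.cos(th)
    dy = segment_length * np.sin(th)
    pts = np.zeros((th.size + 1, 2))
    pts[1:, 0] = np.cumsum(dx)
    pts[1:, 1] = np.cumsum(dy)
    return Midline(pts, frame_index)


# ---------------------------------------------------------------------------
# I/O


def read_midline_csv(path: str | Path) -> list[Midline]:
    """Read per-frame midlines from CSV columns frame, point_index, x, y."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"midline CSV needs columns {sorted(required)}")
    out = []
    for frame, grp in df.sort_values(["frame", "point_index"]).groupby("frame"):
        out.append(Midline(grp[["x", "y"]].to_numpy(float), int(frame)))
    return out


def read_wcon(path: str | Path) -> list[Midline]:
    """Read skeleton records from a WCON (Worm tracker Commons) file.

    Supports the common layout where ``data`` entries carry per-frame
    ``x``/``y`` coordinate lists.
    """
    with open(path) as fh:
        doc = json.load(fh)
    records = doc["data"]
    if isinstance(records, dict):
        records = [records]
    out: list[Midline] = []
    idx = 0
    for rec in records:
        xs, ys = rec["x"], rec["y"]
        if xs and np.isscalar(xs[0]):
            xs, ys = [xs], [ys]
        for fx, fy in zip(xs, ys):
            out.append(Midline(np.column_stack([fx, fy]).astype(float), idx))
            idx += 1
    return out


def frames_to_angle_matrix(
    midlines: Sequence[Midline | DroppedFrame],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize midlines and stack angle vectors.

    Returns ``(angles, missing)`` where ``angles`` is (T, 70) with NaN rows
    for dropped frames and ``missing`` the boolean dropped-frame mask.
    """
    T = len(midlines)
    angles = np.full((T, N_ANGLES), np.nan)
    missing = np.ones(T, dtype=bool)
    for t, m in enumerate(midlines):
        if isinstance(m, DroppedFrame):
            continue
        angles[t] = midline_to_angles(normalize_midline(m)).theta
        missing[t] = False
    return angles, missing


def write_angle_matrix(
    path: str | Path, angles: np.ndarray, missing: np.ndarray
) -> None:
    """Write a frames × 70 angle matrix with a dropped-frame mask column."""
    path = Path(path)
    df = pd.DataFrame(angles, columns=[f"theta{i+1}" for i in range(angles.shape[1])])
    df.insert(0, "frame", np.arange(angles.shape[0]))
    df["missing"] = missing.astype(int)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("angles", data=angles)
            fh.create_dataset("missing", data=missing.astype(np.uint8))
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_angle_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as fh:
            return fh["angles"][()], fh["missing"][()].astype(bool)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c for c in df.columns if c.startswith("theta")]
    return df[cols].to_numpy(float), df["missing"].to_numpy(bool)
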
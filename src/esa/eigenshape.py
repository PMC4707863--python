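"""Eigenshape basis (eigenworms / eigenmaggots) and the coefficient time series.

Principal component analysis of the frames × 70 angle matrix yields an
orthonormal basis of *eigenshapes*; any posture is the mean posture plus a
weighted superposition of eigenshapes.  The trajectory of the three leading
coefficients α_i(t) is the eigenshape coefficient time series (ECTS) — for
both larva and worm three components capture ≈ 90% of postural variance, so
the ECTS is an accurate low-dimensional description of behaviour.

Missing frames (dropped postures) are linearly interpolated when the gap is
shorter than 0.5 s; longer gaps stay masked.  After interpolation the series
is smoothed with a short inverse-distance-weighted running average that
never reaches across a masked gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .posture import N_ANGLES, _wrap_angle

DEFAULT_N_DIMS = 3
DEFAULT_MAX_GAP_S = 0.5
DEFAULT_SMOOTH_WINDOW = 4

__all__ = [
    "EigenshapeBasis",
    "ECTS",
    "fit_eigenshapes",
    "project",
    "reconstruct",
    "variance_explained",
    "interpolate_gaps",
    "smooth_ects",
    "build_ects",
    "write_ects_csv",
    "read_ects_csv",
    "write_ects_hdf5",
    "read_ects_hdf5",
    "read_ects_table",
]


@dataclass
class EigenshapeBasis:
    """Full PCA basis of the angle-vector distribution.

    components[i] is the i-th eigenshape (unit 70-vector); eigenvalues are
    the variances along components, sorted descending.  Signs are fixed so
    each component's largest-magnitude entry is positive, making repeated
    fits on identical data bit-identical.
    """

    mean_angles: np.ndarray  # (70,)
    components: np.ndarray  # (70, 70), rows are eigenshapes
    eigenvalues: np.ndarray  # (70,), descending
    n_frames_fit: int

    def __post_init__(self) -> None:
        self.mean_angles = np.asarray(self.mean_angles, float)
        self.components = np.asarray(self.components, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if self.mean_angles.shape != (N_ANGLES,):
            raise ValueError("mean_angles must be a 70-vector")
        if self.components.shape != (N_ANGLES, N_ANGLES):
            raise ValueError("components must be 70 x 70")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


@dataclass
class ECTS:
    """T × 3 eigenshape coefficient time series with a missing-frame mask."""

    alpha: np.ndarray  # (T, n_dims)
    frame_rate: float
    missing_mask: np.ndarray  # (T,) bool, True where no posture recoverable
    eigenvalue_weights: np.ndarray  # (n_dims,), normalized to sum 1

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        self.missing_mask = np.asarray(self.missing_mask, bool)
        self.eigenvalue_weights = np.asarray(self.eigenvalue_weights, float)
        if self.alpha.ndim != 2:
            raise ValueError("alpha must be 2-D (frames x dims)")
        if self.missing_mask.shape != (self.alpha.shape[0],):
            raise ValueError("missing_mask length must match alpha")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.eigenvalue_weights.shape != (self.alpha.shape[1],):
            raise ValueError("one eigenvalue weight per ECTS dimension")

    @property
    def n_frames(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_dims(self) -> int:
        return self.alpha.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def fit_eigenshapes(
    angles: np.ndarray, missing: np.ndarray | None = None
) -> EigenshapeBasis:
    """PCA of the angle matrix; returns the full 70-component basis.

    Rows flagged in ``missing`` (or containing NaN) are excluded from the
    fit.  Requires more valid frames than angle dimensions.
    """
    angles = np.asarray(angles, float)
    if missing is None:
        missing = np.any(np.isnan(angles), axis=1)
    valid = angles[~np.asarray(missing, bool)]
    n = valid.shape[0]
    if n <= N_ANGLES:
        raise ValueError(
            f"need more than {N_ANGLES} non-missing frames to fit eigenshapes, got {n}"
        )
    mean = valid.mean(axis=0)
    centred = valid - mean
    # SVD of the data matrix; eigenvalues of the covariance are s^2/(n-1)
    _, s, vt = np.linalg.svd(centred, full_matrices=True)
    eigvals = np.zeros(N_ANGLES)
    eigvals[: s.size] = s**2 / (n - 1)
    comps = vt
    # deterministic sign: largest-magnitude entry of each component positive
    flip = comps[np.arange(N_ANGLES), np.argmax(np.abs(comps), axis=1)] < 0
    comps[flip] *= -1.0
    return EigenshapeBasis(mean, comps, eigvals, n)


def project(v: np.ndarray, basis: EigenshapeBasis, d: int) -> np.ndarray:
    """Coefficients of the mean-centred angle vector(s) on the first d components."""
    if not 1 <= d <= N_ANGLES:
        raise ValueError(f"d must be in [1, {N_ANGLES}]")
    v = np.asarray(v, float)
    return (v - basis.mean_angles) @ basis.components[:d].T


def reconstruct(coeffs: np.ndarray, basis: EigenshapeBasis) -> np.ndarray:
    """mean + Σ α_i · component_i, re-wrapped to (−π, π]."""
    coeffs = np.atleast_1d(np.asarray(coeffs, float))
    d = coeffs.shape[-1]
    if d > N_ANGLES:
        raise ValueError("more coefficients than components")
    return _wrap_angle(basis.mean_angles + coeffs @ basis.components[:d])


def variance_explained(basis: EigenshapeBasis, d: int) -> float:
    """Cumulative variance fraction captured by the first d eigenshapes."""
    if not 1 <= d <= N_ANGLES:
        raise ValueError(f"d must be in [1, {N_ANGLES}]")
    return float(basis.variance_fractions[:d].sum())


# ---------------------------------------------------------------------------
# Gap interpolation and smoothing


def interpolate_gaps(
    alpha: np.ndarray,
    missing: np.ndarray,
    frame_rate: float,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate masked gaps strictly shorter than ``max_gap_s``.

    Filled gaps are unmasked; longer (or edge) gaps remain masked.  Returns
    a new (alpha, mask) pair.
    """
    alpha = np.array(alpha, float)
    mask = np.array(missing, bool)
    T = alpha.shape[0]
    t = 0
    while t < T:
        if not mask[t]:
            t += 1
            continue
        start = t
        while t < T and mask[t]:
            t += 1
        end = t  # gap is [start, end)
        gap_len = end - start
        interior = start > 0 and end < T
        if interior and gap_len / frame_rate < max_gap_s:
            left, right = start - 1, end
            frac = (np.arange(start, end) - left) / (right - left)
            alpha[start:end] = (
                alpha[left] + frac[:, None] * (alpha[right] - alpha[left])
            )
            mask[start:end] = False
    alpha[mask] = np.nan
    return alpha, mask


def _smoothing_weights(window: int = DEFAULT_SMOOTH_WINDOW) -> tuple[np.ndarray, int]:
    """Symmetric inverse-distance weights for a window of ``window`` neighbours.

    A window "of four frames" centred on t is read as the four neighbours
    {−2, −1, +1, +2} plus the centre; each tap's weight is ∝ 1/(|offset| + ½)
    so the filter stays symmetric and constant-preserving.
    """
    half = window // 2
    offsets = np.arange(-half, half + 1)
    w = 1.0 / (np.abs(offsets) + 0.5)
    return w / w.sum(), half


def smooth_ects(
    alpha: np.ndarray,
    mask: np.ndarray,
    window: int = DEFAULT_SMOOTH_WINDOW,
) -> np.ndarray:
    """Weighted running average applied within each unmasked run.

    Windows are truncated and renormalized at run edges; the filter never
    mixes values across a masked gap, and constants pass through unchanged.
    """
    alpha = np.asarray(alpha, float)
    mask = np.asarray(mask, bool)
    weights, half = _smoothing_weights(window)
    out = np.array(alpha)
    T = alpha.shape[0]
    t = 0
    while t < T:
        if mask[t]:
            t += 1
            continue
        start = t
        while t < T and not mask[t]:
            t += 1
        end = t
        run = alpha[start:end]
        n = end - start
        sm = np.zeros_like(run)
        norm = np.zeros(n)
        for k, off in enumerate(range(-half, half + 1)):
            lo_dst = max(0, -off)
            hi_dst = min(n, n - off)
            if lo_dst >= hi_dst:
                continue
            sm[lo_dst:hi_dst] += weights[k] * run[lo_dst + off : hi_dst + off]
            norm[lo_dst:hi_dst] += weights[k]
        out[start:end] = sm / norm[:, None]
    return out


def build_ects(
    angles: np.ndarray,
    missing: np.ndarray,
    basis: EigenshapeBasis,
    frame_rate: float,
    n_dims: int = DEFAULT_N_DIMS,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> ECTS:
    """Project frames onto the leading eigenshapes and clean the series.

    Pipeline: project to ``n_dims`` coefficients, interpolate short gaps
    (< ``max_gap_s``), then smooth within unmasked runs (``smooth_window=0``
    skips smoothing, for callers that smooth downstream).  The stored
    eigenvalue weights are the ``n_dims`` leading eigenvalues normalized to
    sum to 1; they set the body score and DTW weighting downstream.
    """
    angles = np.asarray(angles, float)
    missing = np.asarray(missing, bool)
    T = angles.shape[0]
    alpha = np.full((T, n_dims), np.nan)
    valid = ~missing
    if valid.any():
        alpha[valid] = project(angles[valid], basis, n_dims)
    alpha, mask = interpolate_gaps(alpha, missing, frame_rate, max_gap_s)
    if smooth_window and smooth_window > 1:
        alpha = smooth_ects(alpha, mask, smooth_window)
    ev = basis.eigenvalues[:n_dims]
    weights = ev / ev.sum() if ev.sum() > 0 else np.full(n_dims, 1.0 / n_dims)
    return ECTS(alpha, frame_rate, mask, weights)


# ---------------------------------------------------------------------------
# I/O


def write_ects_csv(path: str | Path, ects: ECTS) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(ects.n_frames),
            "time_s": ects.times,
            **{
                f"alpha{i+1}": ects.alpha[:, i] for i in range(ects.n_dims)
            },
            "missing": ects.missing_mask.astype(int),
        }
    )
    # %.17g keeps the round trip bit-exact (pandas' default drops a digit)
    df.to_csv(path, index=False, float_format="%.17g")


def read_ects_csv(
    path: str | Path,
    frame_rate: float | None = None,
    eigenvalue_weights: Sequence[float] | None = None,
) -> ECTS:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = sorted(
        (c for c in df.columns if c.startswith("alpha")), key=lambda c: int(c[5:])
    )
    alpha = df[cols].to_numpy(float)
    mask = (
        df["missing"].to_numpy(bool)
        if "missing" in df.columns
        else np.any(np.isnan(alpha), axis=1)
    )
    if frame_rate is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError("frame_rate not given and not inferable from time_s")
        frame_rate = 1.0 / float(np.median(np.diff(df["time_s"])))
    if eigenvalue_weights is None:
        eigenvalue_weights = np.full(alpha.shape[1], 1.0 / alpha.shape[1])
    w = np.asarray(eigenvalue_weights, float)
    return ECTS(alpha, float(frame_rate), mask, w / w.sum())


def write_ects_hdf5(path: str | Path, ects: ECTS) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("alpha", data=ects.alpha)
        fh.create_dataset("missing", data=ects.missing_mask.astype(np.uint8))
        fh.create_dataset("eigenvalue_weights", data=ects.eigenvalue_weights)
        fh.attrs["frame_rate"] = ects.frame_rate


def read_ects_hdf5(path: str | Path) -> ECTS:
    import h5py

    with h5py.File(path, "r") as fh:
        return ECTS(
            fh["alpha"][()],
            float(fh.attrs["frame_rate"]),
            fh["missing"][()].astype(bool),
            fh["eigenvalue_weights"][()],
        )


def read_ects_table(
    path: str | Path,
    column_map: Mapping[str, str],
    frame_rate: float,
    eigenvalue_weights: Sequence[float] | None = None,
) -> ECTS:
    """Read a pre-computed eigenshape coefficient table (e.g. a worm-database
    feature export) via a column-mapping config.

    ``column_map`` maps our names (``alpha1``, ``alpha2``, ``alpha3`` and
    optionally ``missing``) to the file's column names.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    dims = sorted(k for k in column_map if k.startswith("alpha"))
    alpha = np.column_stack([df[column_map[k]].to_numpy(float) for k in dims])
    if "missing" in column_map:
        mask = df[column_map["missing"]].to_numpy(bool)
    else:
        mask = np.any(np.isnan(alpha), axis=1)
    if eigenvalue_weights is None:
        eigenvalue_weights = np.full(alpha.shape[1], 1.0 / alpha.shape[1])
    w = np.asarray(eigenvalue_weights, float)
    return ECTS(alpha, frame_rate, mask, w / w.sum())
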
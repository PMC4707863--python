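"""Discreteness diagnostics: DTW maps, density cross sections, feature modality.

If an animal's behaviour consisted of discrete stereotyped states, its
actions would form clearly separated groups.  Three diagnostics probe this:

* a weighted dynamic-time-warping (DTW) distance matrix over a sample of
  actions, visualized by metric multidimensional scaling (MDS);
* kernel density cross sections through the aggregated, peak-aligned
  coefficient curves at a fixed time slice — stereotyped curve families
  appear as distinct high-density bands;
* histograms of per-action feature extrema (e.g. the maximum of the first
  coefficient), where discrete states appear as multimodality.

A simulated agent with genuinely discrete states shows separated map
regions, two bands per half-axis and bimodal feature histograms; the real
animals do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.manifold import smacof

from .clustering import AlignedAction

DEFAULT_SAMPLE_SIZE = 5000
DEFAULT_MDS_RESTARTS = 500
MODE_PROMINENCE_FRAC = 0.05

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "dtw_distance",
    "distance_matrix",
    "mds_embed",
    "density_cross_section",
    "count_modes",
    "feature_extremum_histogram",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise action distances with zero diagonal."""

    ids: np.ndarray  # action indices into the source collection
    d: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.isnan(self.d)):
            raise ValueError("distance matrix contains NaN")


@dataclass
class Embedding:
    """2-D MDS coordinates (arbitrary units) with goodness-of-fit R²."""

    coords: np.ndarray  # (n, dims)
    stress_r2: float


def dtw_distance(
    a: AlignedAction | np.ndarray,
    b: AlignedAction | np.ndarray,
    weights: Sequence[float],
) -> float:
    """Weighted dynamic time warping distance between two coefficient curves.

    Local cost between frames is the eigenvalue-weighted Euclidean distance
    sqrt(Σ_i w_i (a_i − b_i)²); the DP uses symmetric unit steps
    (diagonal/horizontal/vertical) with a boundary-complete monotone path,
    no window constraint and no length normalization.
    """
    va = a.values if isinstance(a, AlignedAction) else np.atleast_2d(a)
    vb = b.values if isinstance(b, AlignedAction) else np.atleast_2d(b)
    w = np.asarray(weights, float)
    diff = va[:, None, :] - vb[None, :, :]
    cost = np.sqrt(np.einsum("ijd,d->ij", diff**2, w))
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j - 1], prev[j], row[j - 1])
    return float(D[n, m])


def distance_matrix(
    actions: Sequence[AlignedAction],
    weights: Sequence[float],
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: int | None = None,
) -> DistanceMatrix:
    """Pairwise DTW on a seeded uniform sample without replacement."""
    n = len(actions)
    rng = np.random.default_rng(seed)
    if n > sample_size:
        ids = np.sort(rng.choice(n, size=sample_size, replace=False))
    else:
        ids = np.arange(n)
    sub = [actions[i] for i in ids]
    m = len(sub)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = dtw_distance(sub[i], sub[j], weights)
    return DistanceMatrix(ids, d)


def _embedding_r2(d: np.ndarray, coords: np.ndarray) -> float:
    """Squared Pearson correlation between input and embedded distances."""
    iu = np.triu_indices(d.shape[0], k=1)
    emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    x, y = d[iu], emb[iu]
    if x.std() == 0 or y.std() == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def mds_embed(
    dm: DistanceMatrix,
    dims: int = 2,
    n_restarts: int = DEFAULT_MDS_RESTARTS,
    seed: int | None = None,
) -> Embedding:
    """Metric MDS by stress majorization (SMACOF), best of random restarts.

    Each restart starts from random coordinates; the solution with the
    highest R² (squared correlation between input and embedded distances)
    is kept, so R² is non-decreasing in ``n_restarts``.
    """
    rng = np.random.default_rng(seed)
    best_coords, best_r2 = None, -1.0
    for _ in range(max(1, n_restarts)):
        coords, _ = smacof(
            dm.d,
            metric=True,
            n_components=dims,
            init=None,
            n_init=1,
            max_iter=2000,
            eps=1e-12,
            random_state=int(rng.integers(0, 2**31 - 1)),
            normalized_stress=False,
        )
        r2 = _embedding_r2(dm.d, coords)
        if r2 > best_r2:
            best_coords, best_r2 = coords, r2
    return Embedding(best_coords, best_r2)


# ---------------------------------------------------------------------------
# Density cross sections and feature histograms


def count_modes(
    values: np.ndarray,
    grid_size: int = 512,
    prominence_frac: float = MODE_PROMINENCE_FRAC,
) -> tuple[int, np.ndarray, np.ndarray]:
    """KDE mode count (Gaussian kernel, Silverman bandwidth).

    Maxima whose prominence is below ``prominence_frac`` of the global
    density maximum are discarded.  Returns (n_modes, grid, density); the
    density integrates to ~1 over the grid.  Degenerate (near-constant)
    samples report a single mode.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("no values to estimate density from")
    if np.ptp(values) < 1e-12:
        grid = np.array([values[0]])
        return 1, grid, np.array([np.inf])
    kde = gaussian_kde(values, bw_method="silverman")
    pad = 3.0 * kde.factor * values.std()
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    # interior-only search misses maxima at the grid edges; padding above
    # makes edge maxima impossible for a Gaussian KDE
    return int(peaks.size), grid, dens


def density_cross_section(
    actions: Sequence[AlignedAction],
    dim: int = 0,
    offset: float = 0.0,
    min_curves: int = 10,
) -> dict:
    """KDE of aligned-curve values at one time slice ("cross section").

    Only curves whose support covers ``offset`` contribute; values are
    linearly interpolated between observed frames.  Returns the sampled
    values, KDE grid/density and the persistent mode count.
    """
    vals = []
    for a in actions:
        if a.times[0] <= offset <= a.times[-1]:
            vals.append(float(np.interp(offset, a.times, a.values[:, dim])))
    if len(vals) == 0:
        raise ValueError(f"offset {offset} lies outside every curve's support")
    if len(vals) < min_curves:
        raise ValueError(
            f"only {len(vals)} curves cover offset {offset}; need >= {min_curves}"
        )
    values = np.asarray(vals)
    n_modes, grid, dens = count_modes(values)
    return {
        "values": values,
        "grid": grid,
        "density": dens,
        "n_modes": n_modes,
    }


def bands_per_half_axis(
    actions: Sequence[AlignedAction], dim: int = 0, offset: float = 0.0
) -> tuple[int, int]:
    """Mode counts of the cross section on the negative and positive half-axes."""
    cs = density_cross_section(actions, dim, offset)
    values = cs["values"]
    out = []
    for half in (values[values < 0], values[values > 0]):
        out.append(count_modes(half)[0] if half.size >= 5 else 0)
    return out[0], out[1]


def feature_extremum_histogram(
    actions: Sequence[AlignedAction],
    feature: Sequence[np.ndarray] | None = None,
    stat: Literal["max", "mean"] = "max",
    dim: int = 0,
    bins: int = 40,
) -> dict:
    """Per-action statistic of a frame-wise feature, with modality report.

    ``feature`` gives one per-frame series per action; by default the
    ``dim``-th coefficient column is used.  The per-action ``max`` (of the
    raw values) or ``mean`` is collected, histogrammed, and its KDE mode
    count classified as unimodal / bimodal / multimodal (degenerate for a
    constant feature).
    """
    if feature is None:
        feature = [a.values[:, dim] for a in actions]
    fn = {"max": np.max, "mean": np.mean}[stat]
    stats = np.array([float(fn(np.asarray(f, float))) for f in feature])
    hist, edges = np.histogram(stats, bins=bins)
    if np.ptp(stats) < 1e-12:
        modality = "degenerate"
        n_modes = 1
    else:
        n_modes, _, _ = count_modes(stats)
        modality = {1: "unimodal", 2: "bimodal"}.get(n_modes, "multimodal")
    return {
        "stats": stats,
        "hist": hist,
        "bin_edges": edges,
        "n_modes": n_modes,
        "modality": modality,
    }


# ---------------------------------------------------------------------------
# I/O


def write_distance_matrix(path: str | Path, dm: DistanceMatrix) -> None:
    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(path)


def write_embedding(path: str | Path, emb: Embedding, ids: np.ndarray) -> None:
    df = pd.DataFrame(
        {"id": ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
    )
    df.attrs["stress_r2"] = emb.stress_r2
    df.to_csv(path, index=False)
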
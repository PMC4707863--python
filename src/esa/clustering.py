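"""Peak alignment and spline-regression mixture clustering of actions.

Each segmented action is a short multi-dimensional ECTS curve.  Actions are
aligned in time at their body-score peak and clustered with a mixture model
whose components are cubic spline mean curves with diagonal Gaussian
observation noise — the curve analogue of a Gaussian mixture model.  Because
an action's likelihood is evaluated only over its own observed support,
sequences of unequal duration can belong to the same motif.

Parameters are learned by EM with many random-responsibility restarts; the
number of motifs is selected by BIC, and each action receives a posterior
membership distribution whose Shannon entropy quantifies classification
uncertainty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import logsumexp

from .eigenshape import ECTS
from .segmentation import ActionSegment

logger = logging.getLogger(__name__)

SPLINE_DEGREE = 3
N_INTERNAL_KNOTS = 3
DEFAULT_N_RESTARTS = 500
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6
NOISE_FLOOR = 1e-8
# coefficient ridge of the penalized spline refits: shrinks basis functions
# toward zero exactly where a cluster's members provide no support (bias on
# well-supported coefficients is < ~2%), keeping mean curves bounded on
# offsets observed only by other clusters
RIDGE = 1.0
# ΔBIC below this is weak statistical evidence for the selected model order
DELTA_BIC_STRONG_EVIDENCE = 3.75

__all__ = [
    "AlignedAction",
    "SplineMixtureModel",
    "MembershipPosterior",
    "align_actions",
    "canonicalize_side",
    "fit_spline_mixture",
    "bic",
    "select_k",
    "posterior",
    "annotate",
    "low_uncertainty_fraction",
    "DELTA_BIC_STRONG_EVIDENCE",
]


@dataclass
class AlignedAction:
    """An action's curve re-indexed so its reference frame sits at offset 0."""

    times: np.ndarray  # integer frame offsets relative to the peak
    values: np.ndarray  # (n, n_dims)
    source: ActionSegment | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("offsets must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]


@dataclass
class MembershipPosterior:
    """Posterior cluster membership of one action."""

    probs: np.ndarray  # (K,), sums to 1
    entropy: float  # Shannon entropy in bits
    hard_label: int  # argmax cluster


@dataclass
class SplineMixtureModel:
    """K cubic-spline cluster mean curves with Gaussian noise and weights.

    The observation noise is diagonal Gaussian with one variance per ECTS
    dimension, tied across clusters by default: with per-cluster variances
    and dozens of frames per action, the likelihood rewards splitting a
    genuine cluster by its members' chance-realized noise level, which
    inflates the selected K.  ``tied_variance=False`` restores per-cluster
    variances.
    """

    K: int
    knots: np.ndarray  # full knot vector incl. boundary repeats
    coefficients: np.ndarray  # (K, n_dims, n_basis)
    noise_var: np.ndarray  # (K, n_dims); rows identical when tied
    weights: np.ndarray  # (K,)
    loglik: float
    n_obs: int  # scalar observations entering the likelihood (frames x dims)
    n_actions: int = 0
    seed: int | None = None
    tied_variance: bool = True

    @property
    def n_dims(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_basis(self) -> int:
        return self.coefficients.shape[2]

    @property
    def n_params(self) -> int:
        """Free parameters: spline coefficients + noise variances + weights."""
        n_var = self.n_dims if self.tied_variance else self.K * self.n_dims
        return self.K * self.n_basis * self.n_dims + n_var + (self.K - 1)

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik

    def mean_curve(self, k: int, offsets: np.ndarray) -> np.ndarray:
        """Cluster k's spline mean evaluated at (clamped) offsets, (n, n_dims)."""
        x = np.clip(offsets, self.knots[0], self.knots[-1])
        X = _design_matrix(x, self.knots)
        return X @ self.coefficients[k].T

    def to_json(self, path: str | Path) -> None:
        doc = {
            "K": self.K,
            "knots": self.knots.tolist(),
            "coefficients": self.coefficients.tolist(),
            "noise_var": self.noise_var.tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "n_actions": self.n_actions,
            "seed": self.seed,
            "tied_variance": self.tied_variance,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplineMixtureModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            K=doc["K"],
            knots=np.asarray(doc["knots"], float),
            coefficients=np.asarray(doc["coefficients"], float),
            noise_var=np.asarray(doc["noise_var"], float),
            weights=np.asarray(doc["weights"], float),
            loglik=doc["loglik"],
            n_obs=doc["n_obs"],
            n_actions=doc.get("n_actions", 0),
            seed=doc.get("seed"),
            tied_variance=doc.get("tied_variance", True),
        )


# ---------------------------------------------------------------------------
# Alignment


def align_actions(segments: Sequence[ActionSegment]) -> list[AlignedAction]:
    """Shift each action in time so its reference frame sits at offset 0.

    Active actions are referenced at their body-score peak (the most bent
    posture); low-activity actions, which have no meaningful peak, at their
    midpoint.  Values are untouched.
    """
    out = []
    for seg in segments:
        if seg.curve is None:
            raise ValueError("segment carries no ECTS slice to align")
        ref = seg.peak if seg.kind == "active" else seg.start + seg.n_frames // 2
        offsets = np.arange(seg.start, seg.end) - ref
        out.append(AlignedAction(offsets, seg.curve, seg))
    return out


def canonicalize_side(actions: Sequence[AlignedAction]) -> list[AlignedAction]:
    """Flip sign-mirrored actions onto a canonical side.

    Bilateral body symmetry means a bend to the left and its mirror to the
    right are the same motif, but a mixture with single spline mean curves
    would split every motif into left/right pairs.  Each action whose first
    coefficient at offset 0 (or nearest observed frame) is negative is
    negated across all dimensions — the angle-space mirror reflection.
    """
    out = []
    for a in actions:
        i0 = int(np.argmin(np.abs(a.times)))
        if a.values[i0, 0] < 0:
            out.append(AlignedAction(a.times, -a.values, a.source))
        else:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# Spline machinery


def _make_knots(actions: Sequence[AlignedAction]) -> np.ndarray:
    """Cubic knot vector: 3 internal knots at offset quartiles of the pooled support.

    Boundary knots sit at the 5th/95th percentile of the pooled offsets
    rather than the extremes: offsets beyond are evaluated at the boundary
    (constant extrapolation via clipping in the design matrix), because the
    outermost offsets are observed by only a handful of actions and a free
    cubic tail fitted there is unconstrained.
    """
    pooled = np.concatenate([a.times for a in actions])
    lo, hi = np.percentile(pooled, [5.0, 95.0])
    if hi <= lo:
        lo, hi = pooled.min(), max(pooled.max(), pooled.min() + 1.0)
    internal = np.percentile(pooled, [25.0, 50.0, 75.0])
    internal = np.clip(internal, lo + 1e-9, hi - 1e-9)
    internal = np.maximum.accumulate(internal)
    return np.concatenate(
        [[lo] * (SPLINE_DEGREE + 1), internal, [hi] * (SPLINE_DEGREE + 1)]
    )


def _design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, float), knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, SPLINE_DEGREE).toarray()


@dataclass
class _Suffstats:
    """Per-action sufficient statistics for the weighted spline refits."""

    XtX: np.ndarray  # (N, B, B)
    XtY: np.ndarray  # (N, B, D)
    yty: np.ndarray  # (N, D)
    n: np.ndarray  # (N,) frames per action
    X: list[np.ndarray]
    Y: list[np.ndarray]


def _suffstats(actions: Sequence[AlignedAction], knots: np.ndarray) -> _Suffstats:
    Xs, Ys = [], []
    for a in actions:
        Xs.append(_design_matrix(a.times, knots))
        Ys.append(a.values)
    XtX = np.stack([X.T @ X for X in Xs])
    XtY = np.stack([X.T @ Y for X, Y in zip(Xs, Ys)])
    yty = np.stack([np.sum(Y**2, axis=0) for Y in Ys])
    n = np.array([X.shape[0] for X in Xs], float)
    return _Suffstats(XtX, XtY, yty, n, Xs, Ys)


def _m_step(
    resp: np.ndarray, ss: _Suffstats, tied_variance: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted spline refit per cluster/dimension; returns (coef, var, weights)."""
    N, B, D = ss.XtY.shape
    K = resp.shape[1]
    weights = resp.mean(axis=0)
    coef = np.empty((K, D, B))
    var = np.empty((K, D))
    ssr_k = np.empty((K, D))
    denom_k = np.empty(K)
    eye = RIDGE * np.eye(B)
    for k in range(K):
        r = resp[:, k]
        A = np.einsum("i,ibc->bc", r, ss.XtX) + eye
        Bmat = np.einsum("i,ibd->bd", r, ss.XtY)  # (B, D)
        beta = np.linalg.solve(A, Bmat)  # (B, D)
        coef[k] = beta.T
        # weighted SSR per dim: Σ_i r_i (y'y − 2β'X'y + β'X'Xβ)
        quad = np.einsum("bd,ibc,cd->id", beta, ss.XtX, beta)
        cross = np.einsum("ibd,bd->id", ss.XtY, beta)
        # the ridge acts as a N(0, sigma^2/RIDGE) prior on coefficients, so
        # the matching MAP variance update adds the penalty to the SSR —
        # this makes the penalized EM objective exactly monotone
        ssr_k[k] = np.einsum("i,id->d", r, ss.yty - 2.0 * cross + quad)
        ssr_k[k] += RIDGE * np.sum(beta**2, axis=0)
        denom_k[k] = max(float(r @ ss.n), 1e-12)
    if tied_variance:
        var[:] = np.maximum(ssr_k.sum(axis=0) / denom_k.sum(), NOISE_FLOOR)
    else:
        var = np.maximum(ssr_k / denom_k[:, None], NOISE_FLOOR)
    return coef, var, weights


def _action_logliks(
    coef: np.ndarray, var: np.ndarray, ss: _Suffstats
) -> np.ndarray:
    """(N, K) log-likelihood of each action under each cluster."""
    N = ss.n.shape[0]
    K, D, B = coef.shape
    # SSR_{ikd} = y'y − 2 β_k'X'y + β_k'X'Xβ_k
    quad = np.einsum("kdb,ibc,kdc->ikd", coef, ss.XtX, coef)
    cross = np.einsum("ibd,kdb->ikd", ss.XtY, coef)
    ssr = ss.yty[:, None, :] - 2.0 * cross + quad
    ll = -0.5 * (
        ss.n[:, None, None] * np.log(2.0 * np.pi * var)[None, :, :]
        + ssr / var[None, :, :]
    )
    return ll.sum(axis=2)


def _min_cluster_mass(n_actions: int, K: int) -> float:
    """Smallest admissible effective action count per cluster.

    A cubic spline mean with a per-dimension variance is not identifiable
    from a single curve; clusters carried by fewer than a handful of
    actions let the variance collapse and the likelihood diverge (the
    classic mixture singularity).  Restarts ending in such a state are
    rejected rather than compared by BIC.
    """
    return max(2.0, min(8.0, n_actions / (4.0 * K)))


def _penalty(coef: np.ndarray, var: np.ndarray) -> float:
    """Ridge penalty term of the MAP objective."""
    return float(RIDGE * np.sum(coef**2 / (2.0 * var[:, :, None])))


def _em_once(
    ss: _Suffstats,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    tied_variance: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    N = ss.n.shape[0]
    resp = rng.dirichlet(np.ones(K), size=N)
    coef, var, weights = _m_step(resp, ss, tied_variance)
    prev_ll = -np.inf
    for _ in range(max_iter):
        ll_ik = _action_logliks(coef, var, ss) + np.log(
            np.maximum(weights, 1e-300)
        )
        norm = logsumexp(ll_ik, axis=1)
        raw_ll = float(norm.sum())
        total = raw_ll - _penalty(coef, var)
        # MAP-EM guarantees a monotone penalized objective
        if total < prev_ll - 1e-7 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM objective decreased: {prev_ll} -> {total}"
            )
        resp = np.exp(ll_ik - norm[:, None])
        # re-seed clusters whose responsibility mass vanished
        mass = resp.sum(axis=0)
        dead = mass < 1e-8
        if dead.any():
            logger.warning("re-seeding %d degenerate cluster(s)", int(dead.sum()))
            for k in np.nonzero(dead)[0]:
                pick = rng.integers(0, N, size=max(2, N // K))
                resp[pick] *= 0.5
                resp[pick, k] += 0.5
            resp /= resp.sum(axis=1, keepdims=True)
        coef, var, weights = _m_step(resp, ss, tied_variance)
        if total - prev_ll < tol and not dead.any():
            prev_ll = total
            break
        # a re-seed perturbs the solution, so the monotone run restarts
        prev_ll = -np.inf if dead.any() else total
    # reject solutions with under-supported clusters (variance collapse)
    if resp.sum(axis=0).min() < _min_cluster_mass(N, K):
        return coef, var, weights, -np.inf
    # report the raw log-likelihood of the final parameters (the loop's
    # value is one refit stale); the ridge served only as a prior
    ll_ik = _action_logliks(coef, var, ss) + np.log(np.maximum(weights, 1e-300))
    raw_ll = float(logsumexp(ll_ik, axis=1).sum())
    return coef, var, weights, raw_ll


def fit_spline_mixture(
    actions: Sequence[AlignedAction],
    K: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    knots: np.ndarray | None = None,
    tied_variance: bool = True,
) -> SplineMixtureModel:
    """Fit a K-component spline mixture by best-of-restarts EM.

    Each restart draws random responsibilities (Dirichlet(1) per action) as
    its "random boundary condition" and runs EM to convergence; the restart
    with the highest log-likelihood wins.  Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(actions) < K:
        raise ValueError(f"need at least K={K} actions, got {len(actions)}")
    if knots is None:
        knots = _make_knots(actions)
    ss = _suffstats(actions, knots)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        coef, var, weights, ll = _em_once(ss, K, rng, max_iter, tol, tied_variance)
        if best is None or ll > best[3]:
            best = (coef, var, weights, ll)
    coef, var, weights, ll = best
    if not np.isfinite(ll):
        logger.warning(
            "no restart produced K=%d clusters each supported by enough "
            "actions; model marked non-viable (loglik = -inf)",
            K,
        )
    return SplineMixtureModel(
        K=K,
        knots=knots,
        coefficients=coef,
        noise_var=var,
        weights=weights,
        loglik=ll,
        n_obs=int(ss.n.sum()) * ss.XtY.shape[2],
        n_actions=len(actions),
        seed=seed,
        tied_variance=tied_variance,
    )


def bic(model: SplineMixtureModel) -> float:
    """Bayesian information criterion k·ln(n) − 2·ln(L̂); lower is better."""
    return model.bic


def select_k(
    actions: Sequence[AlignedAction],
    k_range: Iterable[int],
    seed: int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    **fit_kwargs,
) -> tuple[SplineMixtureModel, float, dict[int, float]]:
    """Fit every K in ``k_range`` and pick the BIC minimizer.

    Returns ``(best_model, delta_bic_min, bics)`` where ``delta_bic_min`` is
    the BIC gap to the closest competitor (+inf for a single-K range).
    Values above ``DELTA_BIC_STRONG_EVIDENCE`` count as strong evidence for
    the selected order.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    knots = _make_knots(actions)
    models = {}
    root = np.random.default_rng(seed)
    for k in ks:
        sub_seed = int(root.integers(0, 2**31 - 1))
        models[k] = fit_spline_mixture(
            actions, k, n_restarts=n_restarts, seed=sub_seed, knots=knots, **fit_kwargs
        )
    bics = {k: m.bic for k, m in models.items()}
    best_k = min(bics, key=bics.get)
    others = [v for k, v in bics.items() if k != best_k]
    delta = float(min(others) - bics[best_k]) if others else float("inf")
    return models[best_k], delta, bics


def posterior(model: SplineMixtureModel, action: AlignedAction) -> MembershipPosterior:
    """Bayes responsibilities of one action; entropy in bits, never NaN."""
    ss = _suffstats([action], model.knots)
    ll = _action_logliks(model.coefficients, model.noise_var, ss)[0]
    logp = ll + np.log(np.maximum(model.weights, 1e-300))
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    nz = probs > 0
    entropy = float(-(probs[nz] * np.log2(probs[nz])).sum())
    return MembershipPosterior(probs, entropy, int(np.argmax(probs)))


def annotate(
    ects: ECTS,
    model: SplineMixtureModel,
    segments: Sequence[ActionSegment],
    canonicalize: bool = True,
) -> tuple[np.ndarray, list[MembershipPosterior], pd.DataFrame]:
    """Per-frame ethogram from a fitted model.

    Every frame inside a segment carries the segment's hard cluster label
    and entropy; frames outside any segment (masked gaps, boundary slivers)
    are labelled −1 ("unknown").  Returns (labels, posteriors, table).
    """
    aligned = align_actions(segments)
    if canonicalize:
        aligned = canonicalize_side(aligned)
    posts = [posterior(model, a) for a in aligned]
    labels = np.full(ects.n_frames, -1, dtype=int)
    action_id = np.full(ects.n_frames, -1, dtype=int)
    entropy = np.full(ects.n_frames, np.nan)
    for i, (seg, post) in enumerate(zip(segments, posts)):
        labels[seg.start : seg.end] = post.hard_label
        action_id[seg.start : seg.end] = i
        entropy[seg.start : seg.end] = post.entropy
    table = pd.DataFrame(
        {
            "frame": np.arange(ects.n_frames),
            "label": labels,
            "action_id": action_id,
            "entropy": entropy,
        }
    )
    return labels, posts, table


def low_uncertainty_fraction(
    posteriors: Sequence[MembershipPosterior], K: int, h_frac: float = 0.25
) -> float:
    """Fraction of actions with entropy below h_frac · log2(K)."""
    if not posteriors:
        return 0.0
    h_max = np.log2(K) if K > 1 else 1.0
    return float(np.mean([p.entropy < h_frac * h_max for p in posteriors]))
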
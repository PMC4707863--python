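"""Markov-chain agent: synthetic ground truth with genuinely discrete states.

The agent is a minimal statistical stand-in for a behaving larva whose
behaviour really is a set of discrete states: a bout-level Markov chain over
*straight run*, *run cast* and *stop cast*.  During a cast bout the first
coefficient traces a smooth bend pulse of fixed, state-specific time scale
whose peak magnitude is drawn from the state's amplitude distribution — run
casts (weathervaning) bend moderately, stop casts (head sweeps) strongly.
Straight runs barely bend the midline (peristalsis is invisible to the
eigenshape description), so they appear as near-flat stretches that the
low-activity detector recovers as the passive motif.  The second and third
coefficients carry scaled pulse copies of different widths so the posture
data genuinely span three eigenshape modes; a bend to the left and its
mirror to the right negate every coefficient, as body symmetry demands.

Emission follows a window-observation model: each motif is one fixed
underlying curve, and a bout of a given duration observes that curve over
its own time window — exactly the assumption of the spline-mixture
likelihood (actions contribute only over their own support).  On agent data
BIC therefore discovers K = 3 motifs, the pooled cast-amplitude histogram
is bimodal, and density cross sections show two bands per half-axis.  An
"animal-like" configuration with overlapping amplitude distributions erases
those signatures, mirroring what real larva and worm data look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eigenshape import ECTS
from .clustering import AlignedAction
from .posture import N_ANGLES

STATES = ("straight_run", "run_cast", "stop_cast")
STRAIGHT_RUN, RUN_CAST, STOP_CAST = 0, 1, 2

# relative scale of the second and third coefficient pulses, and their
# widths relative to the first coefficient's pulse
_DIM2_SCALE = 0.35
_DIM3_SCALE = 0.2
_DIM2_WIDTH = 1.4
_DIM3_WIDTH = 0.8
# one-frame marker added on the pulse apex so the body-score argmax
# recovers the pulse centre deterministically under observation noise
_APEX_MARKER = 0.3

__all__ = [
    "STATES",
    "AgentConfig",
    "AgentRecording",
    "default_config",
    "animal_like_config",
    "simulate",
    "synthetic_modes",
    "agent_angle_matrix",
    "make_spline_cluster_curves",
    "write_truth_labels",
]


@dataclass
class AgentConfig:
    """Parameters of the three-state agent.

    ``transition_matrix`` is the bout-level chain (row-stochastic; the
    diagonal is normally zero — a new bout means a new state).
    ``dwell_frames`` gives each state's mean bout length; actual lengths
    are drawn uniformly within ``dwell_spread`` of the pulse support (cast
    bouts never truncate a pulse mid-bend, long bouts pad it with flat
    tails).  ``bend_amp_mean``/``sd`` give the per-state distribution of
    peak first-coefficient magnitude, ordered straight run < run cast <
    stop cast — the amplitude ordering is what makes states separable.
    ``side_bias`` is the probability of a leftward (positive) bend;
    ``noise_sd`` is iid per-frame coefficient noise.
    """

    transition_matrix: np.ndarray  # (3, 3)
    bend_amp_mean: np.ndarray  # (3,)
    bend_amp_sd: np.ndarray  # (3,)
    dwell_frames: np.ndarray = field(
        default_factory=lambda: np.array([30.0, 17.0, 24.0])
    )
    pulse_halfwidth: np.ndarray = field(
        default_factory=lambda: np.array([15.0, 7.0, 10.0])
    )
    dwell_spread: float = 0.2  # half-range of the relative dwell variation
    side_bias: float = 0.5
    noise_sd: float = 0.05
    frame_rate: float = 30.0
    seed: int = 0
    enforce_amp_order: bool = True

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.bend_amp_mean = np.asarray(self.bend_amp_mean, float)
        self.bend_amp_sd = np.asarray(self.bend_amp_sd, float)
        self.dwell_frames = np.asarray(self.dwell_frames, float)
        self.pulse_halfwidth = np.asarray(self.pulse_halfwidth, float)
        P = self.transition_matrix
        if P.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be stochastic")
        if self.bend_amp_mean.shape != (3,) or self.bend_amp_sd.shape != (3,):
            raise ValueError("per-state amplitude mean/sd needed for 3 states")
        if np.any(self.bend_amp_sd <= 0):
            raise ValueError("amplitude sds must be positive")
        if self.enforce_amp_order and not (
            self.bend_amp_mean[STRAIGHT_RUN]
            < self.bend_amp_mean[RUN_CAST]
            < self.bend_amp_mean[STOP_CAST]
        ):
            raise ValueError(
                "amplitude means must be ordered straight run < run cast < stop cast"
            )
        if self.pulse_halfwidth.shape != (3,) or np.any(self.pulse_halfwidth <= 0):
            raise ValueError("pulse_halfwidth needs 3 positive entries")
        if self.dwell_frames.shape != (3,) or np.any(self.dwell_frames < 2):
            raise ValueError("dwell_frames needs 3 entries of at least 2 frames")
        if not 0.0 <= self.side_bias <= 1.0:
            raise ValueError("side_bias must be a probability")
        if self.noise_sd < 0 or self.frame_rate <= 0:
            raise ValueError("noise_sd must be >= 0 and frame_rate > 0")

    @property
    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the bout-level chain."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.abs(np.real(vecs[:, i]))
        return pi / pi.sum()

    @property
    def expected_occupancy(self) -> np.ndarray:
        """Expected per-frame state occupancy: bout frequency × mean dwell."""
        occ = self.stationary_distribution * self.dwell_frames
        return occ / occ.sum()


@dataclass
class AgentRecording:
    """Simulated ECTS with per-frame ground-truth state labels."""

    ects: ECTS
    state_labels: np.ndarray  # (T,) ints into STATES
    config: AgentConfig
    midline_angles: np.ndarray | None = None  # (T, 70) reconstructed angles

    @property
    def n_frames(self) -> int:
        return self.ects.n_frames


_DEFAULT_TRANSITIONS = np.array(
    [
        [0.0, 0.7, 0.3],  # straight run -> mostly run casts
        [1.0, 0.0, 0.0],  # casts always resume a straight run
        [1.0, 0.0, 0.0],
    ]
)


def default_config(seed: int = 0) -> AgentConfig:
    """The discrete-state study configuration.

    Cast pulses last ≈ 0.5–0.7 s at 30 fps with peak bend amplitudes
    1.2 / 2.6 and small spread, so the two cast states are cleanly
    separable by amplitude and the pooled cast-amplitude distribution is
    bimodal; straight runs are flat (bend ≈ 0).
    """
    return AgentConfig(
        transition_matrix=_DEFAULT_TRANSITIONS.copy(),
        bend_amp_mean=np.array([0.0, 1.2, 2.6]),
        bend_amp_sd=np.array([0.01, 0.015, 0.02]),
        seed=seed,
    )


def animal_like_config(seed: int = 0) -> AgentConfig:
    """Cast amplitude distributions overlapping into a continuum.

    Emulates the real animals, where bend amplitudes show no gap between
    behavioural states: density cross sections then show a single band per
    half-axis and the cast-amplitude histogram is unimodal.
    """
    return AgentConfig(
        transition_matrix=_DEFAULT_TRANSITIONS.copy(),
        bend_amp_mean=np.array([0.0, 1.3, 1.9]),
        bend_amp_sd=np.array([0.01, 0.45, 0.5]),
        seed=seed,
    )


def _bump(tau: np.ndarray, halfwidth: float) -> np.ndarray:
    """Smooth rise–peak–fall pulse, zero outside ±halfwidth frames."""
    inside = np.abs(tau) < halfwidth
    return np.where(inside, np.cos(np.pi * tau / (2.0 * halfwidth)) ** 2, 0.0)


def _bout_pulses(
    length: int, halfwidth: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-time-scale pulse shapes observed over one bout's window.

    The pulse is centred on an integer frame of the bout; a short bout
    observes a truncated window of the same underlying curve, a long bout
    pads it with flat tails.  The first dimension carries a one-frame apex
    marker making the most-bent frame unambiguous.
    """
    tau = np.arange(length) - (length - 1) // 2
    p1 = _bump(tau, halfwidth)
    p2 = _bump(tau, _DIM2_WIDTH * halfwidth)
    p3 = _bump(tau, _DIM3_WIDTH * halfwidth)
    return p1 + (_APEX_MARKER * (tau == 0)), p2, p3


def simulate(
    config: AgentConfig, n_frames: int, include_midlines: bool = False
) -> AgentRecording:
    """Run the agent for ``n_frames``; reproducible bit-for-bit per seed.

    Bout lengths: cast bouts draw uniformly from [1, 1 + 2·spread] times
    the pulse support (a pulse always completes; long bouts idle briefly
    after it), straight-run bouts from [1 − spread, 1 + spread] times the
    state's mean dwell.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(config.seed)
    cum = np.cumsum(config.transition_matrix, axis=1)
    states = np.empty(n_frames, dtype=int)
    alpha = np.zeros((n_frames, 3))
    s = int(np.argmax(rng.random() < np.cumsum(config.stationary_distribution)))
    t = 0
    while t < n_frames:
        if s == STRAIGHT_RUN:
            base = config.dwell_frames[s]
            L = int(round(base * rng.uniform(1.0 - config.dwell_spread,
                                             1.0 + config.dwell_spread)))
        else:
            support = 2.0 * config.pulse_halfwidth[s]
            L = int(round(support * rng.uniform(1.0, 1.0 + 2.0 * config.dwell_spread)))
        L = min(max(2, L), n_frames - t)
        states[t : t + L] = s
        amp = abs(rng.normal(config.bend_amp_mean[s], config.bend_amp_sd[s]))
        sign = 1.0 if rng.random() < config.side_bias else -1.0
        if s != STRAIGHT_RUN:
            p1, p2, p3 = _bout_pulses(L, config.pulse_halfwidth[s])
            alpha[t : t + L, 0] = sign * amp * p1
            alpha[t : t + L, 1] = sign * amp * _DIM2_SCALE * p2
            alpha[t : t + L, 2] = sign * amp * _DIM3_SCALE * p3
        t += L
        s = int(np.argmax(rng.random() < cum[s]))
    alpha += rng.normal(0.0, config.noise_sd, size=alpha.shape)
    var = alpha.var(axis=0)
    weights = var / var.sum()
    ects = ECTS(alpha, config.frame_rate, np.zeros(n_frames, bool), weights)
    angles = agent_angle_matrix(alpha) if include_midlines else None
    return AgentRecording(ects, states, config, angles)


def synthetic_modes(n_modes: int = 3) -> np.ndarray:
    """Fixed orthonormal 70-vector posture modes for reconstruction.

    Smooth half-cosine harmonics along the body, orthonormalized, standing
    in for empirical eigenshapes when rendering agent postures.
    """
    s = (np.arange(N_ANGLES) + 0.5) / N_ANGLES
    raw = np.stack([np.cos((i + 1) * np.pi * s) for i in range(n_modes)])
    q, _ = np.linalg.qr(raw.T)
    modes = q.T
    flip = modes[np.arange(n_modes), np.argmax(np.abs(modes), axis=1)] < 0
    modes[flip] *= -1.0
    return modes


def agent_angle_matrix(alpha: np.ndarray) -> np.ndarray:
    """Reconstruct (T, 70) midline angle vectors through the fixed modes."""
    alpha = np.asarray(alpha, float)
    return alpha @ synthetic_modes(alpha.shape[1])


# ---------------------------------------------------------------------------
# Direct generator for clustering unit tests


def make_spline_cluster_curves(
    K: int,
    n_per_cluster: int,
    separation: float,
    noise_sd: float,
    seed: int | None = None,
    length_range: tuple[int, int] = (15, 29),
) -> tuple[list[AlignedAction], np.ndarray]:
    """Sample labelled curves around K known smooth mean curves.

    Cluster k's underlying pulse has peak amplitude ``base + k·separation``
    (zero separation collapses all means onto one curve); each curve
    observes that fixed pulse over a random-duration window centred on the
    peak, plus iid Gaussian noise.  Returns (actions, labels).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    base = 1.0
    halfwidth = 10.0
    actions, labels = [], []
    for k in range(K):
        amp = base + k * separation
        for _ in range(n_per_cluster):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            tau = np.arange(L) - (L - 1) // 2
            mean = np.column_stack(
                [
                    amp * _bump(tau, halfwidth),
                    amp * _DIM2_SCALE * _bump(tau, _DIM2_WIDTH * halfwidth),
                    amp * _DIM3_SCALE * _bump(tau, _DIM3_WIDTH * halfwidth),
                ]
            )
            values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
            actions.append(AlignedAction(tau, values))
            labels.append(k)
    return actions, np.asarray(labels)


# ---------------------------------------------------------------------------
# I/O


def write_truth_labels(path: str | Path, rec: AgentRecording) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(rec.n_frames),
            "state": rec.state_labels,
            "state_name": [STATES[s] for s in rec.state_labels],
        }
    ).to_csv(path, index=False)
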
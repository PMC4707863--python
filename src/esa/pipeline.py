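"""End-to-end orchestration: configuration, logging, staged runs, resume.

A run goes extract → eigen → segment → cluster → annotate, writing one
artifact per stage under an output directory plus a manifest recording every
parameter and seed.  Deleting a downstream artifact and re-running resumes
from the surviving intermediates and reproduces the deleted files
byte-identically, since all randomness funnels through one root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, eigenshape, segmentation
from .clustering import SplineMixtureModel
from .eigenshape import ECTS, smooth_ects

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "segment_and_cluster", "state_agreement"]


@dataclass
class PipelineConfig:
    """All pipeline knobs with their standard defaults.

    Defaults follow the published analysis conditions: 0.5 s interpolation
    gap, 4-frame smoothing window, 3 ECTS dimensions, 3 internal spline
    knots, 500 EM restarts, 50% event overlap, 3-frame flicker gap, the
    0.5 / 0.5 s low-activity rule and a 5000-action DTW sample.
    """

    frame_rate: float = 30.0
    n_dims: int = 3
    smooth_window: int = 4
    max_gap_s: float = 0.5
    master: float = 0.1
    low_frac: float = 0.5
    low_min_dur_s: float = 0.5
    detect_low: bool = True
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    n_restarts: int = 500
    seed: int = 0
    canonicalize_side: bool = True
    flicker_max_gap: int = 3
    min_overlap: float = 0.5
    dtw_sample: int = 5000
    mds_restarts: int = 500
    label_map_path: str | None = None
    exclusion_mask_path: str | None = None

    @classmethod
    def from_json(cls, path: str | Path | None = None) -> "PipelineConfig":
        """Load config from JSON; ``ESA_<FIELD>`` env vars override."""
        doc = {}
        if path is not None:
            doc = json.loads(Path(path).read_text())
        cfg = cls(**{k: v for k, v in doc.items() if k in cls.__dataclass_fields__})
        for name, f in cls.__dataclass_fields__.items():
            env = os.environ.get(f"ESA_{name.upper()}")
            if env is not None:
                cur = getattr(cfg, name)
                if isinstance(cur, bool):
                    setattr(cfg, name, env.lower() in {"1", "true", "yes"})
                elif isinstance(cur, int):
                    setattr(cfg, name, int(env))
                elif isinstance(cur, float):
                    setattr(cfg, name, float(env))
                elif isinstance(cur, tuple):
                    setattr(cfg, name, tuple(int(x) for x in env.split(",")))
                else:
                    setattr(cfg, name, env)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg


def segment_and_cluster(
    ects: ECTS,
    config: PipelineConfig,
    k_range: tuple[int, ...] | None = None,
    n_restarts: int | None = None,
) -> dict:
    """Segment a coefficient series and fit the BIC-selected spline mixture.

    Segmentation runs on a smoothed copy of the series (stable extrema and
    derivative), while the stored action curves and the mixture likelihood
    use the raw coefficients — smoothing correlates the observation noise,
    which the mixture's iid likelihood would misread as cluster structure.

    Returns a dict with segments, aligned actions, the selected model,
    ΔBIC_min, all BIC values, per-frame labels, posteriors and the
    annotation table.
    """
    sm = smooth_ects(ects.alpha, ects.missing_mask, config.smooth_window)
    ects_sm = ECTS(sm, ects.frame_rate, ects.missing_mask, ects.eigenvalue_weights)
    segments = segmentation.segment_recording(
        ects_sm,
        config.master,
        config.low_frac,
        config.low_min_dur_s,
        config.detect_low,
        curve_ects=ects,
    )
    aligned = clustering.align_actions(segments)
    if config.canonicalize_side:
        aligned = clustering.canonicalize_side(aligned)
    model, delta_bic, bics = clustering.select_k(
        aligned,
        k_range if k_range is not None else config.k_range,
        seed=config.seed,
        n_restarts=n_restarts if n_restarts is not None else config.n_restarts,
    )
    labels, posts, table = clustering.annotate(
        ects, model, segments, config.canonicalize_side
    )
    return {
        "segments": segments,
        "aligned": aligned,
        "model": model,
        "delta_bic_min": delta_bic,
        "bics": bics,
        "labels": labels,
        "posteriors": posts,
        "annotation": table,
    }


def state_agreement(
    labels: np.ndarray, true_states: np.ndarray, n_states: int | None = None
) -> tuple[float, dict[int, int]]:
    """Frame-level agreement after the optimal cluster→state permutation.

    Unlabelled frames (label < 0) are excluded.  Returns the agreement
    fraction and the cluster→state mapping used.
    """
    from scipy.optimize import linear_sum_assignment

    labels = np.asarray(labels)
    true_states = np.asarray(true_states)
    mask = labels >= 0
    if not mask.any():
        return 0.0, {}
    k = int(labels[mask].max()) + 1
    s = n_states if n_states is not None else int(true_states.max()) + 1
    dim = max(k, s)
    C = np.zeros((dim, dim))
    for l, t in zip(labels[mask], true_states[mask]):
        C[l, t] += 1
    rows, cols = linear_sum_assignment(-C)
    mapping = {int(r): int(c) for r, c in zip(rows, cols) if r < k}
    return float(C[rows, cols].sum() / mask.sum()), mapping


def _write_ects_meta(path: Path, ects: ECTS) -> None:
    path.write_text(
        json.dumps(
            {
                "frame_rate": ects.frame_rate,
                "eigenvalue_weights": ects.eigenvalue_weights.tolist(),
            }
        )
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, outputs: list[Path]):
    """Decorator-free stage helper: returns True if all outputs exist."""
    done = all(p.exists() for p in outputs)
    if done:
        logger.info("stage %s: resuming from existing artifacts", name)
    return done


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    angles: np.ndarray | None = None,
    missing: np.ndarray | None = None,
    ects: ECTS | None = None,
) -> dict:
    """Execute the pipeline from an angle matrix (or a ready ECTS).

    Returns a dict with the fitted model, segments, annotation table and
    artifact paths.  Raises with the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    paths = {
        "ects": outdir / "ects.csv",
        "ects_meta": outdir / "ects_meta.json",
        "segments": outdir / "segments.csv",
        "model": outdir / "model.json",
        "annotation": outdir / "annotation.csv",
        "manifest": outdir / "manifest.json",
    }

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    # --- eigen: angle matrix -> ECTS -------------------------------------
    stage = "eigen"
    try:
        if ects is None:
            if _stage(stage, [paths["ects"], paths["ects_meta"]]):
                meta = json.loads(paths["ects_meta"].read_text())
                ects = eigenshape.read_ects_csv(
                    paths["ects"], meta["frame_rate"], meta["eigenvalue_weights"]
                )
            else:
                if angles is None:
                    raise ValueError("need an angle matrix or an ECTS")
                t0 = time.perf_counter()
                if missing is None:
                    missing = np.any(np.isnan(angles), axis=1)
                basis = eigenshape.fit_eigenshapes(angles, missing)
                # the stored series stays unsmoothed; segmentation smooths
                # its own working copy (see segment_and_cluster)
                ects = eigenshape.build_ects(
                    angles,
                    missing,
                    basis,
                    config.frame_rate,
                    config.n_dims,
                    config.max_gap_s,
                    smooth_window=0,
                )
                eigenshape.write_ects_csv(paths["ects"], ects)
                _write_ects_meta(paths["ects_meta"], ects)
                record(stage, t0, [paths["ects"], paths["ects_meta"]])
        elif not paths["ects"].exists():
            t0 = time.perf_counter()
            eigenshape.write_ects_csv(paths["ects"], ects)
            _write_ects_meta(paths["ects_meta"], ects)
            record(stage, t0, [paths["ects"], paths["ects_meta"]])
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    # --- segment ----------------------------------------------------------
    stage = "segment"
    try:
        if _stage(stage, [paths["segments"]]):
            segments = segmentation.read_segment_csv(paths["segments"], ects)
        else:
            t0 = time.perf_counter()
            sm = smooth_ects(ects.alpha, ects.missing_mask, config.smooth_window)
            ects_sm = ECTS(
                sm, ects.frame_rate, ects.missing_mask, ects.eigenvalue_weights
            )
            segments = segmentation.segment_recording(
                ects_sm,
                config.master,
                config.low_frac,
                config.low_min_dur_s,
                config.detect_low,
                curve_ects=ects,
            )
            segmentation.write_segment_csv(paths["segments"], segments)
            record(stage, t0, [paths["segments"]])
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    # --- cluster ----------------------------------------------------------
    stage = "cluster"
    try:
        aligned = clustering.align_actions(segments)
        if config.canonicalize_side:
            aligned = clustering.canonicalize_side(aligned)
        if _stage(stage, [paths["model"]]):
            model = SplineMixtureModel.from_json(paths["model"])
            delta_bic = None
        else:
            t0 = time.perf_counter()
            model, delta_bic, _ = clustering.select_k(
                aligned,
                config.k_range,
                seed=config.seed,
                n_restarts=config.n_restarts,
            )
            model.to_json(paths["model"])
            record(stage, t0, [paths["model"]])
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    # --- annotate ---------------------------------------------------------
    stage = "annotate"
    try:
        if _stage(stage, [paths["annotation"]]):
            table = pd.read_csv(paths["annotation"])
            labels = table["label"].to_numpy(int)
            posts = None
        else:
            t0 = time.perf_counter()
            labels, posts, table = clustering.annotate(
                ects, model, segments, config.canonicalize_side
            )
            table.to_csv(paths["annotation"], index=False, float_format="%.17g")
            record(stage, t0, [paths["annotation"]])
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    manifest["seed"] = config.seed
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return {
        "ects": ects,
        "segments": segments,
        "model": model,
        "labels": labels,
        "posteriors": posts,
        "annotation": table,
        "delta_bic_min": delta_bic,
        "paths": paths,
    }
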
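# eigenshape-annotator

Unsupervised discovery and probabilistic annotation of behavioural motifs in
the posture time series of crawling animals (larval *Drosophila*,
*C. elegans*), for behavioural neuroscientists and ethologists who want
data-defined behavioural states instead of hand-tuned thresholds or training
examples.

## The method

A binary video frame is skeletonized to a **midline**, resampled to 71
equidistant points, rotated so the head–tail axis lies on the x-axis, and
encoded as 70 segment angles θ_i ∈ (−π, π].  PCA of the frames × 70 angle
matrix gives the **eigenshapes** (eigenworms / eigenmaggots); any posture is

    θ(t) ≈ θ̄ + Σ_i α_i(t) · eigenshape_i

and the three leading coefficients α₁..α₃ — which capture ≈ 90% of postural
variance — form the **eigenshape coefficient time series (ECTS)**.  Short
tracking gaps (< 0.5 s) are linearly interpolated; a 4-frame
inverse-distance-weighted running average stabilizes the series for
segmentation.

The ECTS is cut into variable-length **actions** at the extrema of a *body
score* s(t) = Σ_i w_i·|α_i(t)| (weights ∝ eigenvalues): an action is a local
score maximum bounded by its neighbouring minima, so the peak marks the most
bent posture.  Low-activity intervals (|ds/dt| below half its mean for more
than 0.5 s) are added as *passive* actions.

Actions are aligned at their peak frame and clustered with a
**spline-regression mixture model**: each of K motifs is a cubic spline mean
curve (3 internal knots) per ECTS dimension with Gaussian noise, and an
action's likelihood is evaluated only over its own observed support, so
actions of unequal duration can share a motif.  Parameters are learned by EM
from many random restarts; the motif count minimizes

    BIC = k·ln(n) − 2·ln(L̂)

(k free parameters, n scalar observations).  Each action gets a posterior
membership p₁..p_K whose Shannon entropy H = −Σ p_i log₂ p_i quantifies
classification uncertainty (H_max = log₂ K).

Annotations are benchmarked against ground-truth ethograms with event-level
precision P, sensitivity S and F = 2PS/(P+S), using a 50%-overlap matching
rule, flicker repair (events < 3 frames apart are joined) and many-to-one
label maps.  Discreteness diagnostics — weighted-DTW distance maps embedded
by metric MDS, kernel-density cross sections of the aggregated aligned
curves, and per-action feature-extremum histograms — test whether the
discovered motifs are separable states or a continuum.

A built-in three-state Markov agent (straight run / run cast / stop cast,
with state-dependent bend amplitudes) provides synthetic recordings with
known ground truth, so the whole pipeline is testable without any data
download.

## Worked example

```bash
esa simulate --frames 3000 --seed 5 --out rec.csv
esa segment  --ects rec.csv --out seg.csv
esa cluster  --segments seg.csv --ects rec.csv --k-range 2:4 --restarts 8 --seed 3 --out model.json
esa annotate --model model.json --segments seg.csv --ects rec.csv --out ann.csv
esa analyze  --segments seg.csv --ects rec.csv --sample 40 --restarts 4 --seed 2 --outdir diag
```

prints

```
simulated 3000 frames, states ('straight_run', 'run_cast', 'stop_cast')
124 actions
selected K=3 (dBIC_min=174.75); BIC: K=2: -11783.2, K=3: -23434.7, K=4: -23260.0
annotated 3000 frames
MDS R2=0.979; peak-slice modes=1
```

Read: segmentation found 124 candidate actions in 100 s of simulated
behaviour; BIC decisively selects three motifs (the BIC of K=3 beats both
neighbours, with a gap of ≈ 175 to the runner-up — far beyond the
strong-evidence bound of 3.75), matching the agent's three generating
states; `ann.csv` holds the per-frame ethogram with action ids and
classification entropies; and the MDS map of pairwise DTW distances embeds
with R² ≈ 0.98.  The same calls work on real data: start from `esa extract`
(binary frames or midline CSV/WCON → angle matrix) and `esa eigen` (angle
matrix → ECTS), or read a pre-computed coefficient table with
`esa.eigenshape.read_ects_table`.

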
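# Methods

This note records the models implemented in `eigenshape-annotator`, the
assumptions behind them, the defaults that matter, and the design decisions
taken where the problem was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Posture representation

A frame's posture is its midline: the longest geodesic path through the
morphological skeleton of the thresholded animal.  We extract it by
medial-axis thinning followed by the tree-diameter path between skeleton
endpoints (two weighted breadth-first sweeps); taking the diameter path
makes a separate spur-pruning pass unnecessary, since short raster spurs are
never on the longest path.  Skeletons containing a cycle — the animal curled
on itself so that thresholding produces a "doughnut" — have no meaningful
head–tail path and yield a dropped-frame marker, distinct from the error
raised for an empty frame.  Head and tail are not identified; orientation is
only kept consistent from frame to frame (the assignment minimizing summed
endpoint displacement), which suffices because the PCA representation is
sign-symmetric.

Midlines are resampled to 71 points equidistant in arc length and rotated
so both endpoints lie on the x-axis, removing translation and overall
rotation.  Resampling is a contraction: repeated application converges
geometrically to a fixed polyline (the suite asserts the decreasing
residuals).  Body length is recorded but ignored downstream.

The angle vector has exactly 70 entries: θ_i is the orientation of segment
i relative to the endpoint axis, wrapped to (−π, π].  A straight animal is
the zero vector; mirror-imaging the animal negates every θ_i.  (A
turning-angle convention between consecutive segments would produce only 69
values from 71 points; the per-segment orientation convention is also the
standard one for eigenworm analyses.)

## Eigenshapes and the coefficient series

PCA is applied to the mean-centred frames × 70 angle matrix via SVD.  The
full 70-component basis is kept; eigenvalues are the variances along
components; each component's sign is fixed so that its largest-magnitude
entry is positive, making repeated fits bit-identical.  The
eigendecomposition of the covariance matrix serves as an independent oracle
in the tests (principal angles < 1e-6).

The ECTS keeps the three leading coefficients.  Interior gaps strictly
shorter than 0.5 s are linearly interpolated per column and unmasked;
longer gaps and gaps touching the series ends stay masked.  The smoothing
filter is a symmetric 5-tap running average with weights ∝ 1/(|offset|+½)
over offsets −2..+2 — our reading of a "window of four frames" with
inverse-distance weights: four neighbours around the centre, with the
centre's distance taken as ½ so the filter stays symmetric, positive and
constant-preserving.  At the edges of an unmasked run the window is
truncated and renormalized; it never mixes values across a masked gap.

**Where smoothing is applied.** Smoothing exists to stabilize the
segmentation (extrema and derivative of the body score) against
frame-to-frame posture-extraction noise, and that is the only place the
pipeline uses it: `segment_and_cluster` smooths a working copy of the
series, while the stored action curves — and therefore the mixture
likelihood — use the raw coefficients.  The reason is statistical, not
cosmetic: the running average correlates the observation noise, leaving the
low-frequency noise power several times larger than the per-point variance
a diagonal Gaussian likelihood fits.  A mixture model confronted with that
discrepancy absorbs between-action noise into extra cluster means, i.e.
smoothing before clustering systematically inflates the selected motif
count.

## Segmentation

The body score is s(t) = Σ_i w_i·|α_i(t)| with w the three leading
eigenvalues normalized to sum to one.  Absolute values are essential: the
score's maximum must mark the most bent posture, and a signed sum would let
opposite bends cancel.  The extrema finder retains maxima whose topographic
prominence is at least `master` (default 0.1) times the robust amplitude of
the score (its 5th–95th percentile range); the threshold is relative, so
segmentation is invariant to uniform rescaling of the ECTS, and ±25%
changes of `master` are a stability check rather than a tuning exercise.
Actions span bounding minima as half-open frame intervals; masked gaps
split them.  Segments that abut the series edge or a masked gap are dropped
by default: they lack a true bounding minimum, so their curve may be an
arbitrarily truncated observation.

Low-activity intervals are maximal runs where |ds/dt| (central difference)
stays below half its mean for more than 0.5 s; they are added to the action
collection before clustering (aligned at their midpoint rather than a
peak), and win ties against overlapping active segments.  For a perfectly
constant score the threshold degenerates to zero, so the criterion falls
back to |ds/dt| = 0 and the whole series is one low-activity interval.  The
derivative mean is per-recording.

## Spline-mixture clustering

Aligned actions are offset so the body-score peak sits at 0.  Each of K
clusters is a cubic B-spline mean curve per ECTS dimension with three
internal knots at the quartiles of the pooled offsets; boundary knots sit
at the 5th/95th percentile of the pooled offsets, with clipped (constant)
evaluation beyond — the outermost offsets are observed by only a handful of
actions, and a free cubic tail fitted there is unconstrained.  An action's
cluster likelihood is the product of Gaussian densities of its own
(offset, value) pairs around the spline; unequal durations therefore
contribute over unequal supports of the *same* underlying curve, which is
what lets one motif cover actions of different lengths.

**Noise model.** One variance per ECTS dimension, shared (tied) across
clusters, floored at 1e-8.  With per-cluster variances and dozens of
observations per action, the likelihood rewards splitting a genuine cluster
into "quieter" and "noisier" halves of its members' chance-realized noise
levels — an overfit worth far more than the BIC penalty.  Tying the
variances removes that channel and rests cluster identity on mean curves,
which is the motif concept; `tied_variance=False` restores the per-cluster
model.

**Penalized refits.** The weighted spline refit uses a coefficient ridge of
λ = 1.0, equivalent to a N(0, σ²/λ) prior: basis functions with essentially
no support under a cluster's responsibilities are shrunk to zero instead of
swinging freely, at a bias of under ~2% on well-supported coefficients.
The variance update adds the penalty to the weighted SSR, making the EM an
exact MAP-EM whose penalized objective is provably non-decreasing; that
monotonicity is asserted on every iteration.  The model's reported
log-likelihood is the raw (unpenalized) one, recomputed for the final
parameters.

**EM.** Each restart draws Dirichlet(1) responsibilities per action ("random
boundary conditions"), alternates responsibility and refit steps, and stops
when the objective gains less than 1e-6 or after 500 iterations; 500
restarts by default (tests and the acceptance script use ~10, which these
problem sizes saturate).  Clusters whose responsibility mass vanishes
mid-run are re-seeded and logged, and the monotonicity clock restarts.  A
converged restart in which any cluster is carried by fewer than
max(2, min(8, N/4K)) effective actions is rejected (log-likelihood −∞): a
spline mean plus variance is not identifiable from a curve or two, and such
solutions are the classic mixture variance-collapse singularity, not
evidence for more motifs.  Fits are bit-reproducible given a seed.

**Side canonicalization.** Bilateral symmetry means a bend to the left and
its mirror image to the right are the same motif, but a mixture with single
mean curves would split every motif into left/right pairs.  The clustering
pipeline therefore flips each aligned action so its first coefficient at
the peak is non-negative (negating all dimensions — the angle-space mirror)
before fitting.  The structure diagnostics (density cross sections, DTW
maps) use the signed curves, because left/right structure is part of what
they display.

**Model order.** BIC = k·ln(n) − 2·ln(L̂) with k = K·(7 spline coefficients)
×(3 dims) + 3 tied variances + (K−1) weights, and **n = the number of
scalar observations entering the likelihood** (frames × dimensions).  The
"number of observations" could also be read as the number of actions, but
that penalty (≈ 25·ln(200)) is smaller than the non-regular overfit gain an
extra cluster can always harvest from a few hundred multi-frame curves, so
it over-selects K even on data generated exactly from the model; the
observation-count penalty is the statistically standard choice and is
consistent with ΔBIC values of the order actually observed for true model
orders.  ΔBIC_min — the gap from the selected K to its closest competitor —
is reported with 3.75 as the weak/strong evidence boundary; a single-K
range reports +∞.

Posteriors are computed in log space (never NaN, even for absurd inputs);
entropy is in bits, maximal at log₂K for uniform membership.  The
annotation assigns every frame its action's hard label and entropy; frames
outside any segment are −1 ("unknown").

## Annotation benchmarking

Events are maximal constant-label frame runs; unknown frames break runs.
Flicker repair joins events separated by strictly fewer than 3 frames
(`0011011100 → 0011111100`), is idempotent and never removes a frame.
Label maps are many-to-one with adjacent same-label events merged, and an
unmapped label is an error rather than a silent pass-through.  A predicted
event is a true positive when at least 50% (inclusive) of its frames carry
the same mapped label in the truth's frame timeline — coverage may come
from several truth events; a truth event with less than 50% coverage in
the prediction is a false negative.  The construction is symmetric:
swapping the annotations swaps FP and FN exactly.  "All behaviours" scores
pool the counts before computing P, S and F; zero denominators yield 0
with a warning.  Display rounding is half-up to two decimals, matching how
such tables are normally printed.  Excluded (unsegmentable) intervals are
applied to both annotations before event extraction.

## Discreteness diagnostics

DTW uses the textbook symmetric step pattern (diagonal/horizontal/vertical
unit steps), no window, no length normalization, with the per-frame local
cost √(Σ_i w_i (a_i−b_i)²) weighted by the same normalized eigenvalues as
the body score.  It is verified against an explicit all-paths enumeration
for short series; the triangle inequality is deliberately not asserted (DTW
violates it).  Distance matrices are computed on a seeded uniform sample
without replacement (default cap 5000 actions).  Metric MDS runs SMACOF
from random starts (ε = 1e-12, up to 2000 iterations per start) and keeps
the solution with the highest R², defined as the squared Pearson
correlation between input and embedded distances — so R² is non-decreasing
in the number of restarts.

Density cross sections interpolate each covering curve at a fixed offset
and estimate the value density with a Gaussian KDE (Silverman bandwidth);
modes are KDE maxima with prominence ≥ 5% of the global maximum, counted
per half-axis where the left/right structure matters.  Feature-extremum
histograms collect a per-action max or mean and report the same KDE mode
count as unimodal / bimodal / multimodal (degenerate for a constant
feature).  Modality is descriptive; no formal dip test is performed.

## The agent simulator

The agent is the package's ground truth: behaviour that really is three
discrete states.  A bout-level Markov chain moves between *straight run*,
*run cast* and *stop cast* (default transitions: runs are followed by a
run cast 70% / stop cast 30% of the time; casts always resume a run).
During a cast bout the coefficients trace fixed-shape pulses of
state-specific half-width (7 frames ≈ 0.23 s for run casts, 10 for stop
casts at 30 fps) whose peak amplitude is drawn per bout — 1.2 ± 0.015 for
run casts, 2.6 ± 0.02 for stop casts — with a random bend side (all three
dimensions change sign together, as mirror symmetry requires).  Straight
runs do not bend at all: peristaltic crawling barely alters the midline, so
the eigenshape description of a run is flat and the low-activity detector
recovers runs as the passive motif.  All dimensions receive iid Gaussian
noise (σ = 0.05).

Two emission details keep the generator consistent with the clustering
model it is meant to probe.  First, durations follow a *window-observation*
rule: a motif is one fixed curve over time, and a bout observes it over a
bout-length window (cast bouts last 1.0–1.4× the pulse support, so a pulse
always completes and long bouts idle briefly; run bouts last 0.8–1.2× a
30-frame mean).  Compressing or stretching the pulse to the bout instead
would make curve shape depend on duration, which no finite mixture of
fixed mean curves can represent.  Second, the first coefficient carries a
one-frame apex marker (+0.3) at the pulse centre, so the body-score argmax
recovers the alignment reference deterministically under noise; without
it, ±1-frame alignment jitter puts amplitude-scale residuals on the steep
pulse flanks.  Amplitude spreads are kept at the scale of the observation
noise for the same reason.  The `animal_like_config` differs only in its
cast amplitude distributions (1.3 ± 0.45 and 1.9 ± 0.5), which overlap
into a continuum — the switchable contrast between separable and
continuous behaviour that the diagnostics are designed to expose.

What the generator deliberately does *not* emulate: sensory-driven
behaviour (no chemotaxis, no stimulus gradients), biomechanics, broad
(e.g. geometric) dwell-time distributions, tracking noise and dropped
frames, posture nuisances such as self-intersection, and within-state
shape variability beyond amplitude.  Consequently, passing tests show the
pipeline recovers discrete structure *when it exists and the model is
well-specified*; they do not show the defaults are optimal for any real
recording, where larger residual heterogeneity will inflate fitted
variances and soften posterior certainties.  Midline rendering uses three
fixed orthonormal half-cosine modes, so the agent's angle matrix is
exactly three-dimensional and the PCA variance check is structural rather
than empirical.

## Problem sizes and numerical conventions

Tests and the acceptance script simulate 3000–6000 frames (100–200 s at
30 fps, ≈ 120–250 actions), fit K ∈ {1..4} with ~10 EM restarts, and use
90–120 actions for the DTW/MDS diagnostics; these sizes saturate the
relevant behaviours of the estimators while keeping runs short.  Frame
indices are 0-based, intervals half-open, coordinates image-convention.
Angle wrapping maps to (−π, π] with the upper endpoint closed.  CSV
artifacts are written with `%.17g` and read with round-trip float parsing,
so a resumed pipeline stage reproduces its outputs byte-identically; all
randomness funnels through a single root seed.

## Known limitations

Self-intersecting postures are dropped, biasing analyses against tightly
curled behaviours.  Head/tail identity is never established, so motifs are
defined up to body orientation.  The 50%-overlap event matching judges
each event once and is insensitive to boundary placement within an event.
BIC order selection, even with the observation-count penalty, remains
sensitive to model misspecification: correlated noise or systematic
within-motif heterogeneity in real data will still bias K upward, which is
worth remembering when interpreting motif counts on animal recordings.
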
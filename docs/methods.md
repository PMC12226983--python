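# Methods

## Pipeline overview

A session enters as an ordered 1 Hz heart-rate series.  Preprocessing
(1) optionally trims to the session extent, (2) removes exclusion windows
(rifle zeroing) without re-zeroing the remaining timestamps, and
(3) converts each sample to `round(100·HR/HRmax)` with ties rounded away
from zero.  Each retained sample counts as exactly one second of dwell
time; recording gaps are never interpolated, so total dwell time equals
the count of retained seconds — an exact conservation law the tests check
for arbitrary inputs.

Zone accounting uses half-open intervals with inclusive lower bounds
(Z2 is exactly [73, 83) %HRmax); the catch-all zone below the first
training zone (Z0, < 54 by default) absorbs sub-aerobic time.  Sessions
are classified from the plan alone: low-intensity (LIT) when all planned
minutes sit in the first two training zones, high-intensity (HIT) when any
planned duration touches the third zone or higher.  A moderate-intensity
category is deliberately absent, matching the dichotomy used in practice
where zone-3 prescriptions are rare.  Performed data can never change a
session's class.

## Density estimation

The dwell profile maps each observed integer %HRmax value to its share of
session time; each (share, %HRmax) pair is one point under the 2D KDE.
Estimators are plain Gaussian product kernels with user-suppliable
weights; the vectorised grid evaluation is required (and tested) to agree
with a literal nested-loop sum to 1e-12 absolute, and independently with
scipy's Gaussian KDE at a matched bandwidth.

Numerical choices:

* **Bandwidths.**  Silverman's normal-reference rule `σ(4/(3n))^{1/5}` in
  1D and per-dimension Scott `σ_d n^{−1/6}` in 2D; both overridable per
  run.  Constant data raises a degenerate-data error instructing the
  caller to supply a fallback bandwidth rather than silently guessing.
* **Grid.**  256×256 uniform cells over the capped ranges by default —
  smooth enough for publication figures, cheap enough to recompute
  interactively.  The x-grid spans [0, max observed share]; the y-grid
  spans [max(0, min %HRmax − 2·h_y), max %HRmax], a data-driven floor that
  avoids empty plot area since only the maxima are capped.
* **Masking.**  Cells below `eps_rel = 10⁻³` of the peak density are
  masked and rendered white, an operational rule for "this combination did
  not occur" that is deterministic and monotone in `eps_rel`.
* **No boundary correction.**  The Gaussian kernel has unbounded support;
  densities therefore smear slightly past 0/100 %HRmax and past the axis
  caps before truncation.  This is a known artefact, accepted to keep the
  estimator the standard one.
* **Pooling.**  Group-level densities default to plain concatenation of
  dwell points with uniform weights — sessions contributing more distinct
  intensity values carry more weight, the documented bias of unweighted
  pooling.  `per_session` weighting (each session normalised to total
  weight 1) is available as a flag.  Uniform weighting is invariant under
  duplicating a session's profile, which the tests exploit.
* **Time weighting for mode analysis.**  In the uniform dwell-point cloud
  every observed %HRmax value has equal mass, so for a single session the
  y-density carries no information about where time accumulated (each
  value is one point); the thin ridge of transition values near x ≈ 0 then
  dominates the density profile.  Mode-recovery analyses therefore weight
  each dwell point by its dwell seconds (`DwellProfile.time_weights`),
  which makes the two dominant %HRmax modes of an interval session land on
  the work and recovery levels.  Visual heatmaps keep the unweighted
  convention.

## The simulator

The generator emulates the features that shape real biathlon HR traces:

* **First-order kinetics.**  HR follows the intensity target through
  `x[t] = x[t−1] + (1/τ)(target[t] − x[t−1])` at 1 Hz with τ = 30 s, the
  standard single-time-constant description of HR on/off kinetics.  The
  recurrence is evaluated with an IIR filter and cross-checked against a
  step-by-step loop.
* **Targets.**  Baseline %HRmax plus a terrain sinusoid (default ±4 %HRmax,
  5 min period), cardiovascular drift (default 2 %HRmax/h), sequential
  work/recovery interval blocks for HIT, and shooting bouts (including an
  initial zeroing block, default 2 min, that the generated plan marks for
  exclusion).  Carrying the rifle adds +3 %HRmax to locomotion targets but
  not to stationary shooting bouts.  Canonical defaults place targets at
  zone midpoints: LIT at 64 %HRmax (middle of Z1), HIT work at 90 (middle
  of Z4) with recovery at 62.
* **Noise.**  Observed HR is the noise-free trajectory plus white Gaussian
  measurement noise of sd `noise_sd_pct` (default 2 %HRmax).  The noise is
  deliberately *outside* the recurrence: injecting innovations inside a
  first-order loop integrates them into a random walk whose stationary sd
  is `noise_sd·√(τ/2)` (≈ 7.7 %HRmax at the defaults), which no longer
  means what a user sets.  As additive observation noise the parameter is
  the actual spread of observations about the dynamic response.
* **Ground truth.**  Zone shares are computed from the noise-free
  trajectory pushed through the same exclusion and rounding steps as the
  analysis, so noise-free simulations are recovered *exactly*; cluster
  centres are the steady-state work/recovery levels.

What the simulator does not model: ectopic beats and sensor dropouts,
autonomic drift of HRmax across weeks, GPS/terrain co-simulation, or any
external-load (speed/power) channel.  Passing tests therefore demonstrate
correctness of the accounting and estimation machinery on physiologically
shaped inputs, not device-level robustness.

## Noise and zone-boundary bias

With white measurement noise of sd σ, a second whose true intensity lies
at distance d from a zone boundary is misclassified with probability
Φ(−d/σ).  Shares in wide zones whose trajectory stays clear of boundaries
are recovered to ~1 pp at σ = 2; shares in narrow zones are biased
irreducibly — steady work at the Zone-4 midpoint (width 5 %HRmax) leaks
~10 % of its seconds to each neighbour.  This is a property of zone-based
accounting of noisy measurements, not of the estimator, and it is the
reason noisy parameter-recovery is assessed on the continuous
low-intensity condition (trajectory ≥ 2σ from every boundary), while
noise-free recovery is asserted exactly for all four session types.

## Problem sizes

Default sessions are 90 min (LIT) and 80 min (HIT) at 1 Hz; programme
fixtures use a handful of athletes with one to a few sessions per type,
and the end-to-end determinism check runs the full CLI pipeline twice on a
one-athlete programme with a 64-cell grid.  Oracle comparisons use n ≤ 50
points on grids of ≤ 400 cells, where the brute-force reference is exact
and fast.

## Known limitations

* The exclusion-window convention keeps wall-clock gaps; analyses that
  need continuous time axes must re-zero themselves.
* Plans carry minutes per zone only; no within-session ordering, so
  compliance is assessed distributionally, not temporally.
* Unweighted pooling at group level inherits contribution bias; the
  per-session weighting flag mitigates but changes the estimand.
* No compliance thresholds are built in: comparisons report differences
  and flag nothing.
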
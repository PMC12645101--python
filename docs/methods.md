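# Methods

This note documents the models implemented in `paircohesion`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
generator does and does not emulate.

## RSS–distance calibration

Received signal strength decays roughly log-linearly with distance, so the
calibration model is

    log10(distance_m) = a + b · RSS,      b < 0,

fitted by ordinary least squares with log10-distance as the response and all
tags and receivers pooled into one global curve. The residual standard
error (log10-meter scale) is carried on the curve object and is the spread
used when resampling distances during multilateration. The bundled
reference curve (a = −1.27009, b = −0.03302, for node-grid hardware with
tags at 1.5 m) places the −80 dB confidence cutoff at a 23.5 m radius.

Fitting distance on RSS (rather than RSS on distance) matches the closed
form actually used downstream — the curve is always *evaluated* as
distance-at-an-RSS — and avoids an inverse-regression bias at evaluation
time. A fitted slope ≥ 0 is rejected as unphysical. Degenerate designs
(< 3 observations, a single distinct RSS value) raise a singular-fit error.

Per-test-point detection metrics define the detection rate as distinct
detected beacon instants divided by expected beacon emissions, capped at 1;
a beacon heard by several receivers counts once. Undetected points report
missing RSS summaries, never 0 dB (0 would be a very strong signal).

## Localization

Detections are binned into half-open, epoch-aligned windows
(`[floor(t/15)·15, +15 s)`), keeping each receiver's strongest detection per
window. Epoch alignment is what makes windows comparable *across* tags,
which every dyadic statistic downstream requires.

**Strongest detection.** The tag is placed at the receiver with the
strongest detection if that detection is at or above the −80 dB cutoff.
Ties at the maximum resolve deterministically to the lowest receiver id.

**Multilateration.** Windows qualify with ≥ 3 member receivers and an
above-cutoff strongest detection. Each of 100 resamples draws per-receiver
distances `10^N(a + b·RSSᵢ, residual_se)` — Gaussian on the log10-distance
scale, the scale on which the regression residuals live — and minimizes
`Σᵢ (‖p − rᵢ‖ − dᵢ)²` with scipy's bounded trust-region least squares,
started from the inverse-predicted-distance-weighted receiver centroid and
bounded to the array box expanded by 200 m. The reported fix is the mean of
converged resample fits (if more than half fail, no estimate). The error
ellipse is fitted to the resample scatter as a bivariate normal: semi-axes
`√2·√λ` for the covariance eigenvalues λ, orientation along the leading
eigenvector. With zero residual spread the resamples coincide and the
ellipse collapses, which the tests assert.

Localization rates divide distinct localized daylight windows by all
aligned daylight windows between a tag's first and last estimate. Gaps are
maximal runs of unlocalized daylight windows; each daylight interval is
scanned separately, so an overnight gap splits at sunset and sunrise rather
than spanning the night. Daylight is supplied as a per-date sunrise/sunset
table; no solar geometry is computed.

## Coverage

The strongest-detection method can only localize a tag within the cutoff
radius of some receiver, so the array's detectable area bounds the
achievable localization rate. Two conventions are reported side by side:
the per-receiver *summed* area `n·πr²` (the arithmetic used in field
summaries; it double-counts overlap) and the geometric *union* of disks.
The "printed" percentage of the array additionally mimics rounded-input
arithmetic (summed area rounded to 2 decimals before dividing, percentage
truncated to 2 decimals), because that is how such figures are typically
quoted; exact arithmetic gives a slightly larger value and both appear in
the report. Disk–polygon intersections use 64-vertex circle approximations
(area error < 0.2%).

Minimum convex polygons: 100% is the convex hull; 95% first peels the 5% of
points farthest from the centroid (a standard convention). Collinear point
sets are rejected as degenerate.

## Utilization distributions and overlap

The UD estimator is a Gaussian-kernel density evaluated on a regular grid
(10 m cells by default) and normalized to unit mass, with per-axis Silverman
bandwidths `σ̂·n^(−1/6)` floored at half a cell — sub-cell bandwidths are
unresolvable and point sets collapsed onto a single receiver would underflow
every kernel. This grid KDE deliberately stands in for autocorrelated KDE
(AKDE/continuous-time movement models): the overlap statistic and the area
extraction are identical, but the bandwidth does not correct for movement
autocorrelation, so absolute home-range areas from strongly autocorrelated
tracks will run small relative to AKDE. Comparative statements (pair vs
non-pair overlap, breeding vs post-breeding area changes) are insensitive to
this choice; absolute area levels are not.

The 95% home range is the smallest set of grid cells whose descending-mass
cumulative sum reaches 0.95 (greedy isopleth). The Bhattacharyya
coefficient is `Σ √(p·q)` over a shared grid; dyad UDs are always estimated
on a common grid covering both individuals padded by 3 bandwidths.

Temporal bookkeeping: weeks are counted from a configured start date;
sections of day are half-open bins of hours after sunrise ([0,3), [3,6),
[6,9), [9,14), with later times flagged into the last section); dates
strictly before the configured breeding-end date are "breeding", on/after it
"post-breeding". Dyad overlap is computed on per-period pooled locations;
weekly × section areas require at least 10 locations per cell.

## Cohesion

**Day-shift null.** The null for pair proximity pairs the focal bird's
locations on day x with the partner's on day x+1 at the same time of day,
i.e. the partner's window index shifted by exactly 86,400 s. This preserves
each bird's daily routine while destroying moment-to-moment coordination;
under independent movement the true and null separation distributions
coincide.

**Movement events.** On the strongest-detection series, an event is a
change of receiver between *consecutive localized windows* — unlocalized
gaps are skipped, because gaps are pervasive in node-grid data and requiring
adjacency would discard most genuine relocations. Departure time is the
last window at the origin, arrival the first window at the destination.

**Following events.** For a leader relocation A→B the partner is a
candidate follower when its most recent localization at or before the
leader's departure was at A and no staler than 600 s, and its next
localization at a different receiver is at B. The staleness limit is a free
parameter (detections are too sparse for exact co-presence); 600 s matches
the scale of the realized lag threshold. The candidate lag is follower
arrival minus leader arrival, floored at zero since sparse detections can
record the follower at B first.

**Lag threshold.** Extreme candidate lags arise from detection gaps, not
behavior, so a per-dataset threshold is set at the 90th percentile of
candidate lags using the nearest-rank convention — which guarantees by
construction that at least 90% of candidates fall within it. The threshold
is global across pairs, then applied per pair.

**Following rate.** The denominator keeps only leader events where *both*
birds have at least one localization within the threshold of the event
(otherwise following could not have been observed); the numerator counts
events with a candidate within the threshold. An empty denominator yields a
missing rate, never 0.

**Initiation.** Episodes are maximal runs of matched windows with both
birds at the same receiver; whichever bird's first subsequent localized
window is at a different receiver earlier is the initiator, equal windows
count as simultaneous, and episodes where either bird is never seen leaving
are skipped. Swapping the input order provably mirrors the shares.

## Synthetic generator

The generator emulates the data-collecting machinery of a node-grid study
of a territorial pair-living songbird:

* **Array**: an nx × ny lattice at 100–150 m spacing with Gaussian jitter.
* **Movement**: each individual is a discretized Ornstein–Uhlenbeck process
  around a territory center, using the exact transition
  `x' = μ + (x−μ)·e^(−Δt/τ) + σ√(1−e^(−2Δt/τ))·z` so long runs are stable
  and the stationary sd equals the configured home-range sd exactly. The
  pair is coupled leader–follower: per step, with probability `coupling`,
  the non-leading partner mean-reverts toward the leader's current position
  with the (short) following timescale instead of toward its own center.
  The per-step positional noise always uses the individual's own OU
  diffusion, so following tightens the pair without inflating step noise —
  with full coupling and a short follow lag the median pair separation sits
  well below the home-range sd. Roles swap by a symmetric Markov chain
  (default 0.1 switches/min), so both members initiate movements. An
  optional period schedule switches home-range sd and coupling at set times
  (e.g. ranges expanding after breeding ends).
* **Detection**: per beacon and receiver, detection is Bernoulli with a
  logistic distance decay `p_max/(1+exp((d−d₅₀)/w))`, a hard maximum range,
  and a multiplicative ground-height penalty (default 1/8.3) for tags in
  the ground height class. RSS is the inverse calibration curve at the true
  distance — clamped below at 1 m, the smallest calibration distance, to
  avoid log-of-zero — plus Gaussian dB noise (default 2 dB).

Defaults for quantities with no external anchor were chosen once at
field-realistic values and documented here: home-range sd 30 m (a ~0.017 km²
95% range, matching a small breeding territory), OU timescale 10 min,
follow lag 60 s, coupling 0.8. No quantitative movement-speed data exist
for the study system, so the movement parameters are free and documented,
not calibrated.

What the generator does **not** emulate: habitat heterogeneity and
preferential receiver placement, roosting/night behavior, nest-attendance
alternation, tag orientation and perch-height effects on RSS, and
autocorrelation structure beyond OU. Consequently, passing simulation-
recovery tests demonstrates that the estimators recover the generator's
truth under idealized field geometry — not that real detection data meet
the generator's assumptions (real localization rates, for instance, exceed
homogeneous-use predictions because receivers are placed where birds go).

## Problem sizes and numerical choices

Test simulations use 5×5 to 10×10 arrays, single- to multi-day tracks at
15-s steps, and 10–100 multilateration resamples — sizes chosen so each
statistic has enough events for its assertion to be ~3 standard deviations
from its failure boundary (e.g. the initiation-symmetry check aggregates
~5,000 episodes across 40 replicates for a 5-point tolerance). Replicated
properties (day-shift null, coupling monotonicity) use paired per-seed
comparisons with sign-test logic. All randomness flows through
`numpy.random.default_rng` seeds; fixing the seed fixes every output byte.

Known limitations: grid-KDE areas are bandwidth-sensitive for small n; the
summed coverage convention can exceed 100% under pathological receiver
overlap (flagged, and the union convention is reported alongside);
multilateration assumes the calibration curve holds at the tag's actual
height; and the simultaneous-departure category of initiation shares is
window-resolution dependent.
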
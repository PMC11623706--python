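# Methods

This note documents the models, parameter choices and numerical
conventions behind `swarmstall`, and what the synthetic data do and do not
show about real microscopy data.

## The flagellar-state chain

Cell motility states are modelled as a continuous-time Markov chain on
{CLOSED, PARTIAL, OPEN} (run / tumble / stall).  Dwell times in state *i*
are exponential with exit rate `q_i`; jumps follow the embedded matrix
`P` (zero diagonal, row-stochastic).  The fitted wild-type model uses

- exit rates `q = (4, 4.76, 1.05) 1/s`, equivalently mean dwells
  `(0.25, 0.21, 0.95) s`;
- `P = [[0,1,0],[1/2,0,1/2],[0,1,0]]` — every stall is entered and left
  through the partially open state; direct CLOSED↔OPEN jumps are
  structural zeros.  The PARTIAL row is split evenly between its two exits;
  the measured split is "close to equal" and the even split is adopted as
  the model convention.

Simulation is Gillespie sampling with either a time horizon (the final
dwell is truncated and flagged censored) or a fixed number of jumps.  The
jump-chain stationary vector `pi` solves `pi = pi P` by least squares
(tiny negative components from unreachable states are clipped); long-run
time fractions weight `pi` by the mean dwells.  For the fitted model the
stationary time fraction spent stalled is
`pi_O m_O / sum_i pi_i m_i ≈ 0.587`.

### Inference

- Maximal constant-state runs become dwells; the first and last dwell of
  every track are flagged censored and excluded from fits by default.
  For exponential dwells this exclusion barely moves the mean (the
  boundary pieces of a stationarily-cut exponential dwell are themselves
  exponential — inspection-paradox cancellation); it matters for short
  observation windows, where truncation biases estimates low, and for any
  non-exponential data.
- The exponential MLE is the sample mean (`rate = 1/mean`,
  `loglik = n(−log m − 1)`).
- The two-component exponential mixture is fit by EM (tolerance 1e-8 on
  the log likelihood, 500 iterations, 10 restarts from log-normally
  perturbed quantile initializations, seeded).  The reported likelihood is
  floored at the nested single-exponential solution, so the mixture can
  never score below it.  `AIC = 2k − 2 loglik` with `k = 1` for the single
  exponential and `k = 3` for the mixture; the comparison is reported as
  `AIC(single) − AIC(mixture)` (negative favors the single exponential).
- The memorylessness check compares the empirical two-step matrix `Q̂`
  (overlapping pairs: state at jump n vs n+2, rows normalized) with the
  square of the empirical one-step matrix, as the maximum entrywise
  relative error over entries of `P̂²` above 0.01 — the cutoff excludes the
  structural zeros, whose relative error is undefined.  Because `Q̂` and
  `P̂` come from the same sample their fluctuations partly cancel, so the
  error at 10⁶ transitions (~0.02–0.2% depending on seed) sits well below
  the independent-sample expectation; the acceptance bound of 1% is
  comfortably met.

## The swarm generator

The generator emulates the region-of-interest statistics of a swarming
colony edge: rod cells 1×7 µm at surface fraction ρ = 0.3 by default, on a
periodic arena (minimum-image neighbor distances; an interior field of
view has no physical walls, and wrapping avoids edge artifacts).  Cell
bodies are *not* sterically excluded — none of the analyses here require
contact mechanics — so overlaps occur.

Per cell and frame (default 50 frames/s):

- base speed from the current dwell: a Rayleigh draw (fresh per dwell,
  constant within it) for runs; a fraction (default 0.4) of a Rayleigh
  draw for tumbles; exactly 0 for stalls.  The Rayleigh choice gives the
  speed distribution its Gaussian tail.
- heading: persistent during runs; kicked once by Uniform(±90°) at the
  start of each tumble dwell.
- density coupling: speed is multiplied by `g(k) = min(k, 5)/5` where `k`
  counts neighbors within 7 µm — a piecewise-linear ramp with `g(0) = 0`
  (isolated cells do not move) saturating at 5 neighbors.  Only the
  qualitative shape of the measured speed-vs-neighbors curve is known;
  the ramp is the simplest curve with the right endpoints.
- wetness `w ∈ [0,1]`: exponential relaxation toward 0 with time constant
  `tau_dry = 2 s` while the cell is immobile (speed exactly 0: stalled, or
  isolated under the coupling) and toward 1 with `tau_wet = 0.15 s` while
  it moves.  The drying constant sets which stalls become visible in the
  hue channel (episodes shorter than `tau_dry·ln 2 ≈ 1.4 s` never cross
  the wet threshold); the fast re-wetting constant keeps the re-wet lag
  (~0.05 s) small compared with the 0.95 s stall scale, so DIC-detected
  episode durations remain distributionally consistent with the OPEN
  dwells, and lets a cell recover fully between consecutive stalls.

Two mutually exclusive speed calibrations are provided, matching the two
ways a swarm's speed scale is quoted.  `calibrate_saturation_speed` sets
the Rayleigh scale so the stationary mean speed at full coupling is
20 µm/s (the plateau of the speed-vs-neighbors curve);
`calibrate_fast_subset_speed` sets it so the mean over samples faster than
7 µm/s is 19.5 µm/s (the "fast subset" summary).  They cannot hold
simultaneously for a Rayleigh mixture — conditioning on the fast tail
necessarily raises the mean above the all-sample mean — so each analysis
uses the calibration matching the quantity it measures.

Two stock state models are exposed: the fitted single-cell chain above,
and a population-level "motility" variant (run exit rate 0.5 1/s, tumble →
stall probability 0.2) in which stalls occupy ~10% of the time — the
regime of scattered temporarily immobile cells among moving clusters.  A
`stall_bias` factor scales the tumble→stall branch to emulate drier
surfaces; doubling it roughly doubles stall occupancy (the wet/dry
contrast).

## Rendering

Intensity frames are the mean of `n_subsamples = 11` instantaneous
rasterizations spread uniformly (endpoints included) over the exposure
window; 11 subsamples keep a 20 µm/s × 0.2 s streak gap-free at the
default 0.2 µm/px.  Each instant draws every cell as a filled rotated
rectangle at intensity 1 on background 0 (scikit-image polygon
rasterization, pixel-center inclusion), with optional Gaussian smoothing
and additive Gaussian noise (σ = 0.02 by default in the pipeline) per
instant.  Averaging is exactly linear — the integral of the mean frame
equals the mean of the instants' integrals — but center-sampled
rasterization changes a rod's pixel count by ~1% under sub-pixel
translation, so blurred-vs-sharp intensity conservation holds only to
that rasterization tolerance.

Long exposures are synthesized by block-averaging `ratio` consecutive
frames (default 10: 50 frames/s, 0.02 s → 5 frames/s, 0.2 s), which is how
a slower camera with proportionally longer exposure would integrate the
same scene.

The DIC hue map is an abstract axis carrying the classification
thresholds; no color-space conversion is attempted.  Background pixels and
cells with wetness ≥ 0.5 draw Uniform(43, 45).  A drier cell's pixels
follow `hue = 27 − 13·d·sqrt(1 − |u|)` where `d` is dryness (0 at the wet
threshold, 1 fully dry) and `u` the normalized transverse offset across
the rod — a slope-like profile that makes a fully dry rod black along its
ridge, blue on the flanks and green at the edges, while a mildly dry cell
is green only.  A configurable fraction (default 0.1%) of pixels is
replaced by Uniform(28, 42) noise; that band is otherwise structurally
empty.

Coordinates: 0-based pixel indices, x rightward, y downward,
`x_um = col × pixel_size`; the arena maps exactly onto the image and
drawing wraps periodically.

## Immobility detection and bin occupancy

A long-exposure frame is thresholded near full intensity (default 0.95)
and connected components with area below 0.9 of the nominal body area
(7 µm² at the stack's pixel size) are discarded.  A rod translating along
its axis keeps a fully covered core of length `L − v·t_exp`, so at 0.2 s
exposure the area band rejects cells moving faster than ≈ 6.5–7 µm/s —
the detection cutoff falls naturally at the slow/fast split used in the
speed statistics.  Slow-moving cells below that speed are accepted as
"temporarily immobile", which matches how thresholded long-exposure
images read in practice.  For scoring, a ground-truth labeling rule is
exported: a cell is immobile at a long-exposure frame iff it is in the
OPEN state for ≥ 90% of the exposure window.

Bin occupancy divides the field into a 10×10 grid (image dimensions must
divide evenly); a bin is occupied in a frame when it contains at least
one third of a body area of masked pixels.  The "third of a cell" rule is
interpreted as projected area, not length.  Statistics over a window
duration T use disjoint windows so across-window samples are independent
for the central-limit check; per-(bin, window) occupation fractions give
the mean and the across-bin std per T (durations 5–360 s in 5 s steps by
default).  The std exponent is the OLS slope of log std vs log T;
memoryless stalling yields −1/2.  The temporal autocorrelation is the
bin-averaged, mean-subtracted autocovariance normalized at lag 0; the
primary decay time is the first 1/e crossing (first zero crossing is also
reported but is noisier).

## Kinematics

Tracking links per-frame centroids by greedy mutual-nearest-neighbor
matching within a displacement gate; unmatched detections start new
tracks.  Identity recovery is guaranteed only while detections stay
mutually resolvable — overlapping cells (which the generator permits) can
pass through each other, making identity physically undefined at the
crossing.  Instantaneous speeds use central differences (one-sided at
track ends), which are less biased than forward differences; tracks
shorter than 5 frames are excluded from statistics.  The fast-subset mean
averages samples above 7 µm/s.  The Gaussian-tail check fits the
log-density above the histogram mode to a quadratic in speed; a Rayleigh
distribution is log-quadratic up to the slowly varying `log v` term, so
high R² plus curvature ≈ −1/(2σ²) is the expected signature.  Neighbor
counts use center-to-center minimum-image distances, scanned over cutoff
radii {3, 5, 7, 10} µm by default; empty neighbor-count bins are reported
as missing, never as zero.

## Hue analysis

Classification floors fractional hues and applies the integer band edges
(≤20 black, 21–24 blue, 25–27 green, 28–42 unclassified, ≥43 background);
the bands are exhaustive and mutually exclusive, and the unclassified band
is never merged into a wet or dry class.  A cell's dryness signal is the
non-background pixel fraction inside its padded, cell-oriented bounding
rectangle (pad 0.25 µm).  The oriented box keeps the fully-dry plateau
(body area / box area ≈ 0.62) orientation-independent and above the upper
hysteresis threshold; an axis-aligned box would dip below it for diagonal
cells.  Events are extracted with hysteresis (dry when the fraction rises
through 0.5, wet again when it falls through 0.2), which guarantees
alternating stopping/wetting events; stall durations are measured between
the dry-declaration and wet-declaration instants of consecutive events.

## Pipeline scale and determinism

The end-to-end pipeline runs all stages at a configurable arena size; the
default (40×40 µm, 20 cells, 60 s, 100×100 px) completes in about a
minute on one CPU, and statistical tests use larger dedicated
configurations (e.g. 154 cells at ρ = 0.3 for 1500 s of occupancy data,
computed from ground-truth stall masks at the long-exposure cadence).
Occupancy window durations are trimmed to at most half the series length.
All randomness derives from a master seed through named per-stage
`SeedSequence` spawns, so a fixed seed reproduces every artifact
byte-for-byte and overriding one stage's seed leaves upstream stages
unchanged.

## What the synthetic data do not show

The generator reproduces the *statistical* structure of swarm imaging —
state-coupled speeds, density coupling, wetness-driven hue, exposure blur —
not its physics or optics.  There is no steric alignment or collision
(no whirls/jets), no hydrodynamics or liquid-film transport, no optical
PSF, phase halo or true DIC interference, and the hue scale is abstract.
Passing tests therefore validate the analysis chain's correctness and its
statistical laws (CLT scaling, memorylessness, detection geometry), not
instrument-specific calibrations; absolute occupancy percentages, for
example, depend on arena scale and stall propensity and are only
directionally comparable (wet vs dry) with experiments.
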
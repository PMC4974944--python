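# Methods

## The estimator

The encounter model treats a survey as an ideal-gas collision problem.  In
the animals' reference frame the sensor sweeps area at rate p̄·v, where v is
the animals' speed and p̄ the mean profile width — the average, over approach
angles, of the width of the band of parallel straight trajectories that lead
to capture.  With density D the expected encounter count over time t is
z = p̄·v·t·D, inverted as D̂ = z/(v·t·p̄).  The model assumes: animals move in
straight lines at constant speed with isotropic headings, independently of
the sensor; detection within the sensor's sector of radius r and width θ is
certain when the animal's directional signal (width α, centred on the
heading) faces the sensor, and impossible otherwise; and every entry into
the detectable set is recorded (a continuously recording sensor with no
trigger delay).  Repeat encounters of one individual count — z is an
encounter count, not an individual count — which is what makes the estimator
insensitive to animals revisiting the sensor.

## Exact profile geometry

For heading γ the detectable set is the intersection of the sensor sector
with the wedge of half-angle α/2 opening from the sensor toward direction
γ + π.  Writing arcs in the angle variable relative to the signal axis, the
intersection is that of two circular arcs, and the profile is

    p(γ) = r · [max(0, sup sin δ) + max(0, −inf sin δ)],  δ over the arc
    intersection,

because the detectable set is a union of at most two circular sectors with
apex at the origin, whose projection onto the direction perpendicular to the
heading is an interval containing zero.  `profile_width` evaluates this
exactly.

Two independent routes give the mean profile:

* `mean_profile_numeric` — composite-Simpson quadrature of p over the
  half-circle (symmetry halves the domain), with interval doubling from
  4 097 nodes until successive estimates agree to `max(tol·2r, 1e-3·r)`.
* `mean_profile_closed` — exact piecewise-analytic integration.  On any
  interval of approach angles where the combinatorial structure of the arc
  intersection is fixed, each of the two terms of p equals one of a small
  family of expressions {0, 1, sin(α/2), ±sin(θ/2 − ψ), ±sin(ψ + θ/2)}·r.
  All candidate breakpoints have the closed form s₁·α/2 + s₂·θ/2 + k·π/2;
  the active expression on each piece is identified by probing and the
  pieces are integrated with exact antiderivatives.  The result is exact up
  to floating-point rounding, continuous in (θ, α) by construction, and is
  verified in the tests against quadrature on a 50 × 50 grid (tolerance
  5·10⁻³·r), against the ideal-gas chord 2r, the camera-trap REM form
  r(2+θ)/π (derived independently by hand), and the SE2 expression
  (r/π)(θ sin(α/2) − cos(α/2) + cos(α/2 + θ)).

Submodel regions — the (θ, α) domains sharing one analytic form — are
*discovered* as the loci where the piecewise structure changes rather than
transcribed from a catalogue: `classify_submodel` returns "gas", "REM" and
"SE2" for the classically named regimes and a deterministic structural
signature elsewhere.  On a region boundary either adjacent label may be
returned; the closed forms agree there.

Degenerate widths: α = 0 or θ = 0 return p̄ = 0 exactly (the detectable set
has measure zero), and `estimate_density` refuses such configurations.

## Parameter sensitivity

`parameter_sensitivity` holds the count at its expectation under the true
parameters and re-estimates with one parameter perturbed by a relative
error e, isolating parameter-induced bias from sampling noise.  Speed and
detection distance enter as 1/(1+e) exactly (−4.76% at +5%); angles act
through p̄, whose elasticities are at most modestly above one — over the
7 × 11 study grid the density error never exceeds the parameter error by
more than 3.6 percentage points (α near π at small θ is the worst case).
Angle perturbations leaving [0, 2π] are clipped and flagged.  The
stochastic counterpart (simulate truly, estimate perturbed) is
`parameter_error_experiment`.

## The simulation world

The validation simulator places floor(L²·D) animals uniformly on an
L × L torus with uniform headings; one sensor sits at the centre.  Defaults
are the canonical validation conditions: L = 7.5 km, D = 70 animals/km²
(3 937 animals), 14 400 steps of 15 min (150 days), v = 40 km/day,
r = 10 m.  Each step an animal stays put with probability S, or turns by
Uniform[−A, A] and moves d ~ Normal(vT, vT/10), truncated at zero (the
truncation acts 10 standard deviations out; it exists for safety, not
effect).  Headings persist through stationary steps.

Detection along a step's motion segment is computed exactly: the disc, the
sector wedge and the signal wedge each delimit closed-form intervals on the
line, and the first detectable point of an "armed" animal emits one
encounter, time-interpolated within the step.  An animal disarms on
detection and re-arms only after its distance from the sensor exceeds r, so
one pass through the profile counts exactly once — matching the
profile-width derivation.  Animals that start inside the detectable set
count once at t = 0 (expected contribution < 0.03 encounters at the
defaults).  Exactness matters: sampling the segment at spatial resolution
δ misses the profile edge, where the detectable stretch of trajectory
vanishes, undercounting by ≈ δ·cos(α/2)/r — about 5% at δ = r/20 for any
narrow signal, which would swamp the estimator's real bias.

Segments are unwrapped against the torus image of the sensor nearest the
segment midpoint; configurations whose steps could span half the torus
(arena ≤ μd + 10σd + 2r) are rejected at construction.

Randomness: a root seed spawns one PCG64 stream per animal plus one for
placement, so runs are bit-identical regardless of internal chunking, and
stop-start/turning variants consume per-animal streams reproducibly.

## Validation experiments and problem sizes

Four studies mirror the validation protocol: grid accuracy (fixed-duration
surveys over seven sensor widths 2π·{1,2,3,4,5,7,9}/9 by eleven signal
widths π·{1..11}/11), capture-number precision (run until 10–100 captures,
estimate with the elapsed time), movement models (S ∈ {0, 0.25, 0.5, 0.75};
A ∈ {0, π/3, 2π/3, π}), and parameter error.  For stop-start movement the
estimator receives the realised average speed v·(1−S): the model's v is
distance covered per unit time during the survey, and feeding the nominal
speed would bias D̂ low by exactly the stationary fraction.

The package's *desk scale* keeps the density, duration, geometry and sensor
(hence the expected captures per survey, which do not involve the arena
size) but shrinks the arena to 1.5 km and runs 30 replicates on six cells
spanning the grid — four corners plus two interior cells — with the four
corner cells standing in for the "representative" submodels of the
capture-number and movement studies.  These sizes keep the whole validation
suite at a few minutes on one core; `--full-scale` restores the 7.5 km /
100-replicate profile.

### What desk scale does and does not preserve

Shrinking the arena preserves the *mean* encounter count (verified: mean z
matches p̄·v·t·D within Monte-Carlo error in every tested cell) but not its
*distribution*.  With straight-line movement an animal keeps one heading
for ~6 000 km of travel — ~4 000 torus wraps at L = 1.5 km — so per-animal
encounter counts are heavy-tailed: an animal whose winding lattice aligns
with the profile logs 10–20 encounters while most log none.  With only 157
animals the replicate count at the smallest grid cell (θ = 2π/9,
α = π/11, E[z] ≈ 146) has CV ≈ 24% versus the Poisson 8%, and its
right-skewed distribution puts the replicate *median* ≈ 3% below the truth
even though the mean is unbiased.  At full scale (3 937 animals, 800
wraps) the same cell measures CV ≈ 8% and the skew is negligible — the
regime in which the headline sub-2% median accuracy and the 10% CV at 100
captures hold.  Desk-scale runs of the narrow-corner cell therefore show
inflated CVs (≈ 22% at 100 captures) and median offsets of several percent;
these are properties of the scaled-down world, not of the estimator.  The
test suite and the acceptance script report the desk-scale numbers as
measured.

The simulation world is also deliberately simpler than field data: no home
ranges or behavioural states, a single sensor, homogeneous density, perfect
detection inside the detectable set, no trigger delay or duty cycling.
Passing validation here shows the estimator inverts its own generative
model accurately — not that field surveys meet the assumptions.

## Numerical choices

* Quadrature: Simpson on uniform angle grids with doubling; kinks in p make
  the effective order low, so the node counts are generous (≥ 4 097).
* Closed-form piece identification probes three interior points per piece
  and requires agreement to 10⁻¹⁰; unmatched pieces raise rather than
  silently fall back.
* Breakpoints closer than 10⁻¹² radians are merged; boundary (θ, α) points
  may classify to either adjacent region.
* Segment/disc and wedge crossings use closed-form ray intersections;
  crossings exactly at the sensor position are kept as partition points
  (a head-on trajectory through the sensor is a genuine boundary case).
* Experiment replicate seeds derive order-independently from
  SeedSequence entropy tuples (cell, movement, replicate), all below 2³¹.

## Known limitations

* The moving-sensor extension (replacing v with the relative speed) is out
  of scope, as are trigger delays, duty-cycled sensors and
  distance-dependent detection probability.
* No variance or confidence-interval estimator for D̂ is provided; the
  precision results here are empirical, from replicate simulation.
* Desk-scale validation inherits the dispersion artefact described above;
  conclusions about estimator *precision* should use the full-scale
  profile.
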
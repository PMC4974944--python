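# grem — generalised random encounter model

`grem` estimates **absolute animal density from count data** recorded by a
single stationary sensor — a camera trap, an acoustic detector, a sonar —
without identifying individuals and without measuring distances.  It
generalises the ideal-gas encounter model and the camera-trap random
encounter model (REM) to sensors of *any* detection width θ ∈ (0, 2π] and
to animals whose signal (call, visible aspect) is *directional*, detectable
only within a width α ∈ (0, 2π] of the animal's heading.  That makes it
usable for wide-angle cameras and, especially, for single acoustic
detectors monitoring species with directional calls (echolocating bats,
cetaceans, songbirds).

It is written for ecologists running remote-sensor surveys and for
methodologists studying estimator behaviour: the package contains the
estimator itself, exact detection-geometry computations, and the
agent-based simulation used to validate accuracy and precision.

## The model

A sensor at the origin detects anything within distance *r* whose bearing
lies within θ/2 of its facing axis; an animal moving with heading γ is
detectable only when the bearing from the animal to the sensor lies within
α/2 of γ.  For each approach angle the set of parallel straight
trajectories that lead to capture forms a band of width *p*(γ) — the
*profile*.  Averaging over approach angles gives the mean profile

    p̄(θ, α, r) = (1/2π) ∫₀²π p(γ) dγ,

the effective encounter cross-section: a population of density *D* moving
with speed *v* produces an expected encounter rate p̄·v·D.  A survey of
duration *t* recording *z* encounters (repeat detections all count)
therefore yields

    D̂ = z / (v · t · p̄).

Special cases: θ = α = 2π gives p̄ = 2r and the ideal-gas estimator
D = z/(2 r v t); α = 2π with θ < π/2 gives the classic camera-trap REM
p̄ = r(2+θ)/π; in the "SE2" regime (2π − α/2 < θ ≤ 2π, α < π),
p̄ = (r/π)(θ sin(α/2) − cos(α/2) + cos(α/2 + θ)).  `grem` evaluates p̄ for
*every* (θ, α) by exact piecewise-analytic integration and cross-checks it
against numerical quadrature.

## Worked example

A 150-day acoustic survey, detector width 337.5° (θ = 15π/8), detection
distance 10 m, species with signal width 90° (α = π/2) moving 40 km/day,
1 047 encounters recorded:

```sh
$ grem profile --theta 5.8905 --alpha 1.5708
p_bar = 0.0139483
region = SE2
method = closed_form

$ grem estimate --z 1047 --t 150 --v 40 --theta 5.8905 --alpha 1.5708 --r 0.01
D_hat = 12.5105 animals/km^2
p_bar = 0.0139483 km
region = SE2
```

The first command reports the mean profile width (km) and the closed-form
regime that applies; the second converts the count into a density:
1047 / (40 km day⁻¹ × 150 days × 0.0139483 km) ≈ 12.5 animals per km².
Ignoring call directionality (α = 2π) would have used p̄ = 0.02 km and
underestimated density by 30%.

The same library surface is importable:

```python
from grem import SensorSpec, SignalSpec, SurveyCounts, SurveyParams, estimate_density
params = SurveyParams(v=40, t=150, sensor=SensorSpec(5.8905, 0.01), signal=SignalSpec(1.5708))
est = estimate_density(SurveyCounts(1047), params)
est.D_hat            # 12.51...
est.p_bar_used.region_label  # 'SE2'
```

`grem simulate` runs the agent-based validation world (animals on a torus
passing a central sensor) and writes an encounter log;
`grem exp-accuracy`, `grem exp-captures`, `grem exp-movement` and
`grem exp-paramerr` run the four validation studies at desk scale
(`--full-scale` for the canonical 7.5 km / 100-replicate profile) and write
tidy CSV summaries, optionally with box-plot figures (`--figures`).

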
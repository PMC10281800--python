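# cuculus

Why hasn't the common cuckoo (*Cuculus canorus*) advanced its spring
arrival to the UK in step with its hosts?  Answering that from satellite
telemetry requires a whole chain of analyses: turning duty-cycled Argos
fixes into stopovers, dating six migratory milestones per annual cycle,
asking how repeatable each milestone's timing is within individuals,
tracing — by Bayesian path analysis — how timing carries over from stage
to stage into breeding-grounds arrival, and testing whether timing
predicts mortality in the following migration stage.  `cuculus`
implements that chain as a tested, reusable pipeline for movement
ecologists, and ships a synthetic-data generator that emulates the whole
observation process (10 h-on / 48 h-off transmission duty cycles, missed
cycles, positional noise, individual random intercepts, stage-wise
mortality) so every stage can be validated against known truth.

## The models at the core

**Repeatability.** For each milestone, date ~ 1 + (1 | individual); with
between- and within-individual variances σ²_b and σ²_w,

    R = σ²_b / (σ²_b + σ²_w),

fitted by Gibbs sampling (4 chains, 2000 burn-in, 4000 retained,
convergence at split-chain R̂ < 1.1), half-t(3) priors on both SDs.

**Timing path model.** A piecewise structural equation model over the six
milestones M₁…M₆ and six covariates (habitat, route, breeding lon/lat,
pre-Sahara stopover locations), all z-scored.  Each node is linear-normal
in its DAG parents; missing entries are drawn from their full
conditionals inside the Gibbs sweep, so imputation uncertainty propagates
into the posteriors.  For a standardized path coefficient β the direct
variance share is β²; an indirect share is the product of the stage
shares along the path; edge support is p(non-zero) = max posterior mass
on either side of zero, tiered at 0.80 / 0.90 / 0.95.  The declared
structure is checked by directed separation (Fisher's C = −2Σln p on 2k
df over the Shipley basis set).

**Mortality model.** Per milestone, a two-equation path model: logistic
regression of death-in-next-stage on standardized timing with habitat,
route and habitat × timing, plus a linear sub-model of timing on habitat
and route; and a pooled analysis of the three milestones that most
positively impact arrival, with milestone-specific intercepts and a
shared timing slope.

## Worked example

The demo configuration simulates 60 tagged males followed for up to three
annual cycles and runs every stage:

```sh
cuculus all --config configs/demo.yaml
```

which logs (abridged):

```
simulate: 60 birds, 109 bird-years, 10508 fixes, 50 deaths
segment: 10508 fixes -> 10508 cycles -> 543 stopovers
milestones: 491 extracted, 458 retained after the 5-day uncertainty
  filter -- 458 milestones from 107 migratory cycles for 58 birds
path-timing: n=107 cycles, converged=True, Fisher's C p=0.809
```

and writes `results/demo/report.txt`:

```
repeatability (median, 95% interval):
  depart_breeding          0.40 [0.07, 0.65]
  ...
  depart_west_africa       0.45 [0.15, 0.69]
  mean 0.36, range 0.20-0.49

supported paths (p >= 0.80):
  depart_west_africa -> arrive_breeding   +0.764 (p=1.00, very well-supported)
  depart_winter -> arrive_breeding        -0.272 (p=1.00, very well-supported)
  complete_sahara_south -> depart_west_africa  +0.549 (p=1.00, ...)
```

Reading this: departure from the West African stopover dominates
breeding-grounds arrival (0.764² ≈ 58% of its variance in this run; the
generating coefficient is 0.883, attenuated by duty-cycle dating error),
winter departure has a small negative direct effect, and the southbound
Sahara crossing carries over into West-Africa departure — the same causal
picture the generator encodes.  The mortality stage recovers its
generating slopes too (e.g. +2.06 for late breeding-grounds departure,
truth +2.0; pooled early-bird effect −1.6, truth −1.5).

The numbered drivers under `analysis/` run the same stages as a narrated
sequence (`01_simulate_tracks.py` … `07_variance_decomposition.py`);
`07` prints the closed-form variance decomposition of arrival timing from
the published coefficient table (78.0% from West-Africa departure, 3.3%
via the breeding-departure chain, 11.2% unexplained, …).

## Layout

```
src/cuculus/      library: synthetic data, io, segmentation, milestones,
                  repeatability, path models, studies, pipeline, CLI
analysis/         numbered narrative drivers over the library
configs/          run configurations (YAML, schema-validated)
scripts/          acceptance script
tests/            pytest suite (unit + property + end-to-end validation)
docs/methods.md   models, assumptions, parameter choices, limitations
```
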
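# stepsel

Integrated step-selection analysis (iSSA) for GPS-tracked animals on
seasonally dynamic landscapes — from raw fixes and gridded covariates to
fitted selection coefficients, AICc model selection and relative selection
strength (RSS), with post-release **experience** and social **group size**
as moderators of habitat selection.

The package grew out of the analysis of scimitar-horned oryx (*Oryx
dammah*) reintroduced into central Chad: captive-born animals released into
an unfamiliar semi-arid reserve, tracked at 4-h intervals, whose responses
to vegetation greenness, terrain and temperature shift with time since
release and with the size of the social group they travel in. It is aimed
at movement ecologists who want that analysis as a tested, reusable,
fully-synthetic-testable pipeline rather than a one-off script.

## The model

Each observed 4-h step is matched with 9 *available* steps drawn from an
empirical movement kernel — gamma step lengths, von Mises turning angles —
sharing its start point. Selection coefficients β maximise the conditional
logistic (partial) likelihood over these 1:9 strata,

    ℓ(β) = Σₛ [ β′x_used(s) − log Σ_{j∈s} exp(β′x_j) ],

with step length and log step length as movement-correction terms, animal
identity as the cluster for sandwich (robust) variance, and centred/scaled
covariates: NDVI anomaly (aNDVI), 16-day NDVI change (dNDVI), elevation,
terrain ruggedness (TRI) and temperature, plus quadratics and one-way
moderator interactions. Four nested candidates per season (dry = Jan–Jun,
wet = Jul–Dec) are ranked by AICc: environment only (M1), + experience
(M2), + group size (M3), + both (M4). RSS = exp(β) is the selection-
probability ratio per standardized unit of a covariate; curves with 95%
delta-method bands are produced against the seasonal mean.

Group size follows the *chain rule*: within a 4-h bin, animals within 200 m
of at least one other member belong to one group (connected components of
the proximity graph). Experience is days since the animal's release.

A first-class synthetic-data module simulates landscapes (16-day NDVI
composites with seasonal cycle and anomalies, multi-scale terrain,
temperature) and multi-animal trajectories driven by a known step-selection
rule — including group cohesion — so every stage is testable by parameter
recovery without the (non-public) field data. See `docs/methods.md`.

## Worked example

`examples/` holds one short script per capability. End-to-end on synthetic
data (`python examples/group_detection.py`):

```
12 animals in 3 planted groups, cohesion strength 25 per km

detected group-size distribution over all 4-h bins:
  size 1:    25 animal-bins  #
  size 2:     4 animal-bins
  size 3:    63 animal-bins  ###
  size 4:   640 animal-bins  ################################

modal detected size: 4 (matches the planted group size of 4; smaller sizes are transient splits)
```

The planted social structure is recovered by the chain rule. On the
inference side, `python examples/published_selection_strengths.py` works
with the published final-model coefficients for the reintroduced oryx
population:

```
environmental main effects (dry period):
       term  coefficient    rss  significant
      aNDVI       0.2206 1.2468         True
      dNDVI      -0.1189 0.8879         True
  elevation       0.0330 1.0336         True
        TRI      -0.0693 0.9330         True
temperature      -0.0183 0.9818         True
```

RSS 1.2468 for aNDVI means a step ending on ground one standard deviation
greener-than-usual is ~25% more likely to be chosen than an otherwise
identical step at typical greenness; TRI's 0.9330 is avoidance of rugged
terrain. `examples/parameter_recovery.py` closes the loop — simulate with
known β, re-estimate through the whole pipeline:

```
replicate seed 103:
            term  truth  estimate     lo     hi  covers
           aNDVI +0.500    +0.427 +0.034 +0.820    True
             TRI -0.400    -0.404 -0.469 -0.338    True
  TRI:experience +0.300    +0.322 +0.257 +0.387    True
```

A thin CLI wraps the same library code:

```sh
stepsel simulate --profile tiny --seed 3 --out data/
stepsel run --config config.yml        # fixes -> steps -> strata -> fits -> RSS
```

writing `steps.csv`, `strata.csv`, `coefficients_{period}_{tier}.csv`,
`aicc_{period}.csv`, `curves_{period}.csv` and a run manifest into the
output directory, byte-identically under a fixed seed.

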
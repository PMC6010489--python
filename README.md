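# stepcue

Step-length distributions from substrate micro-cues: model fitting, model
selection and simulation for animal search paths.

## The problem

Searching insects — the motivating case is Australian ants (*Myrmecia
midas*, *Melophorus bagoti*) searching for their nest — produce paths that
look random and are conventionally modelled as correlated random walks
with exponential step lengths. That randomness may be only apparent: a
walker that travels in straight lines and reorients whenever it contacts
a small substrate feature (a micro-cue) produces

* a simple **exponential** step-length distribution when cues are
  uniformly random (fractal dimension D = 2), and
* a **generalized stretched exponential** (GSE)

  p(l) = N · exp(−(λl)^γ) · l^μ,  with γ = D − 1 and μ = D − 2,

  when cues are fractally clustered with dimension 1 < D < 2 (a pure
  power law in the D = 1 limit).

The exponents are tied to a single measurable quantity — the fractal
dimension of the substrate texture — so fitting the constrained GSE to
observed step lengths yields an estimate D̂ of the environment's
micro-structure, and competing families (bi-exponential, bare stretched
exponential, unconstrained GSE, power law) can be ranked against it by
AICc and Akaike weights.

`stepcue` implements the whole chain as a tested package:

* **families** — all six candidate densities on a truncated support
  [a, b], plus the 2-D encounter theory: cue count n(r) = (r/δ)^D,
  encounter rate q(r) = ρD/(πδ²)(r/δ)^{D−2}, and the free-path law whose
  tail is exactly the constrained GSE;
* **fitting** — `StepLengthModel`, a scikit-learn style density estimator
  (multi-start bounded MLE), with AICc, pairwise and multi-model Akaike
  weights, pooling, an exact binomial sign test, and rank-frequency
  curves;
* **segmentation** — digitized 2-D trajectories cut into straight steps
  with the field criteria (turn angle > 45°, continuation ≥ 4 cm, 4-m
  analysis radius) and per-segment metrics;
* **simulate** — synthetic-data engine: Poisson and quadrant-retention
  fractal cue fields (the experimental quasi-fractal surface; limit
  dimension log 3/log 2 = 1.585), box-counting dimension estimation, the
  automaton walker, and dimension-recovery experiments;
* **pipeline / CLI** — end-to-end studies (`simulate` → `segment` →
  `fit` → `report`) from a JSON config, with CSV/TSV interchange, also
  exposed as the `stepcue` command.

The package bundles the published per-individual fit summary for 23
*M. bagoti* desert ants (step counts, per-family log-likelihoods and
pairwise Akaike weights) in `stepcue.datasets`.

## Worked example

Generate a level-8 quadrant fractal in an 8 × 8 m arena, run the walker,
and fit the candidate families on the fractal's scaling window:

```python
from stepcue import (quadrant_fractal, simulate_walker, WalkerConfig,
                     StepLengthModel, SupportBounds, StepSample, fit,
                     multi_model_weights, box_counting_dimension)

field = quadrant_fractal(levels=8, domain=8.0, seed=42)
D_box, _ = box_counting_dimension(field.points, domain=8.0)

traj, steps = simulate_walker(field, WalkerConfig(max_steps=2000, seed=43))
window = SupportBounds(field.delta, 2.0)
x = steps.lengths[(steps.lengths >= window.lower) & (steps.lengths <= window.upper)]
model = StepLengthModel(family="GSE_CONSTRAINED", bounds=window).fit(x)

s = StepSample(x, bounds=window)
fits = [fit(s, f, bounds=window) for f in ("GSE_CONSTRAINED", "BIEXP", "EXP", "POWER")]
comp = multi_model_weights(fits)
```

This prints (via the obvious `print` calls):

```
cues: 6561, delta = 0.0205 m, box-count D = 1.585
n = 1546 steps in the scaling window
D_hat = 1.559, lambda_hat = 2.117 1/m
logL = -192.25, AICc = 388.51
  GSE_CONSTRAINED  w = 1.00
  BIEXP            w = 0.00
  EXP              w = 0.00
  POWER            w = 0.00
```

The box-counting dimension of the generated cue field matches the
construction's similarity dimension (1.585); the walker's steps, fitted
by maximum likelihood, recover D̂ = 1.56 — the substrate dimension read
off from the movement pattern alone — and the constrained GSE carries
essentially all of the Akaike weight against its competitors, exactly the
theory's signature. On a uniform field the same pipeline returns D̂ ≈ 2
with the simple exponential top-weighted.

The same machinery runs from the shell:

```sh
stepcue simulate --field quadrant-fractal --levels 8 --seed 42 --n-steps 2000 --out run
stepcue fit run.steps.csv --models EXP,BIEXP,GSE_CONSTRAINED,POWER --out fits.tsv
stepcue recover --d-true 1.585 --n-steps 500 --n-seeds 20 --out recovery.csv
```

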
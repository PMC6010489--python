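# Methods

## Model

A walker travels in straight lines on a plane and reorients (to a fresh
uniform-random heading) whenever it contacts a substrate micro-cue of
detection radius ρ. If the number of cues within distance r of a point
scales as n(r) = (r/δ)^D — with δ the mean cue spacing and inner cutoff
of the scaling, and D the fractal dimension of the cue pattern — then the
probability per unit length of an encounter after free travel r is

    q(r) = ρD/(πδ²) · (r/δ)^{D−2},        valid for ρ ≤ δ/2,

the fraction of the circumference of the annulus at r occupied by cues.
Accumulating the hazard from the inner cutoff gives the free-path
survival S(r) = exp(−∫_δ^r q) and the step-length density p(r) = S(r)q(r).
For D = 2 this is a simple exponential with mean free path πδ²/(2ρ); for
1 < D < 2 it is the *constrained generalized stretched exponential* (GSE)

    p(l) = N · exp(−(λl)^γ) · l^μ,   γ = D − 1,  μ = D − 2,

and for D = 1 a pure power law. The practical consequence: fitting the
constrained GSE to observed step lengths estimates the fractal dimension
of the substrate texture from the movement pattern alone.

Candidate families for model selection, all truncated to a support
[a, b]: simple exponential (k = 1), bi-exponential mixture (k = 3,
reported with λ1 < λ2), bare stretched exponential exp(−(λl)^γ) (k = 2),
constrained GSE (k = 2: λ and D), unconstrained GSE (k = 3), and power
law l^μ, μ < 0 (k = 1). The "stretched exponential" family is the bare
kernel (μ = 0), not the Weibull form with an l^{γ−1} prefactor; the two
differ by a power prefactor that the unconstrained GSE covers anyway.
Models are ranked by AICc = 2k − 2lnL + 2k(k+1)/(n−k−1) and Akaike
weights (softmax of −AICc/2 after subtracting the minimum).

## Fitting

Maximum likelihood by bounded multi-start local optimization (L-BFGS-B on
the negative log-likelihood, ftol 1e−8): eight starts with log-spaced
rate values centred on 1/mean(data), cycled shape values (D ∈ {1.1, 1.5,
1.9, 2.3}, γ ∈ {0.3, 0.7, 1.0, 1.5}, …), plus starts seeded from the
optimum of each nested simpler family, which enforces the log-likelihood
nesting monotonicity (EXP ⊆ constrained GSE ⊆ free GSE; EXP ⊆ BIEXP) to
within optimizer slack. Search boxes: λ ∈ [10⁻⁴, 10⁴] m⁻¹ (log scale),
D ∈ (0.5, 3.0] — deliberately open above 2, since data-driven estimates
land on both sides of 2 — γ ∈ (0.05, 3], μ ∈ [−3, 3], w ∈ [0.01, 0.99].
A family with k parameters requires n ≥ k + 2 observations; smaller
samples are refused (and counted in reports, not silently dropped).

Normalization constants come from adaptive quadrature (absolute tolerance
1e−9) of the log-domain kernel with an overflow shift. Sampling inverts a
CDF tabulated on a 4096-node log-spaced grid with monotone piecewise
linear interpolation, which handles all six families uniformly.

Truncation bounds default to [min, max] of the fitted data, the
convention for truncated fits when no physical bounds are known. For
simulated walks the physical window is used instead — see below.

The exact binomial sign test doubles the smaller tail of Binomial(n, ½)
and caps at 1; no normal approximation.

## Segmentation

Digitized paths are polylines with jitter far below any behavioural turn.
A new straight segment begins at a vertex where (1) the turn angle
strictly exceeds 45° and (2) the path continues at least 4 cm beyond the
turn. The turn angle is measured run-to-run: the direction of the current
run (run start to current vertex) against the mean outgoing direction
over the next 4 cm of path, so sub-threshold digitization wiggle neither
fragments runs nor triggers turns, and on-the-spot turns (criterion 2)
are ignored. A vertex-to-vertex convention is available via
`turn_convention="vertex"`. Segment length is the polyline arc length of
the run — sub-threshold wiggle is travelled path — switchable to chord
via `length_convention`. Analysis stops at the first crossing of a 4-m
radius from the release point, located by linear interpolation on the
crossing edge. Summaries of the first k = 20 segments use across-
individual means with normal-theory t-intervals; individuals with fewer
than k segments are excluded and the exclusion count reported.

## Synthetic-data generator

The generator reproduces the study conditions: an 8 × 8 m arena centred
on the release point, a uniform condition (homogeneous Poisson cues,
δ = 1/√(π·density), D = 2) and a quasi-fractal condition built by the
quadrant-retention recursion — each retained square keeps a random 3 of
its 4 sub-quadrants per level, so the retained area fraction is exactly
(3/4)^levels and the infinite-depth similarity dimension log 3/log 2 =
1.585. Three levels reproduce the experimental surface class; deeper
recursions (default 8 for validation work) give the estimators a real
scaling range. A generalized variant keeps 3 sub-cells with probability
p = 4 − 2^D (else all 4), interpolating similarity dimensions in
[1.585, 2] for recovery experiments only.

**Calibration of δ.** For a fractal field the relation n(r) = (r/δ)^D
pins δ only once the mass prefactor is fixed: for the quadrant fractal
the mean number of cues within one deepest-cell size of a cue exceeds 1,
so the cell size itself is not δ. The field's δ is therefore obtained by
fixed-slope least squares of cue-centred mass counts against the scaling
law (log δ = mean(log r − log n̄(r)/D) over a dozen radii between the cell
size and a quarter of the arena, excluding edge-biased centres). The
calibration uses field geometry only, never walker output.

**Walker.** Cue detection is disc intersection (matching the
cross-section argument behind q(r)); the cue that triggered a turn is
refractory until the next turn, preventing zero-length step cascades the
theory does not model. Walls reflect by default (or stop); reflected
travel accrues to the current step. Default detection radius is one tenth
of the deepest cell size, keeping ρ well under δ/2 and the encounter
geometry close to the point-cue idealization. Everything is reproducible
from a single integer seed, and cue discs are persistent (an
ephemeral-cue variant would remove a cue on contact; the predicted
functional form is the same, so only the persistent case is implemented).

**Analysis window for simulated fits.** The free-path law holds only
inside the fractal's self-similar range. Below δ the scaling breaks down;
above roughly a quarter of the arena the finite extent of the pattern and
wall folding homogenize the field, and reflected flights can grow far
beyond any physical step. Recovery fits therefore use the window
[δ, domain/4] and discard steps outside it — the outer exclusion is the
exact mirror of the inner one. Without it, the fit over the full range is
occasionally captured by a heavy-tail mode (D̂ near the box edge) driven
entirely by out-of-range steps; with it, 20-seed recovery of D = 1.585 at
n = 500 steps sits within ±0.3 on every seed tested, matching the
precision claimed for individual-level estimates, with median D̂ ≈ 1.53
(a small downward bias from residual finite-size effects).

**What the generator does not emulate.** No speeds, pauses or
continuous-time dynamics; no homing or looping drive, so a walker does
not revisit the release point the way a searching ant does; no visual
panorama cues; headings after a turn are fully isotropic rather than
forward-biased. Passing tests therefore validate the encounter mechanism
and the estimation machinery, not the full behavioural repertoire of a
searching ant.

## Problem sizes and numerical checks

Simulator validation uses 10⁴-step walks for the mean-free-path and
survival comparisons (sup-norm over [δ, 20δ]), 20 replicate fields for
dimension recovery at n = 500 steps, and pooled conditions of 12
independent 40-step walkers for model selection — pooling per condition
before fitting mirrors the study design, and matters because on a single
very long walk the AICc penalty becomes negligible and flexible families
absorb realization-level quirks that are shape-equivalent to the truth.
Small-sample fits are cross-checked against exhaustive (λ, D) grid
searches; normalization against closed forms and high-resolution Riemann
sums; the hazard construction against a direct Monte-Carlo of the
sequential-interval product; and the sign test against an independent
library implementation.

## Known limitations

* The bundled published summary table reproduces printed values; a few of
  its printed pairwise weights are not internally consistent with the
  printed log-likelihoods under any standard AIC/AICc convention (the
  rows that are consistent recompute exactly), so summary counts based on
  printed versus recomputed weights can differ by one or two individuals.
* Raw step-length data for the published re-analyses are not
  redistributed; the pooled-fit path accepts such data as CSV/XLSX when
  available but is exercised here on synthetic input only.
* Dimension recovery interpolates D only in [1.585, 2] (the 3-or-4
  retention construction); recovery below 1.585 would need a different
  generator.
* The box-counting estimator expects a few hundred points and at least
  four usable dyadic scale octaves; it aligns boxes to the arena when the
  domain is supplied (exact for grid-constructed fractals) and to the
  bounding square otherwise.
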
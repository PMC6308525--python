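# Methods

## Problem setting

A camera-guided variable-rate sprayer for row crops needs three computations
per frame: (i) separate vegetation from soil in an 8-bit grayscale image,
(ii) locate the inter-row gaps and measure how much vegetation — by
definition weed — each gap holds, and (iii) translate each gap's weed
intensity into a nozzle combination and a per-hectare application rate.
`weedvision` implements those three stages plus a synthetic scene generator
that supplies ground truth, so every stage can be scored without field
imagery.

## Threshold segmentation

All three searchers maximize Otsu's between-class variance
σ²(t) = ω₀ω₁(μ₀ − μ₁)² over the gray-level histogram, where ω₀, ω₁ are the
probability masses and μ₀, μ₁ the mean grays of the classes {gray ≤ t} and
{gray > t}. The inclusive/strict split at t, and the tie rule "smallest
threshold among equal-fitness candidates", are fixed package-wide.
σ²(t) for all t is computed in one pass from cumulative sums of the raw
integer counts (partial sums stay exact, so empty-class thresholds give
exactly zero variance); an independent two-pass definitional computation
backs it in the tests.

- **Exhaustive Otsu** evaluates all 256 levels; it is the reference every
  other method is scored against.
- **Standard PSO** runs `swarm_size` (default 15) particles over the full
  occupied range [I_min, I_max] with the usual velocity update
  v ← w·v + c₁r₁(p_best − x) + c₂r₂(g_best − x), learning factors
  c₁ = c₂ = 2, inertia w decaying linearly 0.8 → 0.4 across the (default 30)
  iterations, velocity clamped to half the range width, positions clipped to
  the range. Positions are continuous; fitness is evaluated at the rounded
  integer level.
- **IPSO** first contracts the search range: the image mean μ_L splits the
  occupied histogram into a low and a high region, and the gray-weighted
  means μ_A, μ_B of those regions become the bounds. The swarm is resized to
  G_f = max(5, round(G_s·(μ_B − μ_A)/255)) and run inside [μ_A, μ_B]; after
  it stops, every integer threshold within ±P (default P = 2) of the swarm
  best is scanned exhaustively and the best kept.

**Termination.** Both swarm searches stop at `max_iter` or once the global
best has not improved within a patience budget of `stall_iter × swarm_size`
fitness evaluations (default 150). Expressing patience in evaluations
rather than iterations makes the comparison fair across swarm sizes: the
15-particle standard PSO typically stops after ~15 iterations, while the
contracted 5–7-particle IPSO swarm spends the same budget over ~28
iterations and then lets the ±P refinement absorb any residual offset.
This is what makes early stopping safe for IPSO and is the mechanism behind
its higher exact-agreement rate.

**Tie plateaus.** Bimodal field histograms usually contain a run of empty
bins between the soil and vegetation modes. Every threshold inside such a
run yields bit-identical σ² and the identical binary mask. The IPSO
refinement therefore slides to the smallest member of an exactly-tied run —
the canonical representative under the package tie rule, and the same
threshold the exhaustive scan reports. Without this, cross-method threshold
comparisons would differ by tie resolution alone.

**Evaluation statistics.** For a set of N images, a method's optimization
rate is p = n/N × 100 with n the number of images where its threshold
equals the exhaustive-Otsu threshold exactly, and its error rate is
σ = sqrt(Σ(T_i − TU_i)²/N). `compare_methods` gives each (image, method)
run its own child RNG stream, so per-method results do not depend on which
other methods run alongside.

## Inter-row weed mapping

The binary mask's lateral histogram y_j counts foreground pixels per column.
Crop rows appear as peaks; maximal runs of columns with
y_j ≤ fraction × max(y) (default fraction 1/3, configurable) are the
inter-row intervals. Runs touching the image border are kept — an edge gap
is a real spray target. An all-zero profile returns the whole image as a
single interval flagged `no_vegetation`. No smoothing is applied to y.

Each interval's weed fraction is p(n) = (Σ y over the interval) / (M·N),
i.e. relative to the whole image, and is classified into six intensity
levels (no / few / moderate / many / severe / very severe weeds) as the
number of breakpoints strictly below p. The default breakpoints
(2, 5, 10, 15, 20)% are a design default spanning the per-image weed
percentages reported for real seedling-stage corn fields (13–19%); p = 0 is
always level 0 and the level is monotone in p.

## Spray decisions

Three nozzles of increasing orifice size give seven nominal modes; mode 4
(nozzles 1+2) duplicates mode 3's flow and carries no measured data, so six
working modes remain. Mode 6 is nozzles 2+3 (the published mode list
repeats "nozzle 1" here — a typo; 2+3 is the only unused pair and the only
reading consistent with the monotone flow ordering). The default
level→mode map (0→off, 1→mode 1, 2→mode 2, 3→mode 3, 4→mode 5, 5→mode 7)
makes total flow increase monotonically with weed intensity; it is fully
configurable, as is the line pressure (default 300 kPa, one of the five
tabulated pressures).

The application rate is the standard boom-sprayer formula
R = 60000·Q/(V·W) [L/hm²] with Q the mode's flow (L/min), V the ground
speed (m/s) and W the nozzle spacing (cm). The bundled flow tables
(manufacturer-rated and flow-meter-measured, five pressures × modes) were
recorded at V = 2.5 m/s; W = 100 cm is the unique spacing consistent with
the published per-hectare rates and is verified by a consistency test.
The measured mode-1 flow at 200 kPa reads 0.00 L/min (below the flow
meter's detection limit) and the measured mode-1 flow at 300 kPa sits
10.3% below its rated value; all other measured/rated deviations are
within 10%.

## Synthetic scenes

`generate_scene` emulates a top-down view of seedling-stage row crops:
vertical crop rows (chains of jittered disks, near-full column height) over
soil, weeds as clustered disks confined to the inter-row gaps, vegetation
brighter than soil by default. Gray levels are Gaussian per class
(defaults: soil 40, vegetation 160, sd 12 — the same statistics as the
histogram benchmark), with optional linear illumination gradient and
additive noise. Weed placement is exact: each gap receives precisely
`round(fraction × M·N)` weed pixels (the last disk is trimmed pixel-wise),
so ground truth equals the request up to rounding. Weed columns are capped
at 0.3 × height so clumps never exceed the 1/3 lateral-histogram cutoff —
weed patches are low clumps, not row-spanning strips; `max_gap_fractions`
reports the per-gap feasibility ceiling (~3.4% of the image for a default
border gap, ~6.7% for an inner gap). Default scene size is 240 × 320 with
3 rows and per-gap fraction 0.03.

What the generator does **not** emulate: plant morphology and leaf texture,
perspective and lens distortion, shadows, specular soil, motion blur, and
weeds growing inside crop rows. Consequently, passing the recovery tests
shows the mapping pipeline is correct when classes are separable and rows
are vertical; it does not certify segmentation accuracy on real field
imagery.

`generate_histogram` skips rendering and draws the gray-level mixture
directly (exact pixel total), which is what the 100-image optimizer
benchmark uses: means 40/160, sd 12, vegetation fraction uniform in
[0.1, 0.3], 10⁵ pixels per image. At these settings the exhaustive-Otsu
reference threshold lands between the class modes and IPSO reproduces it
on 98–100 of 100 images (PSO: 91–97) for every master seed we tried.

## Numerical and design choices

- Degenerate images (a single occupied gray level) raise an error from all
  searchers; thresholding such an image is meaningless.
- `max_iter = 0` is allowed and returns the best initial particle.
- Benchmark problem sizes (100 histograms of 10⁵ pixels; 50 scenes of
  240 × 320) were chosen as the package's standard desk-scale protocol;
  all statistics are reproducible bit-exactly from a single integer seed
  via `numpy` `SeedSequence` spawning.
- The actuation threshold of the pipeline is weed level ≥ 1 in an interval;
  weed-free images therefore produce no actuation messages.
- Multi-channel image inputs are averaged to gray with a logged warning
  rather than rejected.

## Known limitations

- The intensity breakpoints and the level→mode map are operational choices,
  not field-calibrated values; real deployments should tune both.
- Interval extraction assumes rows roughly parallel to image columns (a
  transpose flag covers horizontal rows); skewed or curved rows need
  upstream rectification.
- Under a strong illumination gradient a single global threshold
  misclassifies image edges; the generator can produce such scenes, but the
  pipeline makes no attempt at adaptive/local thresholding.
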
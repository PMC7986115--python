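# Methods

## Segmented response model and estimator

Both response curves (water use vs fraction of transpirable soil water,
transpiration rate vs vapour pressure deficit) use one continuous
two-segment model with parameters (intercept1, slope1, X0, slope2):
segment 1 applies for X < X0, segment 2 starts from the segment-1 value at
X0, so the curve is continuous by construction. For soil-drying curves
segment 1 is the water-limited decline after stomatal closure and X0 is
WU_bp; for demand curves X0 is TR_bp, the threshold of the
limited-transpiration trait.

Conditional on X0 the model is linear in the other three parameters via the
reparameterisation Y = b0 + b1·min(X, X0) + b2·max(X − X0, 0). The
estimator therefore profiles the residual sum of squares over a dense X0
grid (400 candidates by default), solving ordinary least squares at each
candidate, then refines the grid argmin by bounded scalar minimisation
(absolute tolerance 1e-10 of the search span). Default search bounds are
[2nd smallest X, 2nd largest X] shrunk by a 1e-6 relative margin, so every
candidate keeps at least two points per segment. A breakpoint landing at a
search bound is flagged (`x0_pinned`) — with noisy, weakly kinked data the
global minimiser can park there, and such fits should not be interpreted as
evidence of a breakpoint. R² is 1 − SSE/SST (defined as 1 for an exact fit
to constant data), and the residual SD uses n − 4 degrees of freedom.
Breakpoint confidence intervals come from a seeded case-resampling
bootstrap (percentile method, 1000 draws by default); resamples with fewer
than five distinct X values are redrawn.

Fits can be pooled (all plants of an accession in one dataset, the default
used by the panel pipeline) or run per plant and averaged; pooling is the
default because per-plant drydowns contribute few points near the
breakpoint.

**Known limitation — small-sample skew.** The global least-squares
breakpoint estimator is consistent but skewed in small samples when the
slope change is weak relative to noise: replicates in which noise masks the
kink place the SSE argmin far from the true breakpoint (or at a search
bound). The replicate recovery experiments (`run_recovery_experiment`)
quantify this directly: with 30 points and noise at 10% of the response
range, parameter sets with a strong slope change recover the breakpoint
essentially without bias, while sets whose second segment is short or
weakly contrasted show mean absolute biases up to ~0.2 kPa with
root-mean-square errors of ~0.5–0.6 kPa. Medians are materially less biased
than means; users comparing genotypes should inspect the bootstrap CIs and
the pinned-fit diagnostics rather than relying on point estimates alone.

## VPD and transpiration rate

Saturation vapour pressure uses the Tetens formulation
es(T) = 0.61078·exp(17.27·T/(T + 237.3)) kPa; VPD = es(T)·(1 − RH/100),
with RH required in (0, 100]. Per chamber step, TR = mass loss (g → mg) /
leaf area (m²) / duration (s), giving mg H₂O m⁻² s⁻¹; the step's X value is
the VPD recomputed from its mean temperature and humidity. Steps showing
mass gain beyond tolerance are flagged, not dropped. Leaf area for
normalization is one-sided (the projected-area convention), from the
grass-leaf allometry area = length × width × 0.858 summed over leaves.

## Gravimetric accounting

Pots are weighed twice daily; records before 12:00 are morning weighings,
after 12:00 evening weighings (the simulator emits 05:00 and 20:00, inside
the platform's ~4:30–6:00 and ~19:30–21:00 windows). For each date,
WU_day = morning − evening weight − mean soil-only daytime loss, and
WU_night = evening − next-morning weight − mean soil-only nighttime loss.
Well-watered refills are reconstructed as refill-to-target: the recorded
evening weight is pre-refill, the night window starts from the target
weight (default 3750 g), and water added = target − recorded weight. Dates
missing a paired record are skipped and logged. By construction, day plus
night water use plus soil evaporation telescopes exactly to the weight drop
over any rewatering-free interval.

The drydown endpoint is the first date whose soil-corrected daily water use
falls to a configurable fraction (default 0.10) of the control reference
(mean daily water use of well-watered plants of the same accession); the
morning weight that date is WTf, TTSW = weight at 100% available water −
WTf, and FTSW = (WTn − WTf)/TTSW. FTSW is clipped to [0, 1] for fitting
while raw values are retained for QC. Because the threshold triggers at a
small positive transpiration (and soil evaporation continues), per-plant
WTf estimates jitter by a few days' worth of weight; the panel pipeline
therefore averages the per-plant endpoint weights of an accession into one
WTf before normalizing (pots share substrate mass and refill target), which
removes per-plant rescaling of the FTSW axis. Recovery after re-watering is
100 × WU on recovery day 6 / mean pre-stress WU (the literal day-6 reading;
a window-mean alternative is available via `mode="mean"`).

## Imaging

Plant pixels are classified on 8-bit channels as green tissue
(2G − R − B > τ, default τ = 20, and G > R) or senescent tissue
(R + G − 2B > 120); the plant foreground is their union, optionally cleaned
of connected specks below a configurable area (off by default so counts on
clean renders are exact). Projected leaf area is the green-pixel count of
the side view with the greatest green area, over any subset of the
platform's seven angles (0–90° in 15° steps). "Area decile by height" is
read as ten bins of equal pixel count ordered from the image bottom upward
(sizes differ by at most one pixel) — equal-count bins, not equal-height
slabs, because the quantity binned is area. The green:red ratio per bin is
mean(G)/mean(R); the per-plant summary is the mean over the ten deciles,
and senescence of a stressed plant is 100 × (1 − GR_WS/GR_WW), floored at
0, against the well-watered reference of the same accession and day. Under
this reading 0% means as green as the control and values approach 100% as
the canopy yellows completely. Destructive validation regresses harvested
leaf area on PLA by ordinary least squares and reports slope, intercept
and r².

## Synthetic-data generator

The generator emulates the study conditions and records full ground truth:

* **Drydown** (`simulate_drydown`): daily plant water loss is the segmented
  response at the morning FTSW plus additive Gaussian noise (the response
  is treated as homoscedastic; no noise model is imposed beyond that),
  split 0.875/0.125 between the 14-h day and 10-h night (day:night water
  use ratios near 7:1 are typical for these grasses). Soil evaporation
  (defaults 6 g day, 2 g night, a few permille of pot weight) draws on a
  separate non-transpirable surface store, so the transpirable pool (TTSW,
  default 2500 g in a 3750 g pot) is depleted by plant water loss only and
  integrated plant loss over a complete drydown equals TTSW exactly in the
  noiseless limit. Well-watered pots are refilled to target at each evening
  record. One RNG per scenario makes every fixture bit-reproducible.
* **VPD steps** (`simulate_vpd_steps`): sequential 60-min steps after
  30-min equilibration at a fixed chamber temperature (default 30 °C);
  emitted temperature/RH pairs invert the Tetens formula so recomputed VPD
  round-trips the target levels exactly. Default levels 1, 1.5, 2.5 and
  3.5 kPa.
* **Plant renders** (`render_plant_image`): a stem-plus-leaves skeleton is
  thickened by keeping exactly the requested number of pixels nearest the
  skeleton (ties broken deterministically), so foreground counts are exact
  by construction; apparent leaf length varies with view angle. Senescence
  recolours the lowest requested fraction of foreground pixels by height
  from green-dominant to yellow/red-dominant — basal-first, the botanical
  norm. The renderer is deliberately schematic: no lighting, occlusion,
  soil, pot or colour-calibration effects, so passing imaging tests
  demonstrates correctness of the measurement code on unambiguous colours,
  not segmentation robustness on photographs.
* **Default panel** (`default_panel`): 12 accessions spanning breakpoints
  FTSW 0.25–0.58 and plateau water use 220–320 g day⁻¹ (so the 2500 g pool
  is exhausted within the 20-day window), residual water use 5 g day⁻¹ at
  FTSW 0, plateau slope 10 g day⁻¹ per FTSW unit, noise SD 8 g day⁻¹, with
  6 plants per watering arm and 25 soil-only pots.

What the generator does **not** emulate: weather-driven day-to-day demand
variation, plant growth feedback on water use during the experiment,
heteroscedastic weighing error, substrate hydraulic dynamics, or realistic
canopy optics. Recovery of truth from these simulations validates the
estimators' correctness and numerical behaviour, not their robustness to
every field artefact.

## Numerical choices and problem sizes

Replicate experiments spawn per-replicate RNG streams from one seed, so
extending the replicate count preserves earlier replicates; recovery
experiments in the tests and the acceptance script use 200 replicates of
30-point datasets, the brute-force optimizer check uses 50 random 12-point
datasets against an exhaustive 1e-4-step breakpoint grid, and the
end-to-end panel uses the default 12 × 6 × 2 × 20-day configuration —
sizes chosen so the whole suite re-runs in well under the scale of the
original experiments while keeping Monte Carlo error on reported summaries
small. Degenerate inputs (constant X, fewer than five points, empty
measurement lists, non-positive TTSW, saturated humidity) raise errors
rather than returning silently; ties in pixel ordering and in the
breakpoint grid are broken deterministically.
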
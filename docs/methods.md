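# Methods

This note documents the models and conventions behind `traitscreen`: what
each stage computes, the defaults and why, what the synthetic data emulate
and where their fidelity stops.

## 1. Parameter space

A parameter is a scalar or a *function parameter* — paired x/y vectors
interpreted piecewise-linearly, where x tracks a driving state (development
stage, temperature, a stress ratio) and y the trait response. The packaged
inventory (`data/hartog_registry.csv`) holds 103 entries (62 scalars, 41
curves) for the reference cultivar Hartog. Twenty entries are *active*: the
surrogate simulator consumes them, so their screening signal reflects real
causal pathways. The other 83 are inert placeholders representing the long
tail of constants a full crop model exposes; they are screened identically
and act as negative controls — any non-zero μ\* on them would reveal a
bookkeeping bug. Placeholder names follow crop-model conventions; their
nominal values are synthetic and carry no field meaning.

Seven meta-parameters tie together 20 placeholder entries that could not
vary independently without producing aberrant inputs (minimum/critical/
maximum N-concentration curves, leaf-expansion geometry, root advance,
temperature–senescence response, frost thresholds). A meta-parameter is one
Morris factor whose level drives every member through its own range, giving
103 − 20 + 7 = 90 independent factors.

**Range rule.** Every factor spans a band of total width 40% of its nominal
magnitude: `[0.8n, 1.2n]` symmetric by default; if that band crosses a
declared hard bound, the full width moves to the feasible side
(`[0.6n, n]` or `[n, 1.4n]`), clipped to the bounds. A zero nominal cannot
be scaled multiplicatively and yields a zero-width "fixed" range excluded
from the factor set. Normalized levels in [0, 1] map linearly onto the
band, so level 0.5 recovers the nominal for symmetric ranges.

**Curve scaling.** Full-curve mode multiplies every y entry by a factor
interpolated across the multiplier band (0.8–1.2 symmetric). Point mode
rescales one designated x- or y-entry — used where perturbing a single
threshold is the biologically meaningful variation (e.g. the leaf-expansion
water-deficit threshold, or the elevated-CO₂ end of the
transpiration-efficiency response). An x-perturbation that would break the
strict ordering of the x vector is rejected with the parameter named,
rather than silently re-sorted: a re-sort would change which physiological
regime each segment describes.

## 2. Morris screening

Factors are discretized to n = 6 grid levels on [0, 1] and the step is
Δ = n/(2(n−1)) = 0.6, the standard choice for even level counts. A
trajectory starts from a random grid point (restricted so all moves stay in
[0, 1]) and moves each factor exactly once, in random order and random
direction, by ±Δ — g+1 points for g factors. When a candidate pool larger
than r is requested, the kept subset greedily maximizes summed pairwise
trajectory distance (sum over all point pairs of Euclidean distance), a
space-filling selection; the pool size trades spread against memory and
time in the O(pool²) distance matrix. By default the pool equals r (no
selection).

Elementary effects divide the output difference across a step by the
*signed normalized* step, so μ\* carries output units per full normalized
range — for yield, t/ha per full trait band. σ is the sample (ddof = 1)
standard deviation of the signed effects. Outputs missing for a row (failed
simulation) propagate to missing effects with a warning; μ\*/σ are computed
over the available effects and the per-factor count is recorded. For
cross-environment comparisons a standardized variant z-scores the outputs
within each environment before computing effects; a constant output
standardizes to zeros (its indices are genuinely zero), and an environment
with a single genotype is an error.

## 3. Crop surrogate

A deliberately simplified daily model preserving the causal roles of the
screened traits; equation forms are the standard ones of the APSIM lineage.
It is a *screening* surrogate: outputs are plausible in magnitude
(1–4 t/ha yields, 10–13% protein at the packaged sites) but not calibrated
to any dataset, so screening results are qualitatively, not quantitatively,
comparable to a full crop model.

- **Thermal time**: trapezoid over cardinal temperatures 0/26/34 °C
  evaluated at the daily mean (°Cd/day).
- **Phenology**: phases sowing → emergence (150 °Cd) → floral initiation
  (`tt_end_of_juvenile`, 555 °Cd) → flowering (`tt_floral_initiation`,
  400 °Cd) → grain-fill start (120 °Cd) → maturity (545 °Cd of fill).
  Pre-flowering thermal time is multiplied by a photoperiod factor
  `1 − 0.002·photop_sens·(20 − daylength)²` (clamped to [0, 1]) and, before
  floral initiation, by a vernalization factor that relaxes to 1 as ~50
  cool-day units accumulate, with `vern_sens` scaling the initial delay.
- **Water**: four-layer bucket; rain infiltrates top-down with drainage
  above the drained upper limit; soil evaporation from the top layer
  declines with canopy cover. Supply = Σ kl·(SW − LL_eff) over rooted
  layers; `ll_modifier` > 1 lowers the effective lower limit by up to half
  the layer's available range, emulating greater root extractability.
  Demand converts the day's potential (radiation-limited) growth through
  transpiration efficiency `1000·transp_eff_cf·f_CO2,TE / VPD` (g m⁻² per
  mm), with VPD = 0.75·(svp(tmax) − svp(tmin)), floored at 0.1 kPa. Daily
  growth is potential growth × min(1, supply/demand) — exactly the minimum
  of RUE-limited and TE-limited growth. The seasonal water-stress index is
  1 − mean(supply/demand ratio) from emergence to maturity.
- **Nitrogen**: one soil mineral pool fed by initial N, scheduled doses
  (with the rainfall/PAW decision rules evaluated at the phenological
  trigger dates) and a small background mineralization; uptake is capped by
  demand, pool size and soil moisture. The photosynthesis factor f_N ramps
  from 0 at half the critical concentration to 1 at critical; the N-stress
  index is 1 − mean(f_N).
- **Canopy**: interception 1 − exp(−k·LAI); leaf share of new biomass
  converts to LAI through SLA, with expansion reduced below the
  `x_sw_demand_ratio` threshold; senescence removes green area (faster with
  age and water stress) but not biomass — dead matter stays in the standing
  crop, which keeps the carbon audit exact (biomass ≡ cumulative gain).
- **Grain**: number fixed at flowering as `grains_per_gram_stem` × stem
  mass; daily fill = min(potential rate × number × °Cd × temperature
  factor, assimilate + stem reserve, remaining capacity to
  `max_grain_size`); a quarter of flowering stem mass is remobilizable.
  Grain N fills from crop N with its own temperature response; protein % =
  5.7 × grain N / grain mass. Yield ≡ number × size by construction.

Failure (no maturity within the weather record) returns zero yield with a
flag; within the screen such rows become missing elementary effects.

## 4. Synthetic environments

The generator targets *first-order* climate statistics of the four
archetypes: long-run annual and May–November rainfall means, the declared
seasonality class, mean temperature and radiation. Rainfall is a Bernoulli
wet-day chain (base probability 0.30) modulated by a single seasonal
harmonic whose amplitude is solved so the May–November share matches the
archetype, with gamma amounts (shape 0.75) whose mean compensates the
occurrence probability — the expected daily depth follows the harmonic
exactly, so the long-run annual mean is unbiased. Temperature and
radiation are single sinusoids (southern-hemisphere phase, January maxima;
amplitudes 6.5 °C and 38%) plus Gaussian noise; the diurnal half-range is
6 ± 1 °C floored at 0.5, which enforces tmin ≤ tmax. Years are synthetic
365-day years, independent and identically distributed: no interannual
autocorrelation, ENSO structure, heat waves or frost events. Soil water and
mineral N reset at sowing each year (annual reset, not a continuous
rotation). Passing screens therefore demonstrate method correctness and
qualitative trait × environment structure, not performance under real
weather sequences.

Soils are four layers (300/300/450/450 mm) whose available-water shares
(30/30/25/15%) sum to the archetype PAWC, with extraction coefficients
decreasing with depth (0.07/0.05/0.035/0.02 d⁻¹) and initial water filled
top-down to the archetype's sowing value. Management encodes each site's
split N doses with their decision rules (Yanco: tillering dose only if
cumulative rain since sowing > 100 mm, elongation dose only if PAW > 60% of
PAWC; Merredin: elongation dose only if PAW > 60 mm); the low N level
halves every dose, the high level adds 50 kg/ha at sowing.

## 5. Impact analysis

- **Classification**: null ⇔ μ\* = 0 in every environment (tolerance
  1e-12); low ⇔ mean μ\* ≤ 0.02 t/ha (boundary inclusive); impactful
  otherwise.
- **Clustering**: Ward linkage on per-output z-scored mean impacts;
  deterministic; default cut k = 3, configurable (k = 4 is the natural
  choice when clustering η² profiles instead). Dendrogram exported as
  Newick text.
- **η² decomposition**: additive fixed-effects model with no interactions
  on a balanced grid, where marginal and sequential sums of squares
  coincide, so η²_e = SS_e/TSS is order-free (asserted against a
  sequential-ANOVA cross-check in the tests). Year and all interactions
  pool into the residual share; shares + residual ≡ 1. A constant impact
  vector (TSS = 0) is returned as all-zero with a degenerate flag rather
  than 0/0. Unbalanced grids are rejected.
- **Drought environment types**: rule-based on mean water deficit in the
  vegetative (emergence→flowering) and grain-fill (flowering→maturity)
  windows. Defaults: both < 0.2 → ET1 (low); both ≥ 0.5 → ET4 (severe);
  otherwise ET2 (mild-late) when the grain-fill window is at least as
  stressed as the vegetative one, else ET3 (mild-early). The cutoffs are a
  configurable surrogate for the reference drought typology, which is
  defined on full stress trajectories.
- **Stress regressions**: ordinary least squares of standardized yield μ\*
  on the baseline (reference-genotype) seasonal stress index, fitted per
  environment type; types with fewer than 3 environments or a constant
  stress index are rejected.

## 6. Pipeline, seeds, problem sizes

All randomness derives from one master seed through fixed-key
`SeedSequence` children (design; weather per site), so a re-run is
bit-identical; stage outputs are cached by configuration hash with
checksums, and a corrupted file is detected and recomputed. Execution is
serial; the `--jobs` flag is accepted for interface stability and results
are by construction independent of it.

The `paper` preset carries the full study geometry (90 factors, r = 100,
4 sites × 125 years × 3 sowings × 3 N × 2 CO₂ → 81.9 M simulations) and is
intended for dry-run planning or cluster execution. The `desk` preset is
the package's own reduced standard: 20 factors (16 active traits + 4 inert
controls), r = 20, and 40 environments (Merredin + Yanco × 5 years × 15 May
sowing × {low, TPE} N × {380, 555} ppm), i.e. 16 800 season runs in a few
minutes on one CPU. The two desk sites were chosen to span the water axis
(shallow dry vs deep moderate profile) and both CO₂ levels are retained so
the CO₂-response trait's environment interaction is observable.

## Known limitations

- The surrogate omits frost/heat shock, tillering, phosphorus, pests, and
  mechanistic N remobilisation; grain protein comes from a single-pool
  bookkeeping model.
- Placeholder parameters are inert by design; their null classification
  validates the pipeline, not crop physiology.
- The weather generator's i.i.d. years understate the persistence of real
  droughts; η² residuals (which absorb the year factor) are therefore not
  comparable in magnitude to results driven by historical records.
- Morris indices rank influence; they are not variance-based (Sobol')
  indices and carry no confidence intervals here.
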
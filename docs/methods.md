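# Methods

## Model structure and assumptions

`beefdam` is a one-compartment toxicokinetic model evaluated on a daily
grid (integer ages, day 0 = birth).  Its assumptions, inherited from the
spreadsheet lineage of such models:

* **Complete absorption.** 100% of ingested PFOS enters the body
  (`absorption_fraction`, adjustable in `TransferParams`).
* **First-order elimination.** A single whole-body half-life governs
  loss; the daily eliminated mass is `A·(1 − 2^(−1/T½))`.
* **Instantaneous redistribution.** Tissue concentrations are algebraic
  functions of the current burden (muscle:body ratio, muscle mass
  fraction, muscle:serum ratio).  After an abrupt change in exposure the
  real animal re-equilibrates over days; the model does not, so
  predictions in the first days after a sharp feed change are biased.
* **No dam kinetics.** The milk pathway maps the dam's *current* daily
  intake to a fluid-milk concentration through a constant transfer factor
  (0.0213 d/kg); her own accumulation history is not tracked.
* **Clean start.** The initial body burden defaults to zero (no
  placental transfer), but is a scenario input.

Within a day the default bookkeeping adds intake first and then applies
elimination to the post-intake burden (`update_order="intake_first"`).
The alternative ordering (`"eliminate_first"`) is exposed because the
day-level discretisation makes the choice a genuine convention; the
difference is one elimination factor (~0.6%) on the final day's intake.
The intake-first default reproduces the published generic-model output
(0.507 vs 0.501 µg/kg at the 0.270 µg/kg ration) slightly better than the
alternative (0.510) and is frozen.

States are recorded end-of-day; the slaughter-day concentration is the
last row of a scenario covering days 0..slaughter inclusive.

## Parameters (defaults in `ParameterProfile`)

| Parameter | Default | Units | Notes |
| --- | --- | --- | --- |
| Half-life `T½` | 108.9 ± 40.5 | days | pooled weight of evidence (below) |
| Muscle:body PFOS ratio | 0.231 ± 0.090 | – | share of burden in muscle |
| Muscle mass fraction | 0.361 ± 0.117 | kg/kg BW | relative muscle weight |
| Muscle:serum ratio | 0.080 ± 0.016 | – | muscle conc = 0.080 × serum conc |
| Birth weight | 35.45 ± 3.27 | kg | all-breed average |
| Daily gain | quartic derivative, ×0.35 rel. SD | kg/day | 0.32 ± 0.112 after day 540 |
| Forage DMI | 5.4702·ln(d) − 22.889, 0 before day 66 | kg DM/day | SD = 0.0013 × BW |
| Cow DMI | −10⁻⁴d² + 0.0196d + 11.697, ×0.062 | kg DM/day | d = calf age |
| Milk production | quartic, 1.445 at birth, ×0.355 | kg fluid/day | 0 from weaning (day 240) |
| Milk dry matter | 0.13 | – | fluid→DM conversion |
| Milk transfer factor | 0.0213 | d/kg | dam intake → milk conc |
| Soil intake | 2.43% ± 0.5% of DMI_F | kg/day | grazing ingestion |
| Water: calf / finisher / cow | 4×DMI_F / 40.84 ± 12.87 / 56.47 ± 8.16 | L/day | temperature-averaged |

The serum direction deserves a note: the 0.080 ratio is read as
muscle conc = 0.080 × serum conc, i.e. serum ≈ 12.5 × muscle, consistent
with PFOS partitioning strongly to serum albumin.

The energy-balance derivation of the nursing calf's forage intake
(`calf_forage_dmi_energy`: DMI_F = (DEI·BW − DE_M·DMI_M)/DE_F with
DEI = 0.0783 Mcal/kg BW/day, DE_M = 4.87, DE_F = 2.27 Mcal/kg) is
implemented as documentation of where the birth-to-slaughter intake curve
comes from, but the operative rule in the simulator is the fitted
logarithmic curve with its hard zero before day 66.  The two disagree for
ages ~30–66 days (the energy balance implies a small positive forage
intake there); the zero-before-66 rule is kept because it is the rule the
parameter table states, and the exposure consequence is small because the
milk route dominates that window.

### Half-life weight of evidence

Six literature half-life values are weighted by four categorical
relevance factors (exposure pattern, ingestion type, tissue, duration;
1 or 3 each), divided by a per-study divisor, and each row contributes
100 × its total weight draws from Normal(µ, σ) — 4200 points in all; rows
without a reported SD default to 20% of the value.  Negative draws are
rejected (a half-life is positive).  Per-row substreams are keyed on the
row's identity, so reordering the evidence table leaves the pool
unchanged.  The direct weighted mean is 108.66 days; the sampled pool
summarises to ≈108.9 ± 40.5 days.

## Monte Carlo design

Parameters are sampled from normal distributions truncated at their
5th/95th percentiles (implemented by inverse-CDF sampling of the central
band, so bounds hold exactly).  Sampling scope follows the parameter's
nature:

* **per iteration** (animal constants): birth weight, muscle:body ratio,
  muscle mass fraction, muscle:serum ratio;
* **per day** (rates, mirroring the row-wise structure of the daily
  model): half-life, daily gain, forage/cow DMI, milk production, soil
  fraction, water intakes, and optionally the feed concentration itself.

Within-field feed variation (`forage_cv`, typically 0.40) multiplies the
scheduled forage concentration by a truncated-normal factor shared by the
calf's and the dam's ration.  Its scope is selectable: `per_day`
(independent day-to-day fluctuation), `per_segment` (one draw per
constant feeding period) or `per_iteration`.

The day loop is vectorised across iterations; 1000 iterations × 541 days
run in ~0.1 s, so the standard n = 1000 of the published analysis is also
the default problem size here.

### The regulatory configuration

Two readings of the published probabilistic analysis are runnable:

1. **Full distributions** (`vary_parameters=True`, per-day feed noise) —
   the default of `run_monte_carlo`, matching the described method, and
   the configuration used for sensitivity ranking.
2. **Feed variation only, per feeding period**
   (`REGULATORY_MC_CONFIG`: `vary_parameters=False`,
   `forage_noise_scope="per_segment"`, `forage_cv=0.40`).

Configuration 1 overpredicts the published 95th-percentile results by
~30% (p95 ≈ 0.65 vs 0.504 µg/kg at the 0.190 µg/kg ration; BAF95 ≈ 3.4
vs 2.64).  The likely reason is structural: drawing the muscle:body ratio
and the muscle mass fraction independently double-counts muscle-mass
variation — in a mass-balance world an animal with more muscle holds a
proportionally larger share of the burden at the *same* concentration, so
the two parameters are strongly positively correlated and their effects
on concentration largely cancel; treated as independent they dominate the
output spread.  Configuration 2, in which the only variation is the 40%
within-field feed variability applied per feeding period, reproduces the
published percentile pair within 8–9% (p95 ≈ 0.54; BAF95 ≈ 2.83) and is
therefore adopted as the package's canonical configuration for the
regulatory (95%-confidence) questions: `regulatory_ration_limit` defaults
to it, and the acceptance script uses it for the percentile quantities.
Correlated parameter draws, which would reconcile configuration 1, are
out of scope.

Sensitivity uses Spearman rank correlation between per-iteration draws
and the output, with per-day parameters represented by their
within-iteration mean draw (so their daily contributions are aggregated,
not rated row by row).  In the full-distribution run the muscle:body
ratio ranks first for both muscle and serum outputs; for serum, the
muscle mass fraction ranks second and the muscle:serum ratio third —
under independent sampling the mass fraction's larger relative SD (32%
vs 20%) necessarily outranks the serum ratio.

### Inverse solving

With zero initial burden the model is linear in all exposure
concentrations (a property the tests assert), so the deterministic
inverse is a single unit-ration simulation plus a division, verified by
re-simulation to 10⁻⁶ relative error.  The 95%-confidence inverse bisects
on the ration concentration with the same seed at every evaluation
(common random numbers), making the empirical 95th percentile an exactly
monotone — in fact linear — objective; non-convergence raises an explicit
error (CLI exit code 3).

## Synthetic feeding histories

`build_synthetic_history` emulates the structure of real case-study
feeding records: a lifetime split into a few seasonal feeding periods
with base concentrations drawn uniformly from a range, day-to-day
multiplicative noise at the within-field CV (default 0.40), and an
optional terminal depuration period on PFOS-free feed.  It reproduces the
*shape* of real histories (piecewise-constant segments, depuration), not
any particular farm's measured concentrations; water and soil stay clean
unless set explicitly.  Tests passing on these fixtures therefore
demonstrate that the scenario format can encode real feeding histories
and that the kinetics behave correctly over them — not that any specific
farm's residues are reproduced.

## Numerical choices, degenerate inputs

* Body weight integrates the gain polynomial by one-step-per-day
  summation (matching the day-per-row bookkeeping); it agrees with the
  closed-form growth quartic within 0.5% at every age to 540 days, which
  the tests assert.
* All intake curves floor at zero outside their fitted ranges (the
  lactation quartic goes negative past ~250 days; the log DMI curve below
  day 66).
* The water-intake class switches from nursing calf to finisher at
  weaning; the lactating-cow class applies to the dam only.
* Truncated draws that could still be unphysical after truncation
  (half-life, intakes, fractions) are clipped to small positive floors or
  [0, 1]; with the default SDs the 5th-percentile truncation already
  keeps every parameter physical.
* Zero-duration scenarios are rejected; a zero-SD distribution returns
  its mean exactly; `combine` on an empty evidence list is an error.
* Reported seeds drive `numpy.random.default_rng`; the same seed gives
  bit-identical results on any platform.

## Known limitations

* Single compartment: no liver/kidney/fat time courses, no redistribution
  lag after exposure shifts.
* PFOS only; precursors (which biotransform to PFOS in vivo) are not
  modelled, biasing predictions low where precursors co-occur.
* The dam is an intake-to-milk pipe; long-memory effects of her own
  burden on milk concentration are ignored.
* Growth and intake curves are breed-averaged; only SD multipliers
  express inter-breed variation.
* Parameter draws are independent; the muscle:body / muscle-mass
  correlation discussed above is the known consequence.
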
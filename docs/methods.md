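# Methods

## Model structure and assumptions

The simulator is individual-based but deliberately simple: a nest is a
well-mixed pool of individuals with age (days), sex and an age-group label.
Demographic rates are group-level constants; there is no density dependence,
no dispersal between nests, no litter structure and no individual energetics.
Consequently population growth is exponential within a season and the model
is meant for *relative* comparisons (treated vs. control, early vs. late
application) over a few years, not for long-horizon absolute forecasts.

Time advances in days. Months are fixed 30-day blocks counted from day 0;
block *b* maps to calendar month `(start_month + b) mod 12`, and the breeding
season is a set of calendar months. The daily event order is fixed: monthly
rate refresh (at block boundaries) → acute mortality → background+chronic
mortality → reproduction → aging. The order matters only at small population
sizes; it is documented here because any reordering changes individual
trajectories (not the distributions appreciably).

Stochasticity enters in exactly three places: binomial death counts per
group (then uniform victim selection), Poisson births per reproductive
female, and Bernoulli(sex-ratio) newborn sexes. Each (iteration, nest) pair
draws from its own substream seeded by `(base_seed + iteration,
crc32(nest_id))`, so results are bit-reproducible and adding a nest to a
scenario does not perturb the others. An unexposed nest inside a treated
scenario therefore reproduces the pesticide-free trajectory exactly.

## Rate conversions

Monthly mortality *m* is converted to a daily probability by geometric
compounding, `d = 1 − (1 − m)^(1/30)`, so that 30 daily steps recover the
monthly rate exactly in expectation. Monthly reproduction *r* (offspring per
reproductive female per month) becomes a per-female daily Poisson mean
`r/30`. Both are linear in expectation, so replicate means match the
deterministic matrix model used for calibration (below).

## Demographic parameters and calibration of the age thresholds

Default rates (rabbit: monthly mortality 0.77/0.38/0.11/0.11, reproduction
0/0/0/4, season December–May, 140 individuals; hare: 0.87/0.30/0.08/0.08,
0/0/0.6/1.75, January–August, 100) follow the published lagomorph case
study. The ages at which individuals move between the four groups are *not*
part of that parameter set, yet they control whether those rates produce a
growing, stable or collapsing population. We therefore calibrated the
thresholds once against a deterministic daily expectation model (exact for
replicate means, since all stochastic draws are linear in expectation),
choosing values that are biologically plausible for the species and make the
published rates near-stationary:

* rabbit: 0 / 20 / 75 / 105 days (nestling, juvenile, subadult, reproductive
  adult from ~3.5 months). Annual multiplier 1.000, seasonal amplitude ~2.9
  (peak at the end of the breeding season, close to a tripling of the
  season-start number).
* hare: 0 / 20 / 45 / 240 days; the "young" group is reproductive at the
  reduced rate. Annual multiplier ~0.98 (slow decline, consistent with a
  near-stable managed population).

The initial age distribution is likewise not a published quantity; fixtures
start at the stable-cycle distribution at season start. For the rabbit with a
December census this is all-adults (the youngest animals from a May birth are
already past 105 days), i.e. initial counts (0, 0, 0, 140); the hare fixture
starts (0, 0, 30, 70). All thresholds and distributions are ordinary
configuration and can be overridden per nest.

## Exposure model

The exposure chain is the generic structure of regulatory dietary
assessments: initial residue on a food item = RUD × application rate ×
zone deposition fraction; first-order dissipation `2^(−Δt/DT50)` with
superposition over applications; daily exposure `ETE_t = FIR/bw ×
Σ fraction_i × residue_i(t)`. All numeric inputs are configuration. The
bundled fixtures use non-normative placeholders (RUD 100 mg/kg per kg/ha,
DT50 10 d for glyphosate and 3 d for bromoxynil reflecting its rapid foliar
dissipation, FIR/bw 0.45 kg/kg bw/d, outer-band drift 3%, feeding radius
250 m) chosen only so the case-study patterns (sharp post-application
exposure peak, decay to ~0 within weeks for bromoxynil) appear; they carry
no regulatory standing and are labelled as placeholders in their provenance
notes. Fixture experiments use the worst-case diet (fraction 1.0 from the
treated field core), matching the screening-level maximum-exposure
assumption; the landscape diet mode (feeding-disc raster overlap × food
weights) is available for refined scenarios.

TWA windows are truncated at simulation start (mean over available days).
Because a *w*-day running mean extends *w−1* days past a pulse, an exposure
pulse ending within *w−1* days of a month boundary contributes to the next
month's maximum TWA as well; this is intended behaviour of the windowing,
not double-counting.

## Effects model

Acute lines pass through `(LD0/f0, 0)` and `(LD50/f50, 0.5)`; an absent LD0
is a zero threshold. Chronic/reproductive lines pass through the origin and
`(LOAEL/f, 0.25)`; the derivation also reports whether the implied effect at
the adjusted NOAEL falls inside the 5–10% linearity band. Evaluations are
clamped to [0, 1] — below at 0 as the source equations state, above at 1
because the outputs are rates. Printed coefficients are echoed with
round-half-up at the conventional precision (0.5/16 → 0.0313, not banker's
0.0312).

The combination rule is independent survival: accumulated mortality
`1 − (1 − bg) Π (1 − SR_x)` and reproduction `bg · Π (1 − RE_x)`. The
verbal definition accompanying the published mortality formula ("Subgroup SR
is 1 minus the background mortality rate") would, taken literally, multiply
mortalities and make higher background mortality *reduce* the accumulated
rate while contradicting the same paper's dose-response equations in which
the SR symbols are mortality rates (0.25 effect at the LOAEL). The
survival-product reading is the only internally consistent one and is what
this package implements.

Timing: chronic mortality for month *b* uses the maximum windowed TWA of
month *b−1*; reproduction uses the maximum over months *b−1* and *b−2*
(pregnancy lag plus in-utero exposure), with a single-month variant available
(`reproduction_lag_months=(1,)`). Acute mortality applies the same day from
the day's ETE with zero background acute mortality, and acute and chronic
terms for the same pesticide both enter the combination on days where they
overlap — they represent distinct processes and nothing in the source
contradicts independence. Where the reproduction span is "the two previous
months", we take the max of the two monthly maxima (identical to the max
over the union of days).

## Replication and summaries

`replicate` runs *n* iterations with seeds `base_seed + i` and reports the
per-day mean with a normal-approximation 95% interval (`mean ± 1.96·sd/√n`)
or a min/max envelope. The normal band is a description of between-replicate
spread, not a small-sample-exact interval; for n ≥ 50 the distinction is
immaterial at these population sizes.

## What the fixtures do and do not show

Passing the bundled experiments demonstrates: seasonal stability under the
default rabbit parameters (cycle-end abundance near the initial 140, peak
2–4×), replicability (independent 50-replicate runs agree within the
confidence band, with the largest variability at the seasonal peak),
monotone dose ordering of post-treatment abundance, stronger within-season
impact for early-season applications, and the exact one/two-month lag
schedule. They do **not** validate absolute abundance levels under real
exposure conditions — those depend on the regulatory exposure inputs that
are configuration here — nor density-dependent recovery, which the model
deliberately omits.

## Numerical and scope choices

* Disc–polygon overlap uses cell-center rasterization at resolution
  radius/100 by default (error O(resolution/radius), tested against analytic
  rectangle and half-plane geometries); polygon bands use mitred buffers so
  rectangular fields stay rectangular.
* Overlapping fields: a point belongs to the first field in declaration
  order.
* Ties and degenerate inputs: empty age groups, non-increasing thresholds,
  band widths that swallow a field, all-zero food weights, rates outside
  [0, 1] and windows < 1 day are configuration errors raised with explicit
  messages; scenario validation collects all violations before running.
* Problem sizes in the test suite (50 replicates × 1000 days for stability
  and replicability, 20 replicates for the dose-grid comparisons) were chosen
  as the smallest runs at which the replicate-mean properties are stable
  well beyond their assertion margins.
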
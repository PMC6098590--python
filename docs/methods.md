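# Methods

## The model

`oxyaccess` is a deterministic, discrete-time (weekly) system-dynamics
model of patient access to therapeutic oxytocin in Zanzibar. It couples
four sub-models:

1. **Degradation kinetics.** Injectable oxytocin (10 IU, pH 4.5) decays by
   first-order kinetics with an Arrhenius rate constant
   `k(T) = A exp(-Ea / (R T))`. A dose stored `t` days at temperature `T`
   retains `exp(-k(T) t)` of its labelled strength.
2. **Effective doses.** Weakened stock is discounted by banded
   multi-dosing: full credit at strength >= 85%, two vials per patient at
   54–85%, three at 33–54%, and a write-off below 33%. Band edges are
   half-open (`[0.85, 1]`, `[0.54, 0.85)`, `[0.33, 0.54)`, `[0, 0.33)`);
   the published band ranges overlap on 50–54% and the 54% edge is the only
   boundary pair that partitions [0, 1], so it is the one used. Divided
   stock is floored because vials are physical units.
3. **Demand.** `annual_births / 52` weekly births, a fraction `p` of which
   occur at facilities. Each facility birth needs one prophylactic dose,
   and the 2% of women who develop postpartum hemorrhage need four more, so
   expected demand is `1.08` doses per facility birth. Demand is an
   expected value, constant across weeks — no microsimulation of
   individual deliveries.
4. **Inventory.** The annual order arrives in equally sized, equally
   spaced shipments (semiannual by default: weeks 0 and 26). Each week a
   shipment arrives (if due), all cohorts decay for 7 days at that week's
   storage temperature, effective doses are counted, and demand (rounded
   up to whole patients) is served FIFO — each patient's 1/2/3 vials drawn
   atomically from the oldest viable cohort, spilling to the next cohort
   at *its* multiplier when one runs dry. Non-viable cohorts are then
   written off. Unmet demand is recorded as shortfall, never raised.

The central output is the **weekly access ratio**: effective doses after
this week's decay, before this week's consumption, divided by
`weekly demand x weeks until the next shipment`, where the count of weeks
includes the current one (the week immediately before an arrival has a
denominator of one week's demand). This convention produces the
characteristic sawtooth whose troughs sit immediately before each restock.
The ratio is uncapped — over-supplied weeks exceed 1 — and the **average
access ratio** is the arithmetic mean over 52 weeks. `minimal_supply`
finds the smallest annual order whose average ratio reaches a target.

## Parameter defaults

All defaults live in `oxyaccess/defaults.py` (single source of truth):

| Parameter | Default | Units | Note |
|---|---|---|---|
| annual births | 49,074 | births/yr | derived: 53,000-dose full-access requirement / 1.08 |
| population growth | 0.03 | fraction/yr | Zanzibar trend |
| literacy rate | 0.67 | fraction | national estimate |
| wealth quintiles | 0.2 each | fractions | uniform where unreported |
| rural share / within-5km share | 0.50 / 0.50 | fractions | survey starting point |
| odds ratios (richest, literate, rural) | 2.55, 1.99, 0.82 | — | facility-delivery ORs |
| PPH rate, extra doses | 0.02, 4 | — | standard practice |
| annual order | 100,000 | doses/yr | actual CMS order |
| shipments/year | 2 | — | semiannual restock |
| storage temperature | 25 | degC | cold-chain-compliant ambient |
| stability anchors | 80% @ 35 degC, 20% @ 45 degC, 91 d | — | calibration pair |

## Kinetics calibration

The Arrhenius pair is fit exactly through the two stability anchors:
`k_i = -ln(f_i)/d_i`, then `Ea = R ln(k2/k1) / (1/T1 - 1/T2)` and
`A = k1 exp(Ea/(R T1))`, giving `Ea = 1.6105e5 J/mol`,
`A = 4.894e24 /day`. "One quarter" is read as 13 weeks = 91 days, the only
duration consistent with the 52-week clock. The remaining published
quarter-decay observations (~90% at 30 degC, 60% at 40 degC) are not
Arrhenius-consistent with the fitted pair; the calibrated model lands at
92.4% and 54.4%, within six percentage points, and they are treated as
consistency checks rather than fit targets.

Exact exponential decay is the default because the process is first-order;
a `discrete_linear` mode (`s <- s (1 - 7k)` weekly, floored at zero) is
kept as an option mirroring a rate-times-interval reading, and agrees with
the exponential within the first-order error bound `(7k)^2/2` per step
while `7k < 0.1`.

## Access probability modes

No published functional form links the three odds ratios to the ~50%
facility-delivery marginal, so two constructions are provided:

- **anchored_linear** (default): `p = 0.41 + 0.12 x literacy`, pinned to
  the published endpoints (41% fully illiterate, 53% fully literate; 49.04%
  at the current 67% literacy). Wealth/rural composition deviations from
  the default mix act as `ln(OR)` perturbations on the log-odds, so the
  defaults reproduce the anchors exactly while scenarios remain sensitive
  to composition.
- **logistic**: the population is split into the eight
  richest x literate x rural cells (independent composition), each cell
  gets `expit(baseline + sum ln(OR) * indicator)`, and the marginal is the
  share-weighted mean. The baseline log-odds is calibrated by a bracketed
  root find to hit a target marginal (0.50 at defaults, giving baseline
  -0.545); the implied literacy endpoints (39.0% / 55.4%) fall within five
  percentage points of the published anchors.

Distance to a facility enters only through the rural OR of 0.82: a
distance scenario reclassifies the share newly within 5 km from rural to
non-rural. Because the OR is near 1, doubling the within-5km share from
50% to 100% raises access by only ~2.5 percentage points — the model's
"more EmONCs won't move access" result.

## Numerical choices

- `minimal_supply` bisects the integer annual order between a doubling
  upper bracket and zero. Because shipments are whole vials, the average
  ratio is a step function of the order (steps of ~1.5e-4 per dose), so
  the bisection terminates on a one-dose bracket — tighter than the
  hundred-dose reporting resolution — rather than on a ratio tolerance.
  Results are rounded to the nearest 100 doses, the convention for
  published requirements.
- Weeks are 0-indexed internally; a year is exactly 52 weeks = 364 days.
- Shipment week `i` of `n` is `floor(52 i / n)`; the first shipment always
  lands at week 0.
- The logistic baseline root find uses `scipy.optimize.brentq` on
  [-60, 60] with `xtol = 1e-12`; the mixture is strictly increasing in the
  baseline, so the root is unique.
- Degenerate inputs: zero demand makes the access ratio undefined and
  raises, rather than returning infinity; zero supply is a valid run with
  all-zero ratios; cohorts below the viability floor are excluded from
  service before they are written off.

## Scenario conventions

Family planning ("reduce the birth rate by x points per year") is
cumulative by default: growth in intervention year `y` is `g0 - x*y`,
clamped at zero unless negative growth is explicitly allowed — the only
reading that produces large long-run effects. A non-cumulative one-time
step (`g0 - x`) is available. Projection years re-run the full 52-week
engine per year instead of scaling year-0 output, so temperature-band
interactions are respected; budget-style claims are expressed in doses,
not currency.

## Verification strategy and the synthetic generator

The weekly engine is cross-checked against an independently written
day-resolution simulator (`tests/_daily_oracle.py`): shipments, FIFO
service, banding and write-offs re-implemented from scratch, with the
decay clock refined to 364 one-day steps. Demand service and record epochs
stay weekly in the oracle because the model *defines* demand as a constant
weekly quantity — a fully day-interleaved demand stream is a different
model, and above ~40 degC it diverges from any weekly scheme by far more
than discretization noise (band transitions shift within the week). On a
10-point grid (25–45 degC x two supply levels) the engine matches the
oracle's average ratio to within 2% (in fact to machine precision, since
exponential daily decay composes exactly).

The synthetic temperature generator emulates Zanzibar's mild seasonality
as `mean + amplitude sin(2 pi w / 52) + N(0, sd)` with a fixed seed. It
does not emulate diurnal swings, cold-chain excursions during transport,
or facility-to-facility variation, so passing tests demonstrate correct
model mechanics under smooth ambient profiles, not field performance.

## Known limitations

- The mapping from odds ratios to probability is a modelling choice; only
  its anchored endpoints are empirically pinned.
- The published pairing of 25,500 doses with an average ratio of 0.85 is
  not reproducible under any linear reading of the ratio definition
  (25,500/26,500 ≈ 0.96) and is not targeted.
- GIS facility siting, currency costs, private-donor supply, CMS-to-EmONC
  transit, light-driven decay and cultural determinants of care-seeking
  are out of scope.
- National aggregation only: the six EmONC facilities are not
  disaggregated.
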
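# Methods

## Model structure

The model is a deterministic annual-cycle Markov **cohort macro-simulation**:
state-occupancy fractions, not individuals, are propagated through the
transition structure. The cohort is the 41,736 community-dwelling people
aged 65+ in the district in 2011, closed (no new entrants) and followed to
death or age 110.

Occupancy is tracked by single year of age (65–110), sex, ethnicity
(Māori / non-Māori), home status and a risk clock:

- **community, unmodified home** / **community, modified home** — the
  modified states additionally track years since modification when the
  effectiveness-decay scenario is active (otherwise one absorbing modified
  state);
- **residential aged care** — no home flag: the HSAM benefit ceases on
  entry, but stratum fall risk continues;
- **dead** (absorbing).

The **risk clock** is 0 for people with no treated injurious fall in the
preceding five years (low risk) and 1–5 counts years since the last one
(high risk). A new treated fall resets the clock to 1; after five fall-free
years it expires back to 0. High-risk people fall at twice the low-risk
stratum rate, and the initial high-risk stock (9% of the cohort) is spread
evenly over clocks 1–5.

### Event order within a cycle

1. injurious falls (at the modified-home risk ratio where applicable),
   split into hospitalized and non-hospitalized;
2. fall case fatality;
3. background mortality on fall survivors;
4. residential-care entry (community survivors);
5. house moves (modified → unmodified; the modification stays with the
   dwelling);
6. risk-clock update and ageing.

Survivors accrue one person-year at utility `1 − YLD`; people dying during
a cycle accrue half a cycle; each surviving injurious fall subtracts the
annualized disability weight. Costs and QALYs of cycle *k* (the year
`2011 + k`) are discounted by `(1 + r)^−k`, so the cycle-0 intervention
outlay is undiscounted. Age 110 is absorbing: background mortality is 1
there, which is how the engine guarantees extinction within 46 cycles.

## The intervention

Every eligible person receives a NZ$44 invitation regardless of uptake;
89% accept and their homes are modified at NZ$250 each, with the expected
per-participant cost multiplied by `1 − share_cohabiting/2` (the cost is
halved when two eligible people share a dwelling). Modified homes
experience injurious falls at `rr = 0.81` (95% CI 0.68–0.97).

Targeting rules cross two age cuts (65+, 75+) with fall-history filters
(everyone / only high-risk / only low-risk). Risk-targeted arms are
delivered *prospectively*: people are also invited in the cycle they enter
the high-risk state, with that cycle's discount factor applied to the
outlay. The scenario grid further varies discounting (0%, 3%, 6%), a
10-year linear decay of effectiveness (the rate reduction `1 − rr`
shrinks linearly to nil), a one-third HSAM cost reduction, and 10-/20-year
horizons.

## Parameters and defaults

| Parameter | Default | Uncertainty |
|---|---|---|
| overall annual treated-fall probability | 6461 / 41,736 = 15.5% | table scalar, log-normal 0.5×–1.5× |
| hospitalized-fall probability | 1364 / 41,736 = 3.3% | table scalar |
| risk ratio high- vs low-risk faller | 2.0 | — |
| high-risk share of cohort | 9% | — |
| HSAM risk ratio | 0.81 | log-normal fitted to CI 0.68–0.97 |
| uptake | 89.0% | Beta(10.03, 1.24) |
| fall disability weight (annualized) | 0.30 × 4/12 = 0.10 | log-normal fitted to CI 0.06–0.15 |
| HSAM cost per participant | NZ$250 | log-normal fitted to CI 165–355 |
| program (invitation) cost per eligible person | NZ$44 | gamma, SD 10% of mean |
| hospitalized / non-hospitalized fall case cost | NZ$4068 / NZ$344 | table scalars |
| residential-care entry by age band | 0.1%–2% | table scalar |
| house-move probability by age band | 5%–2% | table scalar |
| background mortality decline to 2026 | 2.25%/yr Māori, 1.75%/yr non-Māori | — |

Log-normal "table scalars" multiply a whole stratified table by one draw
whose 95% interval is 0.5×–1.5×; background mortality/morbidity levels
carry no sampling uncertainty. All draws are independent; probabilities are
truncated into [0, 1] after scaling. Risk-ratio draws above 1 (the upper
tail of the CI) are accepted as harmful draws rather than truncated.

## Synthetic parameter generation and calibration

The stratified unit-record inputs behind the published analysis
(injury-claim counts, mortality and health-system costs by age, sex and
ethnicity) are confidential; only aggregates and ranges are public. The
generator therefore *reconstructs* plausible stratified tables under
explicit shape assumptions and calibrates them **exactly** to the public
aggregates:

- population: 41,736 split over age bands, sexes and ethnicities by
  published-shape shares with largest-remainder integer apportionment;
- fall rates: an age-increasing band gradient with small multiplicative
  stratum jitter, scaled so population-expected falls equal 6461, with the
  high/low risk-group ratio fixed at 2;
- conditional hospitalization: age-increasing, jointly scaled so expected
  hospitalized falls equal 1364;
- fall case fatality: mean ≈ 3.2% with a peak of 5% (Māori men 65–69),
  decreasing with age band because the denominator of treated falls grows
  faster than deaths;
- background mortality: Gompertz-like in age (level 0.0105, log-slope
  0.101), male and Māori excess, with the published ethnic annual declines
  applied through 2026 and 0% thereafter;
- background annual and last-6-months-of-life costs: anchored to the
  published cells (e.g. NZ$3378 for women 65–69, NZ$6511 for men 85–89;
  end-of-life NZ$20,476 falling to NZ$6127 at 95–99).

The mortality level/slope and fatality shape were chosen once so that the
baseline per-capita discounted QALY expectancy (8.01) and the sign
structure of the base case (positive net cost) sit near the published
values (7.94 per capita; net cost positive); they are fixed constants of
the package, not fitted per run. The calibration to 6461/1364/41,736 and
the cost anchors is exact by construction and verified in the test suite.
What the generator does **not** emulate: real correlation between falls
and mortality within strata, seasonality, regional structure, or any
unit-record realism beyond the published aggregates — headline *numbers*
are therefore illustrative, while the published *orderings* (risk
targeting dominates, decay worsens the ICER, cost cuts improve it, the
effectiveness parameter dominates the tornado) are reproduced and tested.

## ICER conventions

`compute_icer` reports dominance the way published tables do: positive
gain with net savings is "cost saving", health loss with net cost is
"dominated", a ~zero/zero comparison "undefined". Two places need a
*numeric* position instead:

- **Scenario ordering** uses `icer_rank_value`, the signed cost-per-QALY
  ratio among QALY-gaining strategies (`Δcost/ΔQALY`, extended continuously
  through zero so cost-saving strategies rank by savings per QALY;
  strategies gaining no health rank worst).
- **ICER tornado bars**: a bar endpoint that is cost-saving is clipped to
  0 NZ$/QALY on the ICER axis (a cost-saving result is at least as good as
  a free one at any positive willingness-to-pay), which is where tornado
  figures conventionally clip such bars. An endpoint that is dominated or
  undefined has no position on the ICER axis; that bar falls back to
  ranking on its net-cost swing.

In the PSA, cost-saving iterations enter the ICER vector as −∞ and
dominated ones as +∞; the reported mean ICER excludes both (it is the mean
over iterations with a defined ratio), while the 95% interval bounds render
as "cost saving"/"dominated" when they land on the sentinels.

## Validation

- **Micro-simulation oracle**: an independent individual-level Bernoulli
  simulation (200,000 people, sharing only parameter values with the
  engine) reproduces cohort occupancy and modified-home share at cycles 1,
  5 and 10 within 3 standard errors on a two-stratum toy model.
- **Identities**: a null intervention leaves outputs unchanged (bitwise at
  zero uptake; to float precision for an inert free modification); zero
  discounting equals undiscounted sums (1e-9); cohort mass is conserved
  every cycle (1e-9, enforced inside the engine); distribution quantile
  round-trips (1e-9).
- **Linearity/partition**: the engine is linear in person-counts, so
  subgroup runs add to the whole-population run, and (with prospective
  delivery off, which re-invites nobody) the risk-targeted and
  no-history arms partition the all-comers arm exactly.
- **Exact arithmetic**: program cost 44 × 41,736 = NZ$1,836,384; 2011 fall
  cost 1364 × 4068 + 5097 × 344 = NZ$7.30m; Beta(10.03, 1.24) mean 89.0%;
  0.30 × 4/12 = 0.10; 0.066 QALY per capita ≈ 24 days of healthy life.

## Limitations

Problem sizes (one district, 41,736 people, 2011 baseline) are the
package's own modelling choices. The synthetic tables make the absolute
QALY and cost levels illustrative; only the calibrated aggregates and the
qualitative orderings carry over to the real setting. Half-cycle
correction is applied to deaths only; everyone alive at a cycle end is
valued at end of cycle. Fall risk and background mortality are
conditionally independent within strata, and intervention effectiveness is
homogeneous across strata.
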
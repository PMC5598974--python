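# hsamcea — cost-utility model of home safety assessment and modification for falls prevention

`hsamcea` is a district-level cost-utility analysis of a falls-prevention
program for older adults. A **home safety assessment and modification
(HSAM)** program invites community-dwelling people aged 65+ (a NZ$44
letter-and-phone invitation per eligible person), and an occupational
therapist modifies the homes of the ~89% who accept (grab rails, lighting,
trip hazards; NZ$250 labor and materials per participant, halved per person
where two eligible people share a dwelling). Modified homes experience
injurious falls at 0.81 times the stratum rate.

The model follows a closed cohort of 41,736 community-dwelling people aged
65+ in 2011 — stratified by single year of age, sex and ethnicity
(Māori / non-Māori) — with an annual-cycle Markov macro-simulation to death
or age 110, accruing discounted QALYs and health-system costs. On top of
the deterministic engine it provides:

- **probabilistic sensitivity analysis (PSA)**: Monte-Carlo propagation of
  all parameter uncertainty to net cost, QALYs gained and the ICER;
- **one-way (tornado) analysis** ranking parameters by output swing;
- **targeting scenarios**: age cuts (65+/75+) crossed with fall-history
  filters, plus discounting, effectiveness-decay, cost and horizon variants;
- **equity counterfactuals**: re-running disadvantaged subgroups with the
  advantaged group's background mortality and morbidity;
- a **synthetic parameter generator** that produces the stratified input
  tables, calibrated exactly to the published district aggregates (6461
  treated injurious falls and 1364 hospitalized falls among 41,736 people
  in 2011). The underlying unit-record data are confidential, so the
  stratified tables are plausible synthetic reconstructions; see
  `docs/methods.md`.

## Worked example

```python
from hsamcea import ScenarioSpec, compute_icer, run_pair, run_psa
from hsamcea.synthetic import build_default_parameter_set

params, population = build_default_parameter_set(seed=0)

# deterministic base case: HSAM offered to everyone 65+, 3% discounting
baseline, interv = run_pair(params, ScenarioSpec("base_case"), population)
dq = interv.qalys - baseline.qalys            # ≈ 4187 QALYs gained
dc = interv.total_cost - baseline.total_cost  # ≈ NZ$1.32m net cost
print(compute_icer(dc, dq))                   # ≈ NZ$316 per QALY
print(interv.costs["intervention"])           # ≈ NZ$8.80m upfront outlay

# probabilistic sensitivity analysis
psa = run_psa(params, ScenarioSpec("base_case"), population, n_iter=500, seed=1)
print(psa.icer_summary())  # mean ICER ≈ NZ$4400/QALY; ~30% of draws cost-saving
```

The deterministic and probabilistic mean ICERs differ because the ICER is a
nonlinear (ratio) statistic of the parameter draws; both are far below the
conventional NZ$45,000/QALY (GDP-per-capita) threshold.

## Layout

- `src/hsamcea/` — the library (synthetic generator, Markov engine,
  intervention/scenarios, PSA, tornado, equity, reporting);
- `analysis/` — numbered scripts producing the result tables;
- `scripts/acceptance.py` — headline-quantity report;
- `docs/methods.md` — model structure, parameters, calibration and
  conventions;
- `tests/` — unit, property and acceptance tests, including an independent
  individual-level micro-simulation oracle for the cohort engine.
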
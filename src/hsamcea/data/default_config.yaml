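# Default configuration for the district HSAM falls-prevention model.
# Point estimates are the published 2011 values for the modeled district;
# the synthetic generators calibrate stratified tables to these aggregates.
# All monetary values are 2011 NZ$.

start_year: 2011
jitter_sd: 0.03      # within-range demographic-shape noise (seed-dependent)

population:
  total: 41736               # people aged 65+ in the district, 2011
  share_cohabiting: 0.5      # eligible persons sharing a dwelling with another
                             # eligible person (free parameter; only mean
                             # occupancy 3.21/dwelling is published)

falls:
  count: 6461                # injurious falls in 2011 (15.5% of 41,736)
  hospitalized_count: 1364   # hospitalized falls in 2011 (3.3% of 41,736)
  reference_population: 41736
  high_risk_share: 0.09      # treated injurious fall in the preceding 5 years
  risk_ratio_high_vs_low: 2.0  # high-risk vs low-risk fall probability
  fatality_peak: 0.05        # death-after-fall, highest cell (Maori men 65-69)

transitions:
  p_residential_care: [0.001, 0.003, 0.006, 0.012, 0.02]  # by age band, 0-2%
  p_move_house: [0.05, 0.04, 0.03, 0.025, 0.02]           # by age band, 2-5%

mortality_decline:           # annual all-cause mortality decline, to 2026
  maori: 0.0225
  non_maori: 0.0175

intervention:
  rr_hsam: 0.81              # rate ratio for injurious falls in modified homes
  rr_ci: [0.68, 0.97]        # 95% CI (log-normal)
  uptake: 0.890              # 842/946 households in the source trial
  uptake_beta: [10.03, 1.24] # beta uncertainty (95% CI 64% to 99%)
  dw_fall_annualized: 0.10   # fracture DW 0.30 applied for 4 of 12 months
  dw_ci: [0.06, 0.15]        # 95% interval (log-normal)

costs:
  hsam_per_person: 250.0     # labor + materials per participating person
  hsam_ci: [165.0, 355.0]    # 95% interval (log-normal)
  program_per_person: 44.0   # invitation (letter + phone call) per eligible
  program_rel_sd: 0.10       # gamma, SD 10% of the mean
  fall_nonhosp_mean: 344.0   # per non-hospitalized case (varies by age/sex)
  fall_hosp_mean: 4068.0     # per hospitalized case (varies by age/sex)

analysis:
  n_iterations: 2000         # Monte-Carlo iterations for the PSA
  discount_rate: 0.03        # per annum, QALYs and costs alike
  cost_effectiveness_threshold: 45000.0   # NZ GDP per capita, 2011 NZ$/QALY
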
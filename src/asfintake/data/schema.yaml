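# Canonical survey-table schema.  Heterogeneous inputs must declare a
# mapping onto these column names and categorical level spellings.
columns:
  required:
    - survey_id
    - country
    - year
    - asf
    - age_group
    - sex
    - education
    - urbanicity
    - mean_intake
    - sd_intake
    - n
    - method
    - nationally_representative
  optional:
    - region
    - individual_level
    - mean_energy
    - energy_adjusted
levels:
  asf: [milk, cheese, yogurt, eggs, seafood, unprocessed_red_meat, processed_meat]
  age_group: ["<1", "1-2", "3-4", "5-9", "10-14", "15-19", all]
  sex: [female, male, all]
  education: [low, medium, high, all]
  urbanicity: [urban, rural, all]
  method: [24hr_recall, ffq, short_questionnaire, household_budget]
units:
  mean_intake: g/d
  sd_intake: g/d
  mean_energy: kcal/d
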
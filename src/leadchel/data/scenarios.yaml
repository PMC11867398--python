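# Strategy scenarios: the base case (BC) plus 25 variations.
# horizon null = lifetime (model horizon); disc_* null = global defaults
# (costs 4%, effects 1.5%).  Fractions are proportions of the eligible
# (high-tertile) group.  reexposure_delay is the number of years after the
# first treatment year before the first follow-up screening;
# reexposure_interval the spacing of subsequent screenings;
# reexposure_delay null disables follow-up screening entirely.
scenarios:
  - {label: BC}
  - {label: "1", horizon: 10}
  - {label: "2", horizon: 20}
  - {label: "3", disc_costs: 0.0}
  - {label: "4", disc_effects: 0.0}
  - {label: "5", c2: 0.30}
  - {label: "6", c2: 0.70}
  - {label: "7", c2: 0.30, c3: 0.50}
  - {label: "8", c2: 0.70, c3: 0.50}
  - {label: "9", repeated_fraction_year2: 0.30}
  - {label: "10", repeated_fraction_year2: 0.80}
  - {label: "11", safety_iron_check: true}
  - {label: "12", safety_iron_check: true, safety_iron_supplement_weeks: 8}
  - {label: "13", safety_iron_check: true, safety_liver_check: true}
  - {label: "14", reexposure_fraction: 0.01}
  - {label: "15", reexposure_fraction: 0.30}
  - {label: "16", reexposure_fraction: 0.60}
  - {label: "17", reexposure_delay: 10, reexposure_fraction: 0.01, reexposure_interval: 10}
  - {label: "18", reexposure_delay: 10, reexposure_fraction: 0.10, reexposure_interval: 10}
  - {label: "19", reexposure_delay: 10, reexposure_fraction: 0.30, reexposure_interval: 5}
  - {label: "20", reexposure_delay: 10, reexposure_fraction: 0.60, reexposure_interval: 5}
  - {label: "21", reexposure_delay: 20, reexposure_fraction: 0.01, reexposure_interval: 10}
  - {label: "22", reexposure_delay: 20, reexposure_fraction: 0.10, reexposure_interval: 10}
  - {label: "23", reexposure_delay: 20, reexposure_fraction: 0.30, reexposure_interval: 5}
  - {label: "24", reexposure_delay: 20, reexposure_fraction: 0.60, reexposure_interval: 5}
  - {label: "25", reexposure_delay: null, reexposure_fraction: 0.0}
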
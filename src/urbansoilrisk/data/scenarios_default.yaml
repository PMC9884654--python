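# Residential screening exposure scenarios. Ingestion is assessed for
# children only (geophagy predisposition); inhalation for both age
# groups. Units: intake_rate kg soil/day (ingestion) or m3 air/day
# (inhalation); body_weight kg; frequency_days d/y; duration_years y;
# pef m3/kg.
scenarios:
  - receptor: child
    pathway: ingestion
    intake_rate: 2.0e-4
    bioavailability: 1.0
    frequency_days: 350
    duration_years: 6
    body_weight: 15
  - receptor: child
    pathway: inhalation
    intake_rate: 10.0
    bioavailability: 1.0
    frequency_days: 350
    duration_years: 6
    body_weight: 15
    pef: 1.36e9
  - receptor: adult
    pathway: inhalation
    intake_rate: 20.0
    bioavailability: 1.0
    frequency_days: 350
    duration_years: 24
    body_weight: 70
    pef: 1.36e9
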
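# Registry of printed summary inputs for the botanical-extract risk-benefit
# assessment in the Italian adult diet: element definitions, baseline dietary
# intake summaries, botanical concentration summaries (n = 25 extracts),
# consumption patterns, EFSA reference values and US EPA reference doses.
#
# Units use the package's canonical dialect: "mg day-1", "ug kg_bw-1 day-1",
# "mg kg_bw-1 week-1", "mg kg-1" (concentration per kg dry extract), etc.
# "ug" denotes micrograms.

body_weight_kg: 70.0

elements:
  K:  {class: essential, concentration_units: "mg kg-1", intake_units: "mg day-1"}
  P:  {class: essential, concentration_units: "mg kg-1", intake_units: "mg day-1"}
  Ca: {class: essential, concentration_units: "mg kg-1", intake_units: "mg day-1"}
  Mg: {class: essential, concentration_units: "mg kg-1", intake_units: "mg day-1"}
  Fe: {class: essential, concentration_units: "mg kg-1", intake_units: "mg day-1"}
  Zn: {class: essential, concentration_units: "mg kg-1", intake_units: "mg day-1"}
  Al: {class: toxic, concentration_units: "mg kg-1", intake_units: "ug kg_bw-1 day-1"}
  Ni: {class: toxic, concentration_units: "ug kg-1", intake_units: "ug kg_bw-1 day-1"}
  As: {class: toxic, concentration_units: "ug kg-1", intake_units: "ug kg_bw-1 day-1"}
  Pb: {class: toxic, concentration_units: "ug kg-1", intake_units: "ug kg_bw-1 day-1"}

# Baseline dietary intake of Italian adults (total diet excluding botanicals),
# mean +/- SD, modelled lognormal. Toxic-element entries are per kg body weight.
baseline_intakes:
  K:  {mean: 3026, sd: 875, units: "mg day-1"}
  P:  {mean: 1269, sd: 366, units: "mg day-1"}
  Mg: {mean: 279, sd: 87, units: "mg day-1"}
  Ca: {mean: 914, sd: 317, units: "mg day-1"}
  Fe: {mean: 8.7, sd: 2.9, units: "mg day-1"}
  Zn: {mean: 10.7, sd: 3.3, units: "mg day-1"}
  As: {mean: 0.081, sd: 0.030, units: "ug kg_bw-1 day-1"}
  Ni: {mean: 1.55, sd: 0.72, units: "ug kg_bw-1 day-1"}
  Al: {mean: 58.2, sd: 25.0, units: "ug kg_bw-1 day-1"}
  Pb: {mean: 0.160, sd: 0.081, units: "ug kg_bw-1 day-1"}

# Element concentrations across the 25 botanical extracts: summary moments and
# the best-fitting family used for Monte Carlo exposure simulation.
concentrations:
  K:  {family: lognormal, mean: 16876, sd: 31000, median: 8337, p5: 398, p95: 58406, units: "mg kg-1"}
  P:  {family: lognormal, mean: 1605, sd: 2000, median: 986, p5: 76, p95: 5009, units: "mg kg-1"}
  Ca: {family: lognormal, mean: 1400, sd: 2300, median: 756, p5: 42, p95: 4857, units: "mg kg-1"}
  Mg: {family: lognormal, mean: 878, sd: 1300, median: 506, p5: 35, p95: 2820, units: "mg kg-1"}
  Fe: {family: exponential, mean: 55, sd: 55, median: 38, p5: 0.1, p95: 165, units: "mg kg-1"}
  Zn: {family: exponential, mean: 9.0, sd: 9.0, median: 6.2, p5: 0.1, p95: 26.9, units: "mg kg-1"}
  Al: {family: exponential, mean: 28, sd: 28, median: 20, p5: 0.1, p95: 85, units: "mg kg-1"}
  Ni: {family: lognormal, mean: 2433, sd: 7400, median: 719, p5: 13, p95: 9478, units: "ug kg-1"}
  As: {family: lognormal, mean: 3026, sd: 18000, median: 649, p5: 7, p95: 11623, units: "ug kg-1"}
  Pb: {family: lognormal, mean: 128, sd: 220, median: 66, p5: 3, p95: 438, units: "ug kg-1"}

# Botanical consumption of Italian adult consumers (herbal formulations and
# plant extracts), mean +/- SD, modelled lognormal.
consumption:
  chronic_total_g_per_day: {mean: 8.1, sd: 19.4, units: "g day-1"}
  chronic_g_per_kgbw_day: {mean: 0.11, sd: 0.27, units: "g kg_bw-1 day-1"}
  acute_g_per_kgbw: {mean: 0.17, sd: 0.35, units: "g kg_bw-1"}

# EFSA dietary reference values (benefit), health-based guidance values and
# reference points (risk), plus US EPA chronic oral reference doses (RfD).
# The Mg UL applies to supplemental magnesium only, never as a total-diet cap.
health_references:
  - {element: K, kind: AI, value: 3500, units: "mg day-1", endpoint: "adequate intake", basis: daily}
  - {element: P, kind: AI, value: 550, units: "mg day-1", endpoint: "adequate intake", basis: daily}
  - {element: P, kind: UL, value: 3000, units: "mg day-1", endpoint: "upper intake level", basis: daily}
  - {element: Ca, kind: PRI, value: 950, units: "mg day-1", endpoint: "population reference intake", basis: daily}
  - {element: Ca, kind: UL, value: 2500, units: "mg day-1", endpoint: "upper intake level", basis: daily}
  - {element: Mg, kind: AI, value: 325, units: "mg day-1", endpoint: "adequate intake", basis: daily}
  - {element: Mg, kind: UL, value: 250, units: "mg day-1", endpoint: "upper intake level", basis: daily, supplemental: true}
  - {element: Fe, kind: PRI, value: 11, units: "mg day-1", endpoint: "population reference intake", basis: daily}
  - {element: Zn, kind: PRI, value: 11.5, units: "mg day-1", endpoint: "population reference intake", basis: daily}
  - {element: Zn, kind: UL, value: 25, units: "mg day-1", endpoint: "upper intake level", basis: daily}
  - {element: Al, kind: TWI, value: 1.0, units: "mg kg_bw-1 week-1", endpoint: "neurotoxicity", basis: weekly}
  - {element: Ni, kind: TDI, value: 13, units: "ug kg_bw-1 day-1", endpoint: "reproductive and developmental toxicity", basis: daily}
  - {element: Ni, kind: LOAEL, value: 4.3, units: "ug kg_bw-1", endpoint: "systemic contact dermatitis", basis: per_event}
  - {element: As, kind: BMDL, value: 0.06, units: "ug kg_bw-1 day-1", endpoint: "skin cancer", basis: daily}
  - {element: Pb, kind: BMDL, value: 1.5, units: "ug kg_bw-1 day-1", endpoint: "cardiovascular effects", basis: daily}
  - {element: Pb, kind: BMDL, value: 0.63, units: "ug kg_bw-1 day-1", endpoint: "nephrotoxicity", basis: daily}
  - {element: Al, kind: RfD, value: 1.0, units: "mg kg_bw-1 day-1", endpoint: "chronic oral reference dose", basis: daily}
  - {element: As, kind: RfD, value: 0.0003, units: "mg kg_bw-1 day-1", endpoint: "chronic oral reference dose", basis: daily}
  - {element: Fe, kind: RfD, value: 0.7, units: "mg kg_bw-1 day-1", endpoint: "chronic oral reference dose", basis: daily}
  - {element: Ni, kind: RfD, value: 0.02, units: "mg kg_bw-1 day-1", endpoint: "chronic oral reference dose", basis: daily}
  - {element: Zn, kind: RfD, value: 0.30, units: "mg kg_bw-1 day-1", endpoint: "chronic oral reference dose", basis: daily}

# Commercial product labels of the 25 analysed botanical extracts (metadata
# only; no per-product parameterization is attempted).
products:
  - Gardenia extract
  - Garcinia Mangostana fruit rind extract
  - Sea Buckthorn extract
  - Hawthorn extract
  - Cayenne extract
  - Lingustrin lucidum extract
  - Black garlic extract
  - Java tea extract
  - Gymnema Sylvestre extract (75%)
  - Rosemary extract
  - Ginkgo Biloba extract
  - Green Tea Extract
  - Dandelion extract
  - Walnut extract
  - Grape Skin extract
  - Pomegranate extract
  - Cordyceps sinensis extract (4:1)
  - Reishi mushroom extract
  - Cordyceps extract (beta glucan)
  - Beetroot powder E2.6
  - Sarsaparilla extract
  - Skullcap extract
  - Nettle Root extract
  - Guarana extract (10% caffeine)
  - Red yeast rice extract

# Stochastic exposure-factor model for the cumulative (THQ/HI) assessment:
# exposure frequency Ef (days/year) and duration Ed (years), both truncated
# normal; averaging time At = Ed x 365, so Ed cancels algebraically.
exposure_factor:
  ef_days_per_year: {mean: 182.5, sd: 70.0, lower: 1.0, upper: 365.0}
  ed_years: {mean: 23.0, sd: 10.0, lower: 1.0, upper: 46.0}
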
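# Base-case parameter set for the LDCT screening cost-effectiveness model.
# Each leaf carries {base, min, max, distribution}; distribution "fixed" means
# the parameter is excluded from probabilistic sensitivity analysis.
# Costs are 2021 USD; probabilities flagged "per cycle" refer to 3-month cycles.

smoking_prevalence:
  male: {base: 0.741, min: 0.718, max: 0.760, distribution: beta}
  female: {base: 0.054, min: 0.040, max: 0.070, distribution: beta}

packyear_proportion:
  male:
    "20_29": {base: 0.3036, min: 0.2429, max: 0.3643, distribution: beta}
    "30plus": {base: 0.3468, min: 0.2774, max: 0.4162, distribution: beta}
  female:
    "20_29": {base: 0.1087, min: 0.0870, max: 0.1304, distribution: beta}
    "30plus": {base: 0.0651, min: 0.0521, max: 0.0781, distribution: beta}

# Age-specific lung cancer incidence in the general population (annual probability).
incidence:
  "40_44": {base: 0.0001414, min: 0.0001414, max: 0.0001414, distribution: fixed}
  "45_49": {base: 0.0002867, min: 0.0002867, max: 0.0002867, distribution: fixed}
  "50_54": {base: 0.0005538, min: 0.0005538, max: 0.0005538, distribution: fixed}
  "55_59": {base: 0.0010131, min: 0.0010131, max: 0.0010131, distribution: fixed}
  "60_64": {base: 0.0016089, min: 0.0016089, max: 0.0016089, distribution: fixed}
  "65_69": {base: 0.0022856, min: 0.0022856, max: 0.0022856, distribution: fixed}
  "70_74": {base: 0.0029973, min: 0.0029973, max: 0.0029973, distribution: fixed}
  "75_79": {base: 0.0036277, min: 0.0036277, max: 0.0036277, distribution: fixed}
  "80_84": {base: 0.0040047, min: 0.0040047, max: 0.0040047, distribution: fixed}
  "85plus": {base: 0.0032795, min: 0.0032795, max: 0.0032795, distribution: fixed}

# Relative risk of lung cancer versus never smokers, by cumulative exposure.
relative_risk:
  "20_29": {base: 2.70, min: 2.16, max: 3.24, distribution: gamma}
  "30plus": {base: 6.10, min: 4.88, max: 7.32, distribution: gamma}

# Preclinical progression probabilities, per 3-month cycle.
progression:
  I:
    II: {base: 0.3558, min: 0.28464, max: 0.42696, distribution: beta}
    IIIA: {base: 0.0328, min: 0.02624, max: 0.03936, distribution: beta}
    IIIB: {base: 0.00000001, min: 0.000000008, max: 0.000000012, distribution: beta}
    IV: {base: 0.0869, min: 0.06952, max: 0.10428, distribution: beta}
    diagnosis: {base: 0.0246, min: 0.01968, max: 0.02952, distribution: beta}
    death: {base: 0.1544, min: 0.12352, max: 0.18528, distribution: beta}
  II:
    IIIA: {base: 0.2480, min: 0.1984, max: 0.2976, distribution: beta}
    IIIB: {base: 0.0060, min: 0.0048, max: 0.0072, distribution: beta}
    IV: {base: 0.1290, min: 0.1032, max: 0.1548, distribution: beta}
    diagnosis: {base: 0.0270, min: 0.0216, max: 0.0324, distribution: beta}
    death: {base: 0.1231, min: 0.09848, max: 0.14772, distribution: beta}
  IIIA:
    IIIB: {base: 0.2246, min: 0.17968, max: 0.26952, distribution: beta}
    IV: {base: 0.1455, min: 0.1164, max: 0.1746, distribution: beta}
    diagnosis: {base: 0.0811, min: 0.06488, max: 0.09732, distribution: beta}
    death: {base: 0.1527, min: 0.12216, max: 0.18324, distribution: beta}
  IIIB:
    IV: {base: 0.0336, min: 0.02688, max: 0.04032, distribution: beta}
    diagnosis: {base: 0.5177, min: 0.41416, max: 0.62124, distribution: beta}
    death: {base: 0.1853, min: 0.14824, max: 0.22236, distribution: beta}
  IV:
    diagnosis: {base: 0.6584, min: 0.52672, max: 0.79008, distribution: beta}
    death: {base: 0.2978, min: 0.23824, max: 0.35736, distribution: beta}

# Post-diagnosis lung cancer fatality, per 3-month cycle, by stage at diagnosis.
fatality:
  I: {base: 0.0121, min: 0.0097, max: 0.0145, distribution: beta}
  II: {base: 0.0445, min: 0.0356, max: 0.0534, distribution: beta}
  IIIA: {base: 0.0720, min: 0.0576, max: 0.0864, distribution: beta}
  IIIB: {base: 0.1262, min: 0.1010, max: 0.1514, distribution: beta}
  IV: {base: 0.1986, min: 0.1589, max: 0.2383, distribution: beta}

screen:
  sensitivity: {base: 0.8913, min: 0.7696, max: 0.9527, distribution: beta}
  specificity: {base: 0.9436, min: 0.9388, max: 0.9481, distribution: beta}
  baseline_early_recall:
    "40": {base: 0.1442, min: 0.1154, max: 0.1730, distribution: beta}
    "45": {base: 0.1587, min: 0.1270, max: 0.1904, distribution: beta}
    "50": {base: 0.1534, min: 0.1227, max: 0.1841, distribution: beta}
    "55": {base: 0.1513, min: 0.1210, max: 0.1816, distribution: beta}
    "60": {base: 0.1511, min: 0.1209, max: 0.1813, distribution: beta}
    "65": {base: 0.1664, min: 0.1331, max: 0.1997, distribution: beta}
  baseline_immediate_referral:
    "40": {base: 0.0134, min: 0.0107, max: 0.0161, distribution: beta}
    "45": {base: 0.0088, min: 0.0070, max: 0.0106, distribution: beta}
    "50": {base: 0.0122, min: 0.0098, max: 0.0146, distribution: beta}
    "55": {base: 0.0173, min: 0.0138, max: 0.0208, distribution: beta}
    "60": {base: 0.0284, min: 0.0227, max: 0.0341, distribution: beta}
    "65": {base: 0.0306, min: 0.0245, max: 0.0367, distribution: beta}
  annual_early_recall: {base: 0.0442, min: 0.0354, max: 0.0530, distribution: beta}
  annual_immediate_referral: {base: 0.0237, min: 0.0190, max: 0.0284, distribution: beta}

utility:
  no_lc: {base: 0.933, min: 0.929, max: 0.951, distribution: beta}
  I: {base: 0.840, min: 0.756, max: 0.924, distribution: beta}
  II: {base: 0.790, min: 0.711, max: 0.869, distribution: beta}
  III: {base: 0.790, min: 0.711, max: 0.869, distribution: beta}
  IV: {base: 0.770, min: 0.693, max: 0.847, distribution: beta}

disutility:
  false_positive: {base: 0.063, min: 0.057, max: 0.069, distribution: beta}

cost:
  ldct: {base: 53.94, min: 43.15, max: 64.73, distribution: gamma}
  workup: {base: 333.89, min: 267.11, max: 400.67, distribution: gamma}
  treatment:
    I: {base: 2258.33, min: 1806.66, max: 2710.00, distribution: gamma}
    II: {base: 3739.69, min: 2991.75, max: 4487.63, distribution: gamma}
    III: {base: 4066.14, min: 3252.91, max: 4879.37, distribution: gamma}
    IV: {base: 5224.76, min: 4179.81, max: 6269.71, distribution: gamma}

discount_rate: {base: 0.05, min: 0.00, max: 0.08, distribution: fixed}
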
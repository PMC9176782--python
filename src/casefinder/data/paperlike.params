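# Default synthetic-registry configuration.
#
# Calibrated so that the closed-form expected PPV of the final algorithm
# version is ~0.93 and the truth-based sensitivity rises from ~0.25 (2009)
# to ~0.65 (2017), with registry capture growing linearly over the period.

n_patients: 50000
years: [2009, 2017]

# True condition of each simulated patient.
class_mix:
  primary_NSCLC: 0.25
  neuroendocrine_lung: 0.03
  upper_airway_cancer: 0.05
  other_site_cancer: 0.42
  lung_metastasis: 0.012
  benign: 0.238

# Probability an NSCLC case receives one of the listed NSCLC morphology
# codes; the remainder splits between a generic M-8* code whose diagnosis
# text must carry a histology keyword, and an outright miscode.
coding_fidelity: 0.85
generic_text_frac: 0.7

# Probability each relevant keyword appears in the diagnosis text.
keyword_emission: 0.8

# Topography coding of true NSCLC: specific lung code, respiratory-NOS
# code, or no code (lung then only findable through keywords).
topography_fidelity: 0.92
resp_nos_prob: 0.03

# Probability a non-lung/benign report mentions the lung in free text
# (e.g. suspected pulmonary metastasis), creating realistic false positives.
decoy_lung_text_prob: 0.0165

# Registry capture of a true case's report, by calendar year (the registry
# was young in 2009 and its completeness grew).
capture_by_year:
  2009: 0.20
  2010: 0.2625
  2011: 0.325
  2012: 0.3875
  2013: 0.45
  2014: 0.5125
  2015: 0.575
  2016: 0.6375
  2017: 0.70

# Hospital-pharmacy treatment: share of true NSCLC cases treated with an
# NSCLC-indicated intravenous drug, and the (higher) registry capture of
# those hospital-attended patients.
treatment_prob: 0.10
treated_capture: 0.85
other_treatment_prob: 0.05

resident_prob: 0.87
extra_record_prob: 0.2

# Synthetic manual review: per-item probability a rater deviates from
# truth; deviations soften to "maybe" with maybe_prob, else flip yes/no.
rater_error: 0.05
maybe_prob: 0.5
origin_maybe_prob: 0.2

seed: 0
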
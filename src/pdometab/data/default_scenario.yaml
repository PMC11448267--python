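# Default synthetic scenario.
#
# Encodes the planted effect DIRECTIONS of the study design this package
# emulates: basal-like organoids have lower baseline ECAR but higher
# glycolytic reserve and higher OCR than classical ones; UK-5099 treatment
# slightly raises ECAR and attenuates OCR (more strongly in basal-like);
# UK-5099 reduces M+2 TCA-cycle fractions (strongly in basal-like); low
# H-score cases have shorter disease-specific survival and more aggressive
# covariates. Effect magnitudes for flux rates and labelled fractions are
# package defaults (no published magnitudes exist); covariate frequencies
# and the cut-point geometry use the published cohort summaries.
seed: 0

seahorse:
  n_wells_per_group: 12
  cycles_per_phase: 3
  noise_sd: 1.0              # additive Gaussian on rates (mpH/min or pmol O2/min)
  confluency_range: [0.5, 0.95]
  groups:
    basal-like:
      DMSO:
        nga: 5.0
        baseline_glycolysis: 15.0
        glycolytic_capacity: 45.0
        nmr: 10.0
        basal_respiration: 60.0
        atp_linked: 45.0
        maximal_respiration: 110.0
      UK-5099:
        nga: 5.0
        baseline_glycolysis: 18.0
        glycolytic_capacity: 46.0
        nmr: 10.0
        basal_respiration: 44.0
        atp_linked: 32.0
        maximal_respiration: 75.0
    classical:
      DMSO:
        nga: 5.0
        baseline_glycolysis: 30.0
        glycolytic_capacity: 40.0
        nmr: 10.0
        basal_respiration: 40.0
        atp_linked: 30.0
        maximal_respiration: 70.0
      UK-5099:
        nga: 5.0
        baseline_glycolysis: 33.0
        glycolytic_capacity: 41.0
        nmr: 10.0
        basal_respiration: 35.0
        atp_linked: 26.0
        maximal_respiration: 60.0

tracing:
  n_replicates: 3
  noise_cv: 0.05             # multiplicative log-normal CV on intensities
  pool_scale: 1000000.0      # arbitrary total-pool intensity units
  fragment_formulas:         # plausible MOX-tBDMS fragment compositions
    pyruvate:  {C: 9,  H: 19, N: 1, O: 3, Si: 1, n_labelable: 3}
    lactate:   {C: 11, H: 25, O: 3, Si: 2, n_labelable: 3}
    glyc3p:    {C: 15, H: 38, O: 6, Si: 3, n_labelable: 3}
    citrate:   {C: 20, H: 39, O: 7, Si: 3, n_labelable: 6}
    malate:    {C: 18, H: 39, O: 5, Si: 3, n_labelable: 4}
    akg:       {C: 14, H: 28, N: 1, O: 5, Si: 2, n_labelable: 5}
  # true corrected MIDs per metabolite and condition (M+0..M+n, sum to 1)
  mid_truth:
    pyruvate:
      "basal-like:DMSO":    [0.60, 0.05, 0.00, 0.35]
      "basal-like:UK-5099": [0.58, 0.05, 0.00, 0.37]
      "classical:DMSO":     [0.45, 0.05, 0.00, 0.50]
      "classical:UK-5099":  [0.43, 0.05, 0.00, 0.52]
    lactate:
      "basal-like:DMSO":    [0.55, 0.05, 0.00, 0.40]
      "basal-like:UK-5099": [0.53, 0.05, 0.00, 0.42]
      "classical:DMSO":     [0.40, 0.05, 0.00, 0.55]
      "classical:UK-5099":  [0.38, 0.05, 0.00, 0.57]
    glyc3p:
      "basal-like:DMSO":    [0.65, 0.05, 0.00, 0.30]
      "basal-like:UK-5099": [0.71, 0.05, 0.00, 0.24]
      "classical:DMSO":     [0.50, 0.05, 0.00, 0.45]
      "classical:UK-5099":  [0.54, 0.05, 0.00, 0.41]
    citrate:
      "basal-like:DMSO":    [0.55, 0.05, 0.25, 0.05, 0.05, 0.03, 0.02]
      "basal-like:UK-5099": [0.68, 0.05, 0.12, 0.05, 0.05, 0.03, 0.02]
      "classical:DMSO":     [0.48, 0.05, 0.32, 0.05, 0.05, 0.03, 0.02]
      "classical:UK-5099":  [0.50, 0.05, 0.30, 0.05, 0.05, 0.03, 0.02]
    malate:
      "basal-like:DMSO":    [0.63, 0.05, 0.22, 0.05, 0.05]
      "basal-like:UK-5099": [0.75, 0.05, 0.10, 0.05, 0.05]
      "classical:DMSO":     [0.55, 0.05, 0.30, 0.05, 0.05]
      "classical:UK-5099":  [0.59, 0.05, 0.26, 0.05, 0.05]
    akg:
      "basal-like:DMSO":    [0.57, 0.05, 0.28, 0.04, 0.03, 0.03]
      "basal-like:UK-5099": [0.73, 0.05, 0.12, 0.04, 0.03, 0.03]
      "classical:DMSO":     [0.63, 0.05, 0.22, 0.04, 0.03, 0.03]
      "classical:UK-5099":  [0.65, 0.05, 0.20, 0.04, 0.03, 0.03]

expression:
  n_samples: {basal-like: 50, classical: 50}
  n_pairs: 8
  n_background: 184
  base_mean: 100.0           # NB mean of an unperturbed gene
  pair_margin: 4.0           # fold separation between pair genes
  dispersion: 0.1            # NB dispersion alpha (var = mu + alpha mu^2)
  length_range: [500, 5000]  # gene lengths, bp
  model_weight: 2.0          # logistic weight per pair
  # intercept = -model_weight * n_pairs / 2 -> score 0.5 at a split vote

tma:
  n_cases: 252
  mixture:                   # case-level latent H-score mixture
    w_low: 0.35
    low_mean: 30.0
    low_sd: 15.0
    high_mean: 150.0
    high_sd: 60.0
  pct_increment: 5           # pathologist scoring granularity, percent
  second_core_attenuation: [0.5, 1.0]
  true_cut: 55.0
  base_hazard: 0.0315        # events/month in the high-score group
  hazard_ratio: 2.5          # low-score group hazard multiplier
  censor_rate: 0.02          # exponential censoring, events/month (~30% censored)
  covariates:                # P(level | low group), P(level | high group)
    grade_probs_low:  [0.10, 0.46, 0.44]
    grade_probs_high: [0.20, 0.63, 0.17]
    lvi:  [0.67, 0.51]
    pni:  [0.99, 0.87]
    basal: [0.50, 0.25]
  subtype_available_frac: 0.65
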
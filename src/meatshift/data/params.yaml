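# Default model parameters: four race-sex subgroup blocks plus shared
# price elasticities of demand for meats.
#
# Notes:
# - bmi_band_probs are the published rounded percentages transcribed
#   verbatim; two columns sum to 0.99/1.01 and are renormalized when used
#   as a sampling distribution.
# - cross is an aggregate cross-price elasticity of non-meat calories with
#   respect to meat price; it is a placeholder magnitude, used only when a
#   scenario switches the complementarity channel on (base case: off).
elasticities:
  red: -0.52
  white: -0.46
  seafood: -0.53
  cross: -0.1
subtype_split: [0.3333333333333333, 0.3333333333333333, 0.3333333333333334]
elasticity_form: linear
meat_share_mode: sampled
subgroups:
  white_male:
    bmi_band_probs: [0.03, 0.24, 0.38, 0.35]
    meat_share: {mean: 0.178, ci_low: 0.158, ci_high: 0.198}
    utilities: [0.90, 0.87, 0.85]
    rr_by_band: [1.37, 1.31, 1.12, 1.00, 1.01, 1.11, 1.30, 1.63, 1.92]
    yearly_kcal_increase: 5.7
  black_male:
    bmi_band_probs: [0.04, 0.28, 0.30, 0.39]
    meat_share: {mean: 0.229, ci_low: 0.204, ci_high: 0.253}
    utilities: [0.88, 0.89, 0.83]
    rr_by_band: [1.58, 1.58, 1.14, 1.00, 1.02, 1.03, 1.18, 1.31, 1.31]
    yearly_kcal_increase: 12.3
  white_female:
    bmi_band_probs: [0.04, 0.35, 0.27, 0.34]
    meat_share: {mean: 0.153, ci_low: 0.133, ci_high: 0.173}
    utilities: [0.88, 0.87, 0.83]
    rr_by_band: [1.42, 1.10, 1.00, 1.00, 1.07, 1.16, 1.30, 1.60, 2.06]
    yearly_kcal_increase: 4.7
  black_female:
    bmi_band_probs: [0.03, 0.17, 0.26, 0.53]
    meat_share: {mean: 0.215, ci_low: 0.192, ci_high: 0.238}
    utilities: [0.85, 0.85, 0.74]
    rr_by_band: [1.52, 1.21, 1.07, 1.00, 1.09, 1.19, 1.27, 1.49, 1.69]
    yearly_kcal_increase: 8.7
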
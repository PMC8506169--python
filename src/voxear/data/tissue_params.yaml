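# Tissue parameter library, version 1.
#
# Per-organ constants of the mechanistic risk-equivalent-dose (RED) models:
#   alpha    cell-kill coefficient of the linear-quadratic model [Gy^-1]
#   repopulation_R  repopulation/repair parameter in [0, 1]
#                   (0 = no recovery between fractions, 1 = full recovery)
#   beta_ear low-dose slope of the excess-absolute-risk curve
#            [(10,000 person-years Gy)^-1], from atomic-bomb-survivor (LSS) fits
#   beta_sigma_minus / beta_sigma_plus  asymmetric 1-sigma uncertainties on
#            beta_ear (symmetrised to max(-s, +s) when sampling)
#
# model_kind:
#   carcinoma  full carcinoma-induction RED model
#   sarcoma    sarcoma-induction RED model (bone, soft tissue); full tissue
#              recovery is assumed, so repopulation_R is fixed at 1
#   zero_risk  organs with negligible second-solid-cancer risk; every EAR
#              evaluation returns exactly 0
#
# The spleen is deliberately absent: its dose-response is considered too
# uncertain to model, and it is reported as excluded rather than zero-risk.
version: 1
alpha_beta_ratio: 3.0
organs:
  breast:
    model_kind: carcinoma
    alpha: 0.0440
    alpha_sigma: 0.0950
    repopulation_R: 0.1500
    R_sigma: 0.0700
    beta_ear: 8.2
    beta_sigma_minus: 1.05
    beta_sigma_plus: 1.4
  oesophagus:
    # fitted with stomach values
    model_kind: carcinoma
    alpha: 0.4600
    alpha_sigma: 0.0750
    repopulation_R: 0.4600
    R_sigma: 0.2250
    beta_ear: 3.2
    beta_sigma_minus: 1.1
    beta_sigma_plus: 1.45
  heart:
    model_kind: zero_risk
  liver:
    model_kind: carcinoma
    alpha: 0.3230
    alpha_sigma: 0.9050
    repopulation_R: 0.2900
    R_sigma: 0.0950
    beta_ear: 2.4
    beta_sigma_minus: 1.2
    beta_sigma_plus: 0.8
  lungs:
    model_kind: carcinoma
    alpha: 0.0420
    alpha_sigma: 0.0550
    repopulation_R: 0.8300
    R_sigma: 0.0750
    beta_ear: 8.0
    beta_sigma_minus: 1.25
    beta_sigma_plus: 1.5
  pharynx:
    model_kind: carcinoma
    alpha: 0.0430
    alpha_sigma: 0.0095
    repopulation_R: 0.9700
    R_sigma: 0.0700
    beta_ear: 0.73
    beta_sigma_minus: 0.215
    beta_sigma_plus: 0.435
  spinal_cord:
    # beta rescaled from "Brain and CNS" to the spinal-cord partial volume
    model_kind: carcinoma
    alpha: 0.0180
    alpha_sigma: 0.0085
    repopulation_R: 0.9300
    R_sigma: 0.2550
    beta_ear: 0.04
    beta_sigma_minus: 0.015
    beta_sigma_plus: 0.019
  stomach:
    model_kind: carcinoma
    alpha: 0.4600
    alpha_sigma: 0.0750
    repopulation_R: 0.4600
    R_sigma: 0.2250
    beta_ear: 5.2
    beta_sigma_minus: 0.9
    beta_sigma_plus: 1.25
  thyroid:
    model_kind: carcinoma
    alpha: 0.0318
    alpha_sigma: 0.0075
    repopulation_R: 0.0000
    R_sigma: 0.0000
    beta_ear: 0.4
    beta_sigma_minus: 0.1
    beta_sigma_plus: 0.2
  vessels:
    model_kind: zero_risk
  bone:
    model_kind: sarcoma
    alpha: 0.078
    alpha_sigma: 4.3e-4
    repopulation_R: 1.0
    R_sigma: 0.0
    beta_ear: 0.1
    beta_sigma_minus: 4.3e-4
    beta_sigma_plus: 4.3e-4
  soft_tissue:
    model_kind: sarcoma
    alpha: 0.093
    alpha_sigma: 2.03e-4
    repopulation_R: 1.0
    R_sigma: 0.0
    beta_ear: 0.35
    beta_sigma_minus: 2.03e-4
    beta_sigma_plus: 2.03e-4
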
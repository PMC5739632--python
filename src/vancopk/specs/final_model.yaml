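# Published final population PK model of vancomycin in neonates / young infants.
# Two-compartment IV-infusion model; CL(l/h) = 0.42 * (BBW/3.22)^0.888
# * (PNA/29)^0.449 * exp(eta_CL); additive residual error, SD 2.187 ug/mL.
structural: 2cmt
typical:
  V1: 1.27
  V2: 2.422
  CL: 0.42
  Q: 1.161
effects:
- parameter: CL
  covariate: BBW
  exponent: 0.888
  kind: continuous
  reference: 3.22
- parameter: CL
  covariate: PNA
  exponent: 0.449
  kind: continuous
  reference: 29.0
iiv:
  CL: 0.317
residual:
  kind: additive
  sd0: 2.187
  cv: 0.0
infusion_duration_default: 1.0
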
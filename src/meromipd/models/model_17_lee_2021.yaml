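name: model_17_lee_2021
n_compartments: 2
theta:
  cl: 6.37
  vc: 9.07
  q2: 10.7
  vp2: 7.91
relations:
- target: cl
  covariate: egfr_ckdepi
  form: linear_proportional
  reference_value: 91.6
  coefficient: 1.0
eta_names:
- cl
- vc
omega:
- - 0.09
  - 0.0
- - 0.0
  - 0.0625
residual:
  kind: combined
  sigma_add: 0.5
  sigma_prop: 0.2
source_note: 'Approximate encoding of Lee et al. 2021 (ECMO, sepsis and nosocomial
  infection): typical values from the published summary table; covariate relation
  forms/coefficients and variance components are placeholders (exact equations live
  in the source publication).'
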
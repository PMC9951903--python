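name: model_15_lan_2022
n_compartments: 2
theta:
  cl: 7.48
  vc: 15.9
  q2: 26.0
  vp2: 35.3
relations:
- target: cl
  covariate: egfr_ckdepi
  form: linear_proportional
  reference_value: 35.69
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
source_note: 'Approximate encoding of Lan et al. 2022 (critically ill pneumonia):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
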
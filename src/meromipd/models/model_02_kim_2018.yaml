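name: model_02_kim_2018
n_compartments: 1
theta:
  cl: 16.7
  vc: 30.7
relations:
- target: cl
  covariate: serum_creatinine
  form: power
  reference_value: 88.4
  coefficient: -1.0
- target: vc
  covariate: weight_total
  form: linear_proportional
  reference_value: 62.8
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
source_note: 'Approximate encoding of Kim et al. 2018 (sepsis/severe sepsis): typical
  values from the published summary table; covariate relation forms/coefficients and
  variance components are placeholders (exact equations live in the source publication).
  Serum creatinine reference 88.4 umol/L (1.0 mg/dL).'
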
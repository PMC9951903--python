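name: model_03_usman_2016
n_compartments: 2
theta:
  cl: 5.27
  vc: 17.2
  q2: 9.92
  vp2: 10.6
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 39.0
  coefficient: 1.0
- target: cl
  covariate: weight_ideal
  form: power
  reference_value: 75.0
  coefficient: 0.75
- target: vc
  covariate: weight_ideal
  form: linear_proportional
  reference_value: 75.0
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
source_note: 'Approximate encoding of Usman et al. 2016 (elderly critically ill):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
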
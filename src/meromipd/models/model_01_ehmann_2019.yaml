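name: model_01_ehmann_2019
n_compartments: 2
theta:
  cl: 9.25
  vc: 7.89
  q2: 28.4
  vp2: 16.1
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 80.8
  coefficient: 1.0
- target: vc
  covariate: weight_total
  form: linear_proportional
  reference_value: 70.5
  coefficient: 1.0
- target: vc
  covariate: albumin
  form: power
  reference_value: 25.0
  coefficient: -0.5
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
source_note: 'Approximate encoding of Ehmann et al. 2019 (critically ill, non-RRT):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
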
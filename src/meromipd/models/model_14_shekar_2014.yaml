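name: model_14_shekar_2014
n_compartments: 2
theta:
  cl: 5.1
  vc: 18.7
  q2: 21.0
  vp2: 13.2
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 106.0
  coefficient: 1.0
- target: cl
  covariate: rrt
  form: categorical_factor
  reference_value: 1.0
  coefficient: 0.8
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
source_note: 'Approximate encoding of Shekar et al. 2014 (ECMO, sepsis): typical values
  from the published summary table; covariate relation forms/coefficients and variance
  components are placeholders (exact equations live in the source publication).'
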
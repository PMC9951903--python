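name: model_04_chung_2016
n_compartments: 2
theta:
  cl: 9.13
  vc: 14.3
  q2: 15.9
  vp2: 17.7
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 82.0
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
source_note: 'Approximate encoding of Chung et al. 2016 (obese and non-obese ICU):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
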
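name: model_18_alsultan_2021
n_compartments: 1
theta:
  cl: 6.4
  vc: 30.0
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 95.0
  coefficient: 1.0
- target: vc
  covariate: weight_total
  form: linear_proportional
  reference_value: 74.0
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
source_note: 'Approximate encoding of Alsultan et al. 2021 (ICU bacterial infection):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
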
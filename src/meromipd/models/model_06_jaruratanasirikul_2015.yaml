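name: model_06_jaruratanasirikul_2015
n_compartments: 1
theta:
  cl: 7.82
  vc: 23.7
relations:
- target: cl
  covariate: clcr_mdrd
  form: linear_proportional
  reference_value: 59.43
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
source_note: 'Approximate encoding of Jaruratanasirikul et al. 2015 (severe sepsis/septic
  shock): typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
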
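name: model_11_roberts_2009
n_compartments: 2
theta:
  cl: 13.6
  vc: 7.9
  q2: 56.3
  vp2: 14.8
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 100.0
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
source_note: 'Approximate encoding of Roberts et al. 2009 (critically ill, sepsis):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).'
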
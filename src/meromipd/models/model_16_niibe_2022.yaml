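name: model_16_niibe_2022
n_compartments: 2
theta:
  cl: 9.3
  vc: 12.6
  q2: 9.7
  vp2: 7.8
relations:
- target: cl
  covariate: crp
  form: power
  reference_value: 190.0
  coefficient: -0.2
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
source_note: 'Approximate encoding of Niibe et al. 2022 (respiratory/intra-abdominal
  infection; no renal covariate): typical values from the published summary table;
  covariate relation forms/coefficients and variance components are placeholders (exact
  equations live in the source publication).'
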
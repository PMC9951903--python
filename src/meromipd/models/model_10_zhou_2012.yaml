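name: model_10_zhou_2012
n_compartments: 2
theta:
  cl: 8.98
  vc: 16.1
  q2: 15.9
  vp2: 12.0
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 53.4
  coefficient: 1.0
- target: q2
  covariate: apache_ii
  form: linear_proportional
  reference_value: 20.0
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
source_note: 'Approximate encoding of Zhou et al. 2012 (elderly lower respiratory
  tract infection): typical values from the published summary table; covariate relation
  forms/coefficients and variance components are placeholders (exact equations live
  in the source publication).'
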
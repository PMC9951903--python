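name: model_13_li_2006
n_compartments: 2
theta:
  cl: 14.6
  vc: 10.8
  q2: 18.6
  vp2: 12.6
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 85.0
  coefficient: 1.0
- target: vc
  covariate: weight_total
  form: linear_proportional
  reference_value: 70.0
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
source_note: 'Approximate encoding of Li et al. 2006 (intra-abdominal infection and
  pneumonia): typical values from the published summary table; covariate relation
  forms/coefficients and variance components are placeholders (exact equations live
  in the source publication). Source prints creatinine only (median 1.0 mg/dL); CG
  reference 85 mL/min derived for the typical patient.'
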
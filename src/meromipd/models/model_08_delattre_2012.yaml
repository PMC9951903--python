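name: model_08_delattre_2012
n_compartments: 2
theta:
  cl: 9.87
  vc: 24.4
  q2: 4.97
  vp2: 7.01
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 80.0
  coefficient: 1.0
- target: cl
  covariate: weight_total
  form: power
  reference_value: 70.0
  coefficient: 0.75
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
source_note: 'Approximate encoding of Delattre et al. 2012 (severe sepsis/septic shock):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).
  Renal-function median unreported; reference 80 mL/min assumed.'
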
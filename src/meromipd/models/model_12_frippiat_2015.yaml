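name: model_12_frippiat_2015
n_compartments: 3
theta:
  cl: 10.2
  vc: 5.2
  q2: 6.9
  vp2: 12.1
  q3: 66.5
  vp3: 11.3
relations:
- target: cl
  covariate: crcl_cg
  form: linear_proportional
  reference_value: 80.0
  coefficient: 1.0
- target: vc
  covariate: weight_total
  form: linear_proportional
  reference_value: 78.4
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
source_note: 'Approximate encoding of Frippiat et al. 2015 (nosocomial pneumonia):
  typical values from the published summary table; covariate relation forms/coefficients
  and variance components are placeholders (exact equations live in the source publication).
  Epithelial-lining-fluid compartment simplified to a plasma-side third compartment;
  renal-function median unreported, reference 80 mL/min assumed.'
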
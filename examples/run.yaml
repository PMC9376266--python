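# baseline run; pass --dataset data.csv or add a `synth:` block here
v_on: 0.001
e_mag: 1.0
k_input: 4
eval_every: 10
seed_sequence: 1
seed_ties: 2
behaviors:
  predictive: {enabled: false, p_th: 6}
  erase:      {enabled: false, r_th: 400}
  forgetting: {enabled: false, d_rate: 0.015}
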
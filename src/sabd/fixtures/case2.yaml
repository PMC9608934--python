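# Case study 2: different hypotheses per endpoint (response 0.30 -> 0.60,
# non-toxicity 0.60 -> 0.90), identical across subgroups.
label: case2
hypotheses:
  p_r0: 0.30
  p_t0: 0.60
  p_r1_neg: 0.60
  p_r1_pos: 0.60
  p_t1_neg: 0.90
  p_t1_pos: 0.90
  alpha_r: 0.10
  alpha_t: 0.10
  beta: 0.20
design:
  n1_neg: 9
  n_neg: 23
  k_r1_neg: 4
  k_t1_neg: 7
  k_r_neg: 11
  k_t_neg: 18
  n1_pos: 9
  n_pos: 16
  ne_pos: 21
  k_r1_pos: 4
  k_t1_pos: 7
  k_r_pos: 8
  k_t_pos: 13
  k_re_pos: 10
  k_te_pos: 16
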
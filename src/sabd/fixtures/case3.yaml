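# Case study 3: different hypotheses per endpoint and, for non-toxicity,
# per subgroup (acceptable 0.80 negative vs 0.90 positive).
label: case3
hypotheses:
  p_r0: 0.10
  p_t0: 0.60
  p_r1_neg: 0.40
  p_r1_pos: 0.40
  p_t1_neg: 0.80
  p_t1_pos: 0.90
  alpha_r: 0.10
  alpha_t: 0.10
  beta: 0.20
design:
  n1_neg: 17
  n_neg: 35
  k_r1_neg: 3
  k_t1_neg: 12
  k_r_neg: 7
  k_t_neg: 26
  n1_pos: 9
  n_pos: 10
  ne_pos: 16
  k_r1_pos: 2
  k_t1_pos: 7
  k_r_pos: 3
  k_t_pos: 9
  k_re_pos: 4
  k_te_pos: 13
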
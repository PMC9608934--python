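# Case study 1: feasibility of chemotherapy in older prostate-cancer
# patients stratified as frail (negative) vs vulnerable/fit (positive).
# Identical hypotheses for both endpoints and subgroups.
label: case1
hypotheses:
  p_r0: 0.70
  p_t0: 0.70
  p_r1_neg: 0.90
  p_r1_pos: 0.90
  p_t1_neg: 0.90
  p_t1_pos: 0.90
  alpha_r: 0.10
  alpha_t: 0.10
  beta: 0.20
design:
  n1_neg: 10
  n_neg: 35
  k_r1_neg: 8
  k_t1_neg: 8
  k_r_neg: 29
  k_t_neg: 29
  n1_pos: 10
  n_pos: 32
  ne_pos: 35
  k_r1_pos: 8
  k_t1_pos: 8
  k_r_pos: 27
  k_t_pos: 27
  k_re_pos: 29
  k_te_pos: 29
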
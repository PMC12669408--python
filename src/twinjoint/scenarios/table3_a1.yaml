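name: table3_a1
sim:
  n_pairs: 2000
  beta0: 1.0
  beta1: 0.01
  sigma_b: 0.1
  sigma_u: 0.1
  theta: 0.5
  weibull_shape: 2.0
  weibull_scale: 0.001
  censor_upper: 15.0
  delay_prob: 0.5
  delay_upper: 5.0
  alpha: 1.0
  sigma_e: 0.1
  grid_scheme: sparse
  grid_max_k: 3
methods:
- locf
- rrc
- orc
- jm
n_reps: 1000
base_seed: 20251014
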
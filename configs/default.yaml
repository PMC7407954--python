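learning:
  mu: 0.16
  instar_scale: 0.03
  hippocampal_scale: 0.3
  output_rule: gradient
  error_deadzone: 0.1
  outstar_target_mode: literal
  error_sign: descent
  eps_clamp: false
coupling:
  lambda_init: 1.0
  lambda_trial: 0.02
  noise_sigma: 0.0
  novelty_gain: 1.8
  novelty_floor: 0.2
criterion:
  hi: 0.85
  lo: 0.18
  consecutive: 3
  max_trials: 500
init:
  out_w_scale: 1.0
  out_eps_low: -4.0
  out_eps_high: -2.0
battery:
  q: 16
  n_seeds: 25
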
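# Two-window cohort with a steepness-reduction effect during offer2 only.
seed: 7

design:
  q_max_a: 2
  q_max_b: 6
  n_trials: 400
  stim_fraction: 0.5
  n_offer_types: 8
  # List-valued fields are sampled per session, e.g.:
  # q_max_b: [5, 6, 7]

conditions:
  - window: offer1
    level: "15uA"
    n_sessions: 49
    truth:
      rho: 2.2
      eta: 2.5
      epsilon: -0.25
      theta_juice: 0.2
      error_rate_off: 0.06
      error_rate_on: 0.06
  - window: offer2
    level: "15uA"
    n_sessions: 42
    truth:
      rho: 2.2
      eta: 2.5
      epsilon: -0.25
      theta_juice: 0.2
      error_rate_off: 0.06
      error_rate_on: 0.06
      stim:
        eta_gain: 0.6       # steepness multiplier on stimON trials
        # value_shift_gain: 0.1   # fraction of each value range added
        # delta_epsilon: 0.0      # additive order-bias shift

analysis:
  outlier_k: 3.0
  ellipse_level: 0.90
  alpha: 0.01
  wilcoxon_variant: signed_rank
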
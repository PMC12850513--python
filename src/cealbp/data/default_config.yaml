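# Default model inputs: chronic low back pain, pharmacopuncture (PPT) vs
# physiotherapy (PT).  All monetary values in USD unless currency: KRW, in
# which case they are divided by model.krw_per_usd at load time.
currency: USD

model:
  cycle_length_years: 0.25
  horizon_cycles: 12
  annual_discount_rate: 0.045
  initial_distribution: {mild: 0.0, moderate: 0.12, severe: 0.88}
  wtp_krw: 30500000
  krw_per_usd: 1144.61
  # Conventions selected by the calibration harness (see `cealbp calibrate`):
  # the 2-cycle mild row applied per cycle, trapezoidal (half-cycle) accrual,
  # discounting to cycle start.
  mild_handling_mode: direct
  cycle_correction: half_cycle
  discount_timing: cycle_start

transitions:
  mild_interval_cycles: 2   # the mild row is a 2-cycle quantity
  PPT:
    mild:     {probs: [0.731, 0.268, 0.001], alphas: [20.995, 7.686, 0.022]}
    moderate: {probs: [0.472, 0.334, 0.194], alphas: [2.614, 1.618, 1.034]}
    severe:   {probs: [0.612, 0.321, 0.067], alphas: [22.413, 11.299, 3.048]}
  PT:
    mild:     {probs: [0.731, 0.268, 0.001], alphas: [20.995, 7.686, 0.022]}
    moderate: {probs: [0.052, 0.765, 0.183], alphas: [0.125, 3.198, 0.954]}
    severe:   {probs: [0.209, 0.569, 0.222], alphas: [6.572, 20.097, 13.346]}

costs:
  PPT:
    medical_components:
      consultation: 80.01
      syndrome_differentiation: 17.42
      therapy: 201.34
    transport: 4.32
    time: {mean: 183.83, se: 12.15}
  PT:
    consultation: 107.53
    scenarios:
      - {cost: 43.83, weight: 0.25, beta: [62183.0, 186549.0]}
      - {cost: 47.23, weight: 0.61, beta: [151727.0, 97005.0]}
      - {cost: 61.40, weight: 0.08, beta: [19899.0, 228833.0]}
      - {cost: 64.80, weight: 0.06, beta: [14924.0, 233808.0]}
    transport: 5.46
    time: {mean: 209.40, se: 14.14}
  transport_se_fraction: 0.10   # transportation sampled with SE = 10% of mean

productivity_loss:
  mild:     {mean: 1645.46, se: 123.74}
  moderate: {mean: 2585.98, se: 92.96}
  severe:   {mean: 3405.16, se: 108.29}

utilities:
  # value: state utility; qaly_beta: Beta pair whose mean is the per-cycle
  # QALY weight (utility x 0.25), sampled directly in the PSA.
  mild:     {value: 0.837, qaly_beta: [3009.990, 11377.064]}
  moderate: {value: 0.782, qaly_beta: [3738.664, 15392.143]}
  severe:   {value: 0.750, qaly_beta: [2683.764, 11641.459]}

psa:
  n_iterations: 1000
  seed: 2026
  wtp_grid: {start: 0.0, stop: 60000.0, step: 500.0}

dsa:
  discount_rate: {low: 0.035, high: 0.060}
  horizon_years: {low: 1.0, high: 5.0}
  initial_severe_share: {delta: 0.03}
  qaly_weight_delta: 0.003
  # Per-element deltas for transition rows, ordered (to mild, moderate, severe).
  transition_deltas:
    mild: [0.081, 0.081, 0.010]
    PPT:
      moderate: [0.195, 0.195, 0.157]
      severe:   [0.079, 0.078, 0.037]
    PT:
      moderate: [0.121, 0.186, 0.155]
      severe:   [0.071, 0.082, 0.053]

trial:
  n_per_arm: 50
  baseline_distribution: {moderate: 0.12, severe: 0.88}
  utility_sd: 0.08
  utility_noise: truncated_normal
  seed: 7
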
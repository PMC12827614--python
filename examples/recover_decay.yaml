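# Parameter-recovery experiment for the attention-decay model:
# simulate 50 noisy replicates from known parameters, fit each, and
# report per-parameter bias and RMSE.
format_version: "1.0"
command: recover
seed: 5
model: decay
n_replicates: 50
params:
  initial_level: 1.0
  base_rate: 0.08
  monotony_sensitivity: 0.7
  reward_sensitivity: 0.9
# three separate task sessions (reset: each starts at the initial level),
# giving a well-conditioned three-condition design
schedule:
  units: minutes
  segments:
    - {start: 0,  end: 40,  context: {monotony: 0.9, reward: 0.1}}
    - {start: 40, end: 80,  context: {monotony: 0.1, reward: 0.8}, reset: true}
    - {start: 80, end: 120, context: {monotony: 0.5, reward: 0.5}, reset: true}
grid: {start: 0.0, stop: 119.0, num: 60}
noise: {family: gaussian, sd: 0.05}
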
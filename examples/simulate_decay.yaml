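# Simulate one subject's sustained-attention trajectory across three
# task segments (monotonous -> rewarding -> mixed), minutes timescale.
format_version: "1.0"
command: simulate
seed: 7
model: decay
params:
  initial_level: 1.0
  base_rate: 0.06          # 1/min
  monotony_sensitivity: 1.0
  reward_sensitivity: 1.0
schedule:
  units: minutes
  segments:
    - {start: 0,  end: 40,  context: {monotony: 0.9, reward: 0.1}}
    - {start: 40, end: 80,  context: {monotony: 0.1, reward: 0.9}}
    - {start: 80, end: 120, context: {monotony: 0.5, reward: 0.5}}
grid: {start: 0.0, stop: 119.0, num: 120}
noise: {family: gaussian, sd: 0.02}
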
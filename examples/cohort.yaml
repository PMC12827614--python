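# Generate a small synthetic EMA cohort: ADHD-like and control-like
# groups with the default (synthetic, non-empirical) priors.
format_version: "1.0"
command: generate-cohort
seed: 42
n_subjects_per_group: 10
segment_durations: [30.0, 30.0, 30.0, 30.0]   # minutes
dt: 1.0
noise: {family: gaussian, sd: 0.05}
missingness_rate: 0.1
battery: {n_delays: 6, n_amount_ratios: 5}
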
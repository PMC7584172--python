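# Selection operating characteristics across community effect sizes
# (log-odds per SD of exposure; one signal variable per domain).
experiment: effect_recovery
effect_grid: [0.0, 0.25, 0.5]
reps: 10
seed: 0
n_hospitals: 300
n_discharges: 30000
n_variables_per_domain: 5
n_trees: 500
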
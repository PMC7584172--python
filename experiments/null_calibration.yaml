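# Type-I-error calibration: every community effect zero.
experiment: null_calibration
n_hospitals: 1000
n_discharges: 30000
reps: 20
seed: 0
n_variables_per_domain: 5
n_trees: 500
alpha: 0.05
tau: 0.3
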
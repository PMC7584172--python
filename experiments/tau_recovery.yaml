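# Recovery of the hospital random-intercept SD and covariate effects.
experiment: tau_recovery
n_hospitals: 300
discharges_per_hospital: 300
tau: 0.3
n_seeds: 5
seed: 0
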
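# Study configuration for progdelay. Every key is optional; packaged
# defaults fill the gaps. Replace placebo_means/covariance with real
# cohort estimates to simulate from them.
visit_months: [0, 6, 12, 18, 24, 36]
placebo_means: [1.5, 1.72, 2.0, 2.29, 2.67, 3.5]
slowing_fraction: 0.20
n_per_arm: [300, 700]
duration_months: [18, 36]
n_replicates: 100
seed: 0
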
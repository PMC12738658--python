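; Bayesian calibration of the nonlocal colony-growth model on synthetic
; radius measurements (generated at the [model] parameter values).
[model]
name = colony
alpha = 0.3
sigma_k = 1.5
sigma_s = 2.0
sigma_o = 0.05
n_r = 120

[likelihood]
mode = bayes
data_seed = 12345

[sampler]
algorithm = adaptive_metropolis
steps = 4000
t0 = 200
seed = 1

[output]
dir = results/colony
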
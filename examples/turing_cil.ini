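; CIL inference of the inhibitor diffusivity of the Schnakenberg model from
; synthetic pattern ensembles (training data simulated at the values below).
[model]
name = turing
grid_n = 32
grid_length = 50.0
t_int = 150.0

[likelihood]
mode = cil
m_bins = 8
n_ens = 12
n_per_subset = 8
infer = d_v

[sampler]
algorithm = metropolis
step_s = 0.005
steps = 1000
seed = 1

[output]
dir = results/turing
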
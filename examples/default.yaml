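# Default configuration, written out in full. Every key is optional;
# omitted keys fall back to these values.

# network geometry and connectivity
n: 1000
angle_min: -50.0
angle_max: 50.0
m1: 28.0        # excitatory strength
m2: 10.0        # inhibitory strength
sigma1: 1.5     # excitation range, deg
sigma2: 3.0     # inhibition range, deg
mode: linear    # linear | squared divisive normalization

# dynamics
input_steps: 5
max_steps: 100
tol: 1.0e-9

# readout
threshold_frac: 0.1
min_sep: 3.0
assign_rule: nearest   # nearest | weakest auditory-bump rule

# stimulus (input bumps and sensory noise)
m_v: 10.0
m_a: 10.0
sigma_v: 1.0
sigma_a: 2.0
sigma_vx: 3.0
sigma_ax: 6.5

# Bayesian ideal observer
p_co: 0.2
bayes_sigma_v: 3.0
bayes_sigma_a: 6.5
bayes_a: 100.0

# experiment driver
model: network-linear
disparities: [0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0]
n_trials: 500
base_seed: 0
noiseless: false
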
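# novelty-dominated regime: slow manifold with near-constant sigma/mu,
# near-exponential growth of the mean toward the fixed point at 1/2
mu = 0.02
sigma = 0.01
beta_t = 0.0
beta_n = 1.0
generations = 200
start_year = 1500
years_per_generation = 25
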
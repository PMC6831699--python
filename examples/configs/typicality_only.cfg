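# typicality-dominated regime: mean and sd both shrink, mean freezes at the mode
mu = 0.2
sigma = 0.1
beta_t = 0.5
beta_n = 0.0
generations = 200
start_year = 1500
years_per_generation = 25
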
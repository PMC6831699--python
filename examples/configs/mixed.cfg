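# both pressures active: sigma balances at an interior fixed value
# while the mean keeps drifting slowly
mu = 0.02
sigma = 0.01
beta_t = 2.0
beta_n = 0.5
generations = 200
start_year = 1500
years_per_generation = 25
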
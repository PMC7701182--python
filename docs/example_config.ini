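# Run configuration: game presets, strategy parameters, population, cohort.
# Omitted keys fall back to the shipped defaults; fractions may be written
# as "1/3".

[game.NU]
n = 6
e = 40
actions = 0 2 4
tau = 120
r = 0.9
m0 = 10
w = 1

[game.LU]
m0 = 8
w = 1/3

[game.HU]
m0 = 6
w = 1/5

[strategies]
theta = 10
reciprocal_first_action = 4
high_action = 4
low_action = 0

[population]
z = 50
beta = 0.004

[cohort]
n_groups = 12
noise_eps = 0.0
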
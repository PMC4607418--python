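# A representative peach at 808 nm: thin highly scattering skin over
# weakly scattering flesh, stone below entering as a refractive boundary.
[stack]
n_above = 1.00
n_below = 1.46

[[stack.layers]]   # skin
n = 1.337
mua = 0.075
mus = 102.0
g = 0.65
d = 0.03

[[stack.layers]]   # flesh
n = 1.342
mua = 0.024
mus = 28.4
g = 0.61
d = 2.0

[sim]
photons = 200000
seed = 1
wth = 1e-4
m = 10
dr = 0.01
dz = 0.01
nr = 400
na = 90

[beam]
profile = "gaussian"
energy_J = 0.5
radius_cm = 0.05
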
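# Default four-cluster, two-regime scenario (200 regions, 2003-2043).
#
# The "east" cluster starts with the highest support ratio (low fertility,
# a worker boom born 1945-1959, a deep 1990s bust among its children, and a
# deficit of pre-1939 elderly cohorts) but carries 2.5x working-age
# mortality and out-migration that surges sharply from 2008.  The other
# clusters age more gently through their own boom waves.  From 2013 the
# projected regime converges migration rates toward the all-region mean,
# shrinking their cross-region variance.  Region-level lognormal noise
# (sd 0.13) keeps a persistent dispersion floor within every cluster.

[scenario]
n_regions = 200
start_year = 2003
observed_until = 2013
end_year = 2043
open_age = 100
seed = 42

[[cluster]]
label = "east"
n_regions = 50
initial_size = 1.0e6
noise_sd = 0.13

[cluster.mortality]
form = "points"
points = [[0, 0.004], [1, 0.0004], [10, 0.0003], [20, 0.0008], [50, 0.003], [64, 0.008], [75, 0.032], [85, 0.1], [95, 0.26], [100, 0.42]]
working_age_multiplier = 2.5

[cluster.fertility]
form = "gaussian"
level = 0.034
mean_age = 27.0
sd_age = 5.5

[cluster.migration]
form = "gaussian"
level = -0.0030
mean_age = 26.5
sd_age = 9.0
shock_year = 2008
shock_delta = 7.0
convergence_rate = 0.20

[[cluster.wave]]
start = 1900
end = 1938
multiplier = 0.75

[[cluster.wave]]
start = 1945
end = 1959
multiplier = 1.30

[[cluster.wave]]
start = 1990
end = 1999
multiplier = 0.60

[[cluster]]
label = "west"
n_regions = 50
initial_size = 1.3e6
noise_sd = 0.13

[cluster.mortality]
form = "points"
points = [[0, 0.003], [1, 0.0003], [10, 0.0002], [20, 0.0006], [50, 0.0024], [64, 0.0065], [75, 0.028], [85, 0.09], [95, 0.24], [100, 0.4]]

[cluster.fertility]
form = "gaussian"
level = 0.058
mean_age = 29.0
sd_age = 5.5

[cluster.migration]
form = "gaussian"
level = 0.0025
mean_age = 26.5
sd_age = 9.0
shock_year = 2009
shock_delta = -2.0
convergence_rate = 0.20

[[cluster.wave]]
start = 1900
end = 1938
multiplier = 0.85

[[cluster.wave]]
start = 1950
end = 1964
multiplier = 1.20

[[cluster]]
label = "south"
n_regions = 50
initial_size = 1.1e6
noise_sd = 0.13

[cluster.mortality]
form = "points"
points = [[0, 0.003], [1, 0.0003], [10, 0.0002], [20, 0.0006], [50, 0.0024], [64, 0.0065], [75, 0.028], [85, 0.09], [95, 0.24], [100, 0.4]]

[cluster.fertility]
form = "gaussian"
level = 0.056
mean_age = 29.5
sd_age = 5.5

[cluster.migration]
form = "gaussian"
level = 0.0012
mean_age = 26.5
sd_age = 9.0
shock_year = 2009
shock_delta = -3.0
convergence_rate = 0.20

[[cluster.wave]]
start = 1900
end = 1938
multiplier = 0.85

[[cluster.wave]]
start = 1955
end = 1969
multiplier = 1.10

[[cluster]]
label = "north"
n_regions = 50
initial_size = 0.9e6
noise_sd = 0.13

[cluster.mortality]
form = "points"
points = [[0, 0.003], [1, 0.0003], [10, 0.0002], [20, 0.0006], [50, 0.0024], [64, 0.0065], [75, 0.028], [85, 0.09], [95, 0.24], [100, 0.4]]

[cluster.fertility]
form = "gaussian"
level = 0.060
mean_age = 29.0
sd_age = 5.5

[cluster.migration]
form = "gaussian"
level = 0.0015
mean_age = 26.5
sd_age = 9.0
convergence_rate = 0.20

[[cluster.wave]]
start = 1900
end = 1938
multiplier = 0.85

[[cluster.wave]]
start = 1950
end = 1964
multiplier = 1.20
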
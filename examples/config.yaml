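# Desk-scale simulation of the regenerating ependymal strip.
# Units at this surface: D in um^2/s, k in 1/day, lengths in um, times in days.
D: 1.0               # signal diffusion coefficient
k: 1.0               # signal degradation rate (half-life ln2/k days)
rho0: 60.0           # signal density imposed at the regenerating front
rhosmin: 3.0         # recruitment threshold (sensitivity = 1/rhosmin)
rho_star: null       # diffusion-velocity regularization (null -> rho0/100)
particle_mass: 240.0 # signal mass per particle (rho0/m = source number density)
h_um: null           # SPH kernel support (null -> 4R)
R_um: 7.0            # cell radius
L0_um: 400.0         # initial tissue length
ymin_um: 0.0
ymax_um: 56.0        # circumference (must be >= 2h for periodic kernel sums)
kappa: 1.0           # hard-disc repulsion intensity
cycle:
  mu_slow: 340.0     # slow cycle mean, h
  sd_slow: 32.0
  mu_fast: 119.0     # fast (recruited) cycle mean, h
  sd_fast: 10.0
  frac_slow: [0.45, 0.40, 0.15]   # G1 / S / G2+M shares (placeholders)
  frac_fast: [0.20, 0.60, 0.20]
division_model: clock   # 'clock' (lognormal timers) or 'poisson'
t_end_days: 6.0
record_every_days: 0.2
snapshot_days: [2.0, 4.0, 6.0]
seed: 42
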
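# 2D flapping-leaflet valve demo: one full 1.124 s cardiac cycle in a
# desk-scale channel.  Lengths in [geometry] are millimeters, SI elsewhere.

kind = "channel2d"
duration = 1.124
seed = 0

[geometry]
channel_length = 80.0
channel_height = 20.0
leaflet_length = 17.0
leaflet_thickness = 1.5
mesh_size = 2.0

[material]
rho_fluid = 1060.0
rho_solid = 1000.0
mu_f = 0.0027
mu_s = 1.0e6        # soft-tissue scale so the leaflet flexes at desk scale

[cycle]
T_cycle = 1.124
T_systole = 0.4
T_reversal = 0.05
U_peak = 0.5
U_reversal = 0.3

[solver]
cfl_target = 0.5
cfl_floor = 0.01
dt_max = 0.003
kappa1 = 1.0
kappa2 = 1.0
picard_tol = 1e-6
krylov = "direct"

[smoothing]
pseudo_steps = 30
quality_trigger = 3.0
max_quality = 100.0

[contact]
enabled = true
threshold = 0.0045   # m; ~2.2x the local cell diameter at the free edge
method = "geometric"

[output]
directory = "out_leaflet2d"
store_every = 0
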
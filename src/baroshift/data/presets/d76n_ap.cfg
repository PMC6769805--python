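# D76N_AP: amyloidogenic mutant at ambient pressure — converged local
# ensemble (one subensemble), suppressed peripheral motion, aggregation
# channel active during exchange.  Shares param_seed with WT_AP so the
# mutation contrast is exactly the planted offsets.

[meta]
name = D76N_AP
description = D76N mutant, ambient pressure: single subensemble, damped periphery
sequence = IQRTPKIQVYSRHPAENGKSNFLNCYVSGFHPSDIEVDLLKNGERIEKVEHSDLSFSKDWSFYLLYYTEFTPTEKNEYACRVNHVTLSQPKIVKWDRDM
param_seed = 20190916

[pressure]
pressures = 5 25 50 75 100 125 150 175 200 225
excluded_residues = 1 5 11 18 24 31 37 44 50 58 60 70 77 83 88 92 96
temperature_k = 298.15
dg0_j_per_mol = 12000
dv_ml_per_mol = -100
slope_sd_h = 0.0010
slope_sd_n = 0.0040
amp_sd_h = 0.10
amp_sd_n = 0.40
noise_sd_h = 0.002
mutation_offset_residues = 41 55 63 76 78
mutation_offset_h = 0.12
mutation_offset_n = 0.60

[chain]
n_states = 1
transition = 1.0
initial = uniform

[dihedrals]
kappa = 8.0
coupled_residues = 41 55 76
coupled_shift_deg = 60

[distance]
state_means = 4.0
state_sds = 0.4

[modes]
mode_amp_sd = 0.5
noise_sd = 0.25

[r2]
delays_ms = 17.6 52.8 88.0 123.2 158.4 193.6 228.8
baseline_rate = 12.0
elevated_residues =
elevated_rate = 22.0
noise_sd = 0.01

[exchange]
pd_reading = 5.1
temperature_k = 298.15
core_residues = 22 23 24 25 26 62 63 64 78 79 80
loop_residues = 8 17 28 48 59 85
k_ex_core_per_min = 0.001
k_ex_loop_per_min = 0.05
k_agg_per_min = 0.02
times_min = 0 20 40 60 90 120 180 240 360 480 720 1440
noise_sd = 0.01

[unfolding]
midpoint_ph = 4.54
slope = 2.0
s_folded = 1.0
s_unfolded = 3.0
ph_min = 3.0
ph_max = 6.0
n_points = 20
noise_fraction = 0.01
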
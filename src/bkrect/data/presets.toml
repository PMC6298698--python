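[mSlo1]
R_alpha = 1.12
R_eq_full = 1.12
p_bind = 0.0
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[WT-beta2]
R_alpha = 1.12
R_eq_full = 1.85
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C1S]
R_alpha = 1.12
R_eq_full = 1.38
p_bind = 0.52
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C2S]
R_alpha = 1.12
R_eq_full = 1.43
p_bind = 0.91
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C3S]
R_alpha = 1.12
R_eq_full = 1.47
p_bind = 0.91
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C4S]
R_alpha = 1.12
R_eq_full = 1.62
p_bind = 0.92
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C5S]
R_alpha = 1.12
R_eq_full = 1.4
p_bind = 0.34
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C6S]
R_alpha = 1.12
R_eq_full = 1.43
p_bind = 0.59
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C7S]
R_alpha = 1.12
R_eq_full = 1.45
p_bind = 0.92
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[C8S]
R_alpha = 1.12
R_eq_full = 1.45
p_bind = 0.62
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["C1S/C5S"]
R_alpha = 1.12
R_eq_full = 1.36
p_bind = 0.45
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["C3S/C7S"]
R_alpha = 1.12
R_eq_full = 1.49
p_bind = 0.9
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["C6S/C8S"]
R_alpha = 1.12
R_eq_full = 1.47
p_bind = 0.55
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["C1S/C4S"]
R_alpha = 1.12
R_eq_full = 1.5
p_bind = 0.6
tau_act = 2.0
tau_inact = 25.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[S173K]
R_alpha = 1.12
R_eq_full = 2.13
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[S173D]
R_alpha = 1.12
R_eq_full = 1.69
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["S173K/K141A"]
R_alpha = 1.12
R_eq_full = 1.83
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["S173K/K141D"]
R_alpha = 1.12
R_eq_full = 1.65
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[Q83K]
R_alpha = 1.12
R_eq_full = 1.88
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[L114K]
R_alpha = 1.12
R_eq_full = 1.85
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[S100K]
R_alpha = 1.12
R_eq_full = 2.13
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[S100D]
R_alpha = 1.12
R_eq_full = 1.68
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["S100K/K147D"]
R_alpha = 1.12
R_eq_full = 1.69
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

["S100K/K147A"]
R_alpha = 1.12
R_eq_full = 1.85
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[N96K]
R_alpha = 1.12
R_eq_full = 2.45
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02

[D104A]
R_alpha = 1.12
R_eq_full = 1.71
p_bind = 0.93
tau_act = 2.0
tau_inact = 20.0
V50 = -15.0
kappa = -12.0
g_max = 10.0
noise_sd = 0.02
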
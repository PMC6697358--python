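[network]
units = pre-I, early-I, post-I, aug-E
include_pico = False

[shared]
C = 20.0
E_Na = 50.0
E_K = -85.0
E_synE = 0.0
E_synI = -75.0
theta_h = -48.0
sigma_h = 8.0
theta_m = -37.0
sigma_m = -6.0
theta_n = -29.0
sigma_n = -4.0
epsilon = 4000.0
g_synE = 10.0
g_synI = 60.0

[unit.pre-I]
excitatory = True
g_NaP = 4.5
g_K = 1.0
g_L = 3.0
E_L = -65.0
theta_out = -32.0
sigma_out = -8.0
h_mode = quasi-steady

[unit.early-I]
excitatory = False
g_NaP = 0.25
g_K = 10.0
g_L = 3.25
E_L = -60.0
theta_out = -30.0
sigma_out = -4.0
tau_p = 2000.0
d_adapt = 1.0
h_mode = quasi-steady

[unit.post-I]
excitatory = False
g_NaP = 0.25
g_K = 10.0
g_L = 3.25
E_L = -60.0
theta_out = -30.0
sigma_out = -4.0
tau_p = 1500.0
d_adapt = 1.0
h_mode = quasi-steady

[unit.aug-E]
excitatory = False
g_NaP = 0.25
g_K = 10.0
g_L = 3.25
E_L = -60.0
theta_out = -30.0
sigma_out = -4.0
tau_p = 2000.0
d_adapt = 1.0
h_mode = quasi-steady

[excitatory_weights]
a_1_2 = 0.6

[inhibitory_weights]
b_2_3 = 0.6
b_2_4 = 0.3
b_3_1 = 0.125
b_3_2 = 0.27
b_3_4 = 0.45
b_4_1 = 0.015
b_4_2 = 0.3
b_4_3 = 0.05

[drives]
c1_1 = -0.03
c1_2 = 0.19
c1_3 = 0.58
c1_4 = 0.2
c2_1 = 0.095
c2_2 = 0.3
c2_3 = 0.0
c2_4 = 0.4

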
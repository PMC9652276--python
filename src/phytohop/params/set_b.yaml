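# Packaged model parameters, ensemble variant set-B: identical to set-A
# except for a weak H-bond well depth D_hb, so the His290 interaction is
# only marginally featured.
E_vert: 40.8
V6_S1: 11.1
V6_S0: 70.5
V5: 6.0
chi: 2.5
theta6_CI: 98.0
w0: 2.8
sigma_w: 7.5
D_hb: 2.0
a_hb: 2.0
r0_hb: 2.9
lambda_hb: 1.4893122649286066
s6: 1.0
v_asym: 28.0
I_theta6: 12.0
I_theta5: 12.0
m_r: 10.0
gamma: 4.0
T: 300.0
T_excited: 700.0
r_wall: 6.0
k_wall: 2.0
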
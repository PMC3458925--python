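residue	mean_ap	sd_ap	mean_np	sd_np
S	0.053	0.015	0.051	0.016
Q	0.030	0.012	0.036	0.016
N	0.025	0.011	0.029	0.015
T	0.056	0.015	0.046	0.014
C	0.010	0.009	0.010	0.010
G	0.086	0.021	0.083	0.022
A	0.114	0.030	0.106	0.037
H	0.022	0.011	0.024	0.012
M	0.026	0.011	0.025	0.011
Y	0.019	0.011	0.027	0.014
F	0.032	0.012	0.032	0.014
V	0.077	0.019	0.076	0.020
L	0.096	0.023	0.098	0.027
P	0.051	0.016	0.048	0.016
I	0.052	0.016	0.059	0.023
W	0.010	0.008	0.011	0.010
D	0.059	0.015	0.056	0.015
E	0.065	0.019	0.066	0.020
K	0.040	0.022	0.043	0.029
R	0.074	0.024	0.073	0.024
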
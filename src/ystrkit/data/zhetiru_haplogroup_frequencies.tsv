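haplogroup	Zhetiru	Kerderi	Kereit	Ramadan	Tabyn	Tama	Teleu	Zhagalbaily
C2a1a1b1-F1756	0.071	0.000	0.031	0.026	0.259	0.000	0.000	0.015
C2a1a2-M48	0.103	0.075	0.125	0.026	0.259	0.111	0.019	0.015
C2a1a3-F1918	0.100	0.025	0.063	0.026	0.071	0.639	0.000	0.031
C2b-F1067	0.009	0.025	0.000	0.000	0.000	0.000	0.000	0.031
D1-M174	0.003	0.000	0.000	0.000	0.000	0.000	0.000	0.015
E1b1b1b2a1-M123	0.011	0.000	0.000	0.000	0.000	0.111	0.000	0.000
G1-M285	0.014	0.000	0.000	0.026	0.012	0.028	0.000	0.031
I2a-M438	0.017	0.000	0.000	0.000	0.000	0.000	0.000	0.092
J2a1-CTS7683	0.063	0.300	0.188	0.000	0.024	0.028	0.000	0.015
J2a2-PF5050	0.131	0.000	0.000	0.000	0.000	0.000	0.830	0.031
N1a1a-M178	0.017	0.000	0.000	0.000	0.000	0.000	0.075	0.031
N1a2-CTS6380	0.100	0.000	0.594	0.000	0.176	0.000	0.000	0.015
O2-M122	0.077	0.000	0.000	0.205	0.000	0.028	0.000	0.277
Q1b-M346	0.026	0.000	0.000	0.231	0.000	0.000	0.000	0.000
R1a1a-M198	0.143	0.550	0.000	0.308	0.141	0.028	0.019	0.031
R1b1a1a1-M478	0.080	0.025	0.000	0.026	0.012	0.000	0.038	0.354
R1b1a1b-M269	0.034	0.000	0.000	0.128	0.047	0.028	0.019	0.015
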
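	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	0.2303	0.5699	0.6072	0.5627	0.1114	0.4939	0.3498	0.6936	0.3257	0.4093	0.4137	0.2143	0.4919	0.944	0.2143	0.2434	0.2352	0.8284	0.6474
C	0.2303	0	0.5	0.5085	0.3825	0.3273	0.2786	0.2496	0.5913	0.1923	0.2028	0.2656	0.1175	0.3155	0.8069	0.2004	0.096	0.1735	0.6197	0.4237
D	0.5699	0.5	0	0.099	0.7602	0.5777	0.4178	0.6966	0.155	0.6539	0.5693	0.3009	0.4003	0.3122	0.4375	0.3748	0.4146	0.6404	0.9044	0.694
E	0.6072	0.5085	0.099	0	0.7207	0.6301	0.3859	0.683	0.1567	0.6428	0.5413	0.3161	0.4211	0.3007	0.4136	0.4188	0.4331	0.6426	0.8462	0.6449
F	0.5627	0.3825	0.7602	0.7207	0	0.6733	0.3961	0.242	0.8177	0.2403	0.2019	0.5449	0.4766	0.5258	0.9692	0.5743	0.4583	0.3383	0.2882	0.2205
G	0.1114	0.3273	0.5777	0.6301	0.6733	0	0.5724	0.4594	0.7074	0.437	0.5139	0.4609	0.2834	0.5476	0.966	0.2441	0.3161	0.3458	0.9367	0.75
H	0.4939	0.2786	0.4178	0.3859	0.3961	0.5724	0	0.4264	0.4421	0.3712	0.2356	0.1933	0.2925	0.1366	0.591	0.3537	0.2573	0.415	0.511	0.2889
I	0.3498	0.2496	0.6966	0.683	0.242	0.4594	0.4264	0	0.7925	0.066	0.2014	0.4942	0.3386	0.5169	1	0.429	0.3403	0.1165	0.5294	0.4091
K	0.6936	0.5913	0.155	0.1567	0.8177	0.7074	0.4421	0.7925	0	0.7443	0.6378	0.3491	0.5074	0.3284	0.2828	0.4859	0.5067	0.745	0.917	0.7107
L	0.3257	0.1923	0.6539	0.6428	0.2403	0.437	0.3712	0.066	0.7443	0	0.1574	0.4357	0.291	0.4593	0.9476	0.3821	0.285	0.0988	0.5187	0.3759
M	0.4093	0.2028	0.5693	0.5413	0.2019	0.5139	0.2356	0.2014	0.6378	0.1574	0	0.3526	0.2816	0.3472	0.818	0.3795	0.2637	0.2329	0.4317	0.2513
N	0.4137	0.2656	0.3009	0.3161	0.5449	0.4609	0.1933	0.4942	0.3491	0.4357	0.3526	0	0.2151	0.0945	0.5498	0.2187	0.1852	0.4361	0.6976	0.4737
P	0.2143	0.1175	0.4003	0.4211	0.4766	0.2834	0.2925	0.3386	0.5074	0.291	0.2816	0.2151	0	0.2837	0.746	0.1012	0.0588	0.255	0.7051	0.4994
Q	0.4919	0.3155	0.3122	0.3007	0.5258	0.5476	0.1366	0.5169	0.3284	0.4593	0.3472	0.0945	0.2837	0	0.4972	0.3066	0.2525	0.4784	0.6445	0.4225
R	0.944	0.8069	0.4375	0.4136	0.9692	0.966	0.591	1	0.2828	0.9476	0.818	0.5498	0.746	0.4972	0	0.7323	0.7304	0.9673	0.9905	0.809
S	0.2143	0.2004	0.3748	0.4188	0.5743	0.2441	0.3537	0.429	0.4859	0.3821	0.3795	0.2187	0.1012	0.3066	0.7323	0	0.1227	0.3332	0.7966	0.5854
T	0.2434	0.096	0.4146	0.4331	0.4583	0.3161	0.2573	0.3403	0.5067	0.285	0.2637	0.1852	0.0588	0.2525	0.7304	0.1227	0	0.2614	0.6753	0.4653
V	0.2352	0.1735	0.6404	0.6426	0.3383	0.3458	0.415	0.1165	0.745	0.0988	0.2329	0.4361	0.255	0.4784	0.9673	0.3332	0.2614	0	0.6174	0.467
W	0.8284	0.6197	0.9044	0.8462	0.2882	0.9367	0.511	0.5294	0.917	0.5187	0.4317	0.6976	0.7051	0.6445	0.9905	0.7966	0.6753	0.6174	0	0.2242
Y	0.6474	0.4237	0.694	0.6449	0.2205	0.75	0.2889	0.4091	0.7107	0.3759	0.2513	0.4737	0.4994	0.4225	0.809	0.5854	0.4653	0.467	0.2242	0
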
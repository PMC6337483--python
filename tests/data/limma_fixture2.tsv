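	s1	s2	s3	s4	s5	s6	s7	s8
g01	2.110573	2.063845	0.773738	2.076215	1.360161	-1.548668	0.860229	0.119472
g02	1.185349	4.540477	2.96805	0.476934	0.094634	0.732381	-0.239748	0.867278
g03	1.946582	2.535848	3.155238	1.457394	0.163135	-0.37207	0.102206	-0.953403
g04	1.715893	1.90378	2.44078	2.561651	-0.649097	-0.389716	0.317261	-0.977142
g05	1.678063	1.932378	2.873719	2.479187	-0.227438	-0.256188	-0.173904	1.058966
g06	1.806386	1.862633	2.159491	1.94537	-0.08924	-0.503939	-0.005212	-0.20065
g07	1.223608	0.68528	-0.025334	0.701326	-0.356622	1.103987	-0.005666	0.612138
g08	-3.771628	1.012902	-4.932458	-5.94666	-0.889596	-2.629336	0.479316	6.558548
g09	-0.561008	-0.420858	0.138548	0.332544	-0.118988	-0.138903	0.47382	0.350684
g10	-0.62923	-0.0482	0.02148	-0.641897	0.158172	-0.522264	0.591726	0.11733
g11	0.132151	-0.874575	-0.175513	-2.956167	-1.674201	0.536912	-3.149749	1.25277
g12	-2.323076	1.006795	-1.124883	1.036401	0.174223	-2.044666	1.661917	1.918105
g13	-0.071595	-0.298018	-0.173934	-1.060955	1.195251	-0.590661	-0.055695	-0.863098
g14	-0.297404	-0.60696	0.597147	-0.073196	0.458843	0.00633	-0.329863	-0.155186
g15	-0.547273	0.007775	-0.366587	-0.292985	-1.346689	-0.788184	1.6158	-0.655708
g16	-1.838452	0.588333	2.454433	-2.535974	-0.363684	-1.102367	-3.071406	1.281791
g17	-0.007998	0.024374	-0.256667	0.155159	-0.183993	-0.048754	-0.378106	-0.414899
g18	0.926109	-0.351646	0.202262	-0.023432	-0.305907	-0.35224	0.436924	-0.209327
g19	-0.03309	0.004855	0.257065	0.14869	0.083597	-0.123139	-0.301957	0.20747
g20	0.344466	-0.050152	0.193141	0.278526	0.296255	0.328405	-0.162394	0.539975
g21	-0.285654	0.197462	0.113183	0.200188	0.430571	0.340157	-0.262415	-0.386955
g22	0.676837	-0.840993	-0.010279	0.69576	-1.361975	-1.748233	0.214843	0.036776
g23	-0.089173	0.01398	-0.312178	-0.549066	-0.060459	-0.352517	-0.596223	0.183451
g24	-0.076279	0.505054	-1.229059	-0.817545	-1.241169	-1.101527	0.242767	-0.972735
g25	0.403638	0.385148	2.295728	-1.57887	1.006529	-0.101444	-0.015904	-1.64357
g26	-0.396273	0.639967	-0.071022	0.069796	-0.250336	0.9942	-0.01849	-1.894778
g27	-0.092414	-0.262899	-0.434174	-0.070788	0.178074	0.006292	-0.156573	-0.125614
g28	0.734773	0.10244	0.031194	-0.034744	0.024956	0.523424	0.359107	0.140184
g29	-1.003179	0.491657	-0.658206	1.052216	-1.222678	-0.132383	-0.007078	-1.274233
g30	1.885357	1.598974	-0.50757	0.844944	0.414606	-2.861541	0.274156	-0.067165
g31	0.024468	-0.316622	-0.079193	-0.052412	0.349323	0.098328	-0.001633	0.449547
g32	-0.378877	-0.26573	-1.239675	1.07069	0.658019	0.625617	0.456427	0.075161
g33	0.098504	-0.115197	-0.093069	0.024823	0.691083	0.254015	-0.026723	-0.26485
g34	-0.332471	0.839141	0.26529	0.035368	-0.181253	-0.580676	-0.035007	0.457428
g35	-0.917223	-0.530987	-0.51648	0.256084	-3.722311	-0.550044	-1.996425	2.066967
g36	-0.403889	0.302444	0.798994	-0.164363	-0.3153	0.100334	-0.001063	-0.520778
g37	0.449082	1.963754	-0.251483	-0.197666	-1.018096	0.310894	-1.214952	-1.078503
g38	2.596364	-1.837107	2.194006	3.092826	0.526157	1.122796	3.960994	-0.399149
g39	-0.371788	-0.848415	0.026148	0.927357	0.601623	-0.590649	-0.536282	-0.316093
g40	0.267284	-0.18776	0.196121	0.271373	-0.273233	-0.03674	0.188932	-0.076792
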
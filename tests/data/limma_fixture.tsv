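	s1	s2	s3	s4	s5	s6	s7	s8	s9
g01	1.804717	0.460016	2.250451	2.440565	-0.451035	-1.30218	0.12784	-0.316243	-0.016801
g02	0.646956	2.379398	2.277792	1.566031	2.627241	0.467509	-0.859292	0.368751	-0.958883
g03	2.37845	1.450074	1.315138	0.81907	2.722541	-0.154529	-0.428328	-0.352134	0.532309
g04	1.865444	1.912733	1.930821	3.641648	1.093585	-0.512243	-0.813773	0.615979	1.128972
g05	1.386053	0.659844	0.675519	2.150593	2.243254	0.543154	-0.66551	0.232161	0.116686
g06	0.218689	0.871429	0.223596	0.678914	0.067579	0.289119	0.631288	-1.457156	-0.319671
g07	-0.470373	-0.638878	-0.275142	1.494941	-0.865831	0.968278	-1.68287	-0.334885	0.162753
g08	0.586222	0.711227	0.793347	-0.348725	-0.462352	0.857976	-0.191304	-1.275686	-1.133287
g09	-0.919452	0.497161	0.142426	0.690485	-0.427253	0.15854	0.62559	-0.309347	0.456775
g10	-0.661926	-0.363054	-0.381738	-1.19584	0.486972	-0.469402	0.012494	0.480747	0.446531
g11	0.665385	-0.098485	-0.423298	-0.079718	-1.687334	-1.447112	-1.3227	-0.997247	0.399774
g12	-0.905479	-0.378163	1.299228	-0.356264	0.737516	-0.933618	-0.205438	-0.950022	-0.339033
g13	0.840308	-1.72732	0.434424	0.237736	-0.59415	-1.446058	0.07213	-0.529493	0.232676
g14	0.021852	1.601779	-0.239356	-1.023497	0.179276	0.219997	1.359188	0.835111	0.356871
g15	1.463303	-1.188763	-0.639752	-0.926576	-0.38981	-1.376686	0.635151	-0.222223	-1.470806
g16	-1.015579	0.313514	0.838127	1.996731	2.913862	0.414409	-0.989538	-2.132046	0.267711
g17	-0.812941	-0.415357	-0.612097	-0.140791	1.06598	0.157049	-0.158635	-1.035654	-1.674683
g18	-0.486308	-0.053783	1.76793	0.130275	0.98274	-0.499296	-1.184944	-0.965117	-0.725226
g19	2.12847	-0.821387	0.838489	-0.902927	0.931573	0.384951	-0.156638	-0.040763	-0.654788
g20	0.446072	-0.454983	-1.225606	-1.277938	0.172588	1.579091	0.159992	-0.118638	0.285826
g21	1.306002	0.219383	-0.410927	1.106289	0.428756	1.535756	0.183234	-1.224469	-1.368159
g22	1.650928	1.723666	-0.179519	-0.383187	1.461444	-1.107046	-0.894727	0.643327	-0.394605
g23	-0.005122	-0.163443	0.337575	1.407482	0.090585	0.643939	-2.050172	-0.048718	-0.84323
g24	-1.218813	-0.878152	-0.334123	0.915903	-1.326393	0.030631	-0.484169	-0.327673	1.002758
g25	0.538115	1.337398	-0.154506	-0.695943	-0.223859	0.242497	0.176573	-1.084388	0.09049
g26	0.228228	2.517474	1.876845	-0.853243	-0.287383	-1.463442	-0.590707	0.315605	1.205854
g27	-0.729084	-0.654146	-2.147289	-0.162666	-1.062414	-0.529439	-0.876861	-0.094263	-1.757728
g28	-1.467045	2.129247	-1.287423	-1.096786	1.836914	2.905067	-1.171567	-0.368249	0.341556
g29	1.728698	-0.986857	-0.245278	0.777338	0.434766	-0.376156	-0.133823	-1.374896	-0.238174
g30	-0.266387	0.23217	-0.555327	0.471539	1.012716	0.155429	0.351756	0.053155	8.4e-05
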
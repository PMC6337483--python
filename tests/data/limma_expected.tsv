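gene	logFC	t	p
g01	 1.67778880	 2.738832385301	0.00669560708173
g02	 2.14496235	 3.501449258352	0.00056514741482
g03	 1.83772510	 2.999913349737	0.00302703542439
g04	 1.98411245	 3.238876927858	0.00139493939443
g05	 1.36642985	 2.230568189168	0.02676761856020
g06	 0.62614640	 1.022125095995	0.30789771869209
g07	 0.07062440	 0.115287689316	0.90832725718165
g08	 0.69151905	 1.128839797472	0.26025331296736
g09	-0.23621610	-0.385600562246	0.70018283617076
g10	-0.54070970	-0.882657720332	0.37843048903730
g11	 0.51713125	 0.844168118747	0.39953608765519
g12	 0.68639535	 1.120475839212	0.26379080360887
g13	 0.25588585	 0.417709578774	0.67658623734065
g14	-0.58478095	-0.954599890145	0.34087761984858
g15	 0.27232140	 0.444539068046	0.65711068347249
g16	 1.61919700	 2.643186783570	0.00883225045982
g17	 0.49493955	 0.807942256085	0.42003807807361
g18	 1.31181655	 2.141417114427	0.03339237027817
g19	 0.55165310	 0.900521791379	0.36887417426232
g20	-0.94454115	-1.541874573766	0.12460959145860
g21	 0.74831010	 1.221545844225	0.22324894669223
g22	 1.29292915	 2.110585210677	0.03599128335522
g23	 0.90796065	 1.482160348668	0.13979666460481
g24	-0.62370235	-1.018135414283	0.30978513746045
g25	 0.30394800	 0.496166517411	0.62029584157813
g26	 0.82955670	 1.354173275804	0.17713648257742
g27	-0.13654705	-0.222900214054	0.82382982621678
g28	-0.40372035	-0.659035493135	0.51059496245213
g29	 0.87249565	 1.424267072384	0.15585344089563
g30	 0.03883620	 0.063396443153	0.94951112183810
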
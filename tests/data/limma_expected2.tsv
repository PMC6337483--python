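gene	logFC	t	p
g01	 1.55829425	 2.396603048175	4.46715078452e-02
g02	 1.92906625	 2.257012048072	5.53356883270e-02
g03	 2.53879850	 5.967552382373	3.93871424821e-04
g04	 2.58019950	 7.607381072194	7.79769930132e-05
g05	 2.14047775	 5.353917452320	7.83276536213e-04
g06	 2.14323025	11.120341857222	5.28139814223e-06
g07	 0.30776075	 0.777196496286	4.60323577552e-01
g08	-4.28919400	-1.919395997920	9.27464661685e-02
g09	-0.26934675	-0.958285699425	3.67127020301e-01
g10	-0.41070275	-1.371164456338	2.09071309092e-01
g11	-0.20995900	-0.191586822736	8.53036899762e-01
g12	-0.77858550	-0.708573146529	4.99540644761e-01
g13	-0.32257475	-0.679174804666	5.16980324053e-01
g14	-0.09013425	-0.290124159929	7.79404678641e-01
g15	-0.00607225	-0.010011922220	9.92267100389e-01
g16	 0.48100150	 0.370529879418	7.21004200299e-01
g17	 0.23515500	 1.262330299473	2.43833517989e-01
g18	 0.29596075	 0.904754757318	3.93108836674e-01
g19	 0.12788725	 0.668867677275	5.23183883229e-01
g20	-0.05906500	-0.275138620079	7.90470838367e-01
g21	 0.02595525	 0.100082025416	9.22843831101e-01
g22	 0.84497850	 1.502765992902	1.72878311125e-01
g23	-0.02767225	-0.114920188007	9.11457743516e-01
g24	 0.36370875	 0.757391729964	4.71424905558e-01
g25	 0.56500825	 0.654312073790	5.32022492578e-01
g26	 0.35296800	 0.605446125611	5.62352541150e-01
g27	-0.19061350	-1.044304300570	3.28116857403e-01
g28	-0.05350200	-0.223045311453	8.29321389566e-01
g29	 0.62971500	 1.158006979999	2.81623098437e-01
g30	 1.51541225	 1.792381556949	1.12419588617e-01
g31	-0.32983100	-1.736403135024	1.22295573451e-01
g32	-0.65720400	-1.416986169887	1.95774296635e-01
g33	-0.18461600	-0.765741943450	4.66722703213e-01
g34	 0.28670900	 0.879662196522	4.05741098355e-01
g35	 0.62330175	 0.559015352308	5.92082799820e-01
g36	 0.31749825	 1.033210347467	3.32959956027e-01
g37	 1.24108600	 2.158792184092	6.43326599201e-02
g38	 0.20882275	 0.159504181289	8.77388907416e-01
g39	 0.14367575	 0.326202998961	7.52986815449e-01
g40	 0.18621275	 0.936108495433	3.77731385479e-01
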
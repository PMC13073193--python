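rsid	risk_allele	beta	chromosome	position	genes
rs9275490	G	2.08	6	32673385	
rs540653847	I	1.78	6	31274794	LOC112267902
rs9271346	T	1.69	6	32583468	
rs17843689	T	1.39	6	32622047	HLA-DQA1
rs9273369	C	1.26	6	32626484	HLA-DQB1-AS1
rs116522341	C	1.24	6	32367697	BTNL2, TSBP1-AS1
rs1281934	G	0.9	6	32584382	
rs2567287	A	0.84	6	33049185	HLA-DPA1, HLA-DPB1
rs3842753	G	0.83	11	2181060	INS, INS-IGF2
rs75658393	T	0.81	6	32395517	
rs72848653	T	0.78	6	29836602	
rs144530872	A	0.74	6	29863887	
rs9269173	A	0.67	6	32447188	
rs2476601	A	0.64	1	114377568	PTPN22, AP4B1-AS1
rs9500974	T	0.63	6	29728253	
rs17211699	T	0.48	6	32626037	HLA-DQB1-AS1
rs12189871	T	0.45	6	31251924	
rs12153924	A	0.44	6	29914089	HLA-A, LOC124901298
rs371250843	D	0.39	6	31324737	HLA-B, MIR6891
rs9259118	T	0.31	6	29850909	
rs2289702	C	0.28	15	79237293	CTSH
rs4948088	C	0.26	7	51027194	
rs653178	C	0.26	12	112007756	ATXN2
rs559242105	I	0.24	6	33071028	
rs4759229	A	0.22	12	56474480	ERBB3
rs9924471	A	0.22	16	28591530	SGF29
rs1893217	G	0.19	18	12809340	PTPN2
rs72928038	A	0.18	6	90976768	BACH2
rs60888743	A	0.18	10	90051317	RNLS, LOC101929727
rs11170466	T	0.17	12	53585859	ITGB7, ZNF740
rs9981624	C	0.17	21	43825722	UBASH3A
rs9388489	A	0.16	6	126698719	CENPW
rs425105	T	0.15	19	47208481	PRKD2
rs5763779	A	0.15	22	30504652	HORMAD2
rs72727394	T	0.14	15	38847022	RASGRP1
rs17388568	A	0.12	4	123329362	ADAD1
rs1615504	T	0.12	18	67526644	CD226
rs6476839	T	0.11	9	4290823	GLIS3
rs9585056	C	0.11	13	100081766	
rs2281808	C	0.1	20	1610551	SIRPG
rs229541	A	0.1	22	37591318	C1QTNF6
rs9469200	C	-0.03	6	32603212	HLA-DQA1, LOC124901301
rs1738074	T	-0.08	6	159465977	TAGAP, TAGAP-AS1
rs56994090	C	-0.13	14	101306447	MEG3
rs10492166	A	-0.14	12	9885999	CLECL1
rs3024505	A	-0.15	1	206939904	
rs2111485	A	-0.16	2	163110536	LOC105373724
rs3087243	A	-0.17	2	204738919	CTLA4
rs17214657	C	-0.19	6	33047173	HLA-DPA1, HLA-DPB1
rs12708716	G	-0.19	16	11179873	CLEC16A
rs144309607	T	-0.4	19	10492274	TYK2
rs10947332	A	-0.46	6	32677440	
rs61839660	T	-0.48	10	6094697	IL2RA
rs9378176	G	-0.49	6	33049309	HLA-DPA1, HLA-DPB1
rs2524277	A	-0.6	6	31407579	LINC01149
rs1281935	T	-0.63	6	32583820	
rs62406889	T	-0.65	6	32672214	
rs6934289	C	-0.68	6	33044956	HLA-DPA1, HLA-DPB1
rs41295121	T	-0.71	10	6129643	RBM17
rs28746898	G	-0.76	6	32648594	
rs16899379	A	-0.83	6	31343267	
rs12527228	T	-0.89	6	32679992	
rs149663102	D	-0.94	6	31344183	
rs1794265	G	-1.31	6	32674737	
rs9405117	A	-1.43	6	32602751	LOC124901301
rs16822632	A	-2.21	6	32411712	HLA-DRA
rs117806464	A	-2.41	6	32626447	HLA-DQB1-AS1
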
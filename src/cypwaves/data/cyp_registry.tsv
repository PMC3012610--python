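name	family	subfamily	chromosome	tx_start	tx_end	strand	exon_count	flags
CYP5A1	5	5A	18	12577084	12755668	1	13	on_array
CYP7A1	7	7A	2	20390259	20392545	-1	6	on_array
CYP7C1	7	7C	2	41226478	41238852	1	5	on_array
CYP7D1	7	7D	7	60786672	60803272	-1	6	on_array
CYP8A1	8	8A	6	50097042	50118485	-1	10	on_array
CYP8B1	8	8B	2	2631931	2633902	-1	1	on_array
CYP8B2	8	8B	2	2598906	26000260	-1	1	pseudogene,on_array
CYP8B3	8	8B	2	2583060	2584972	-1	1	pseudogene,on_array
CYP11A1	11	11A	25	23348335	23363675	1	11	on_array
CYP11A2	11	11A	25	23325076	23339692	1	9	on_array
CYP11C1	11	11C	16	51516891	51525686	1	10	on_array
CYP17A1	17	17A	13	33337340	33347115	1	8	on_array
CYP17A2	17	17A	23	44130651	44138933	1	9	on_array
CYP19A1	19	19A	18	39131244	39146992	-1	9	on_array
CYP19A2	19	19A	25	3756544	3767668	1	10	on_array
CYP20A1	20	20A	5	61726392	61743655	-1	15	on_array
CYP21A1	21	21A	16	15091143	15104788	-1	12	on_array
CYP24A1	24	24A	Zv8_NA3215	47572	49579	-1	12	on_array
CYP26A1	26	26A	12	9329895	9333488	-1	7	on_array
CYP26B1	26	26B	7	25393384	25417689	1	6	on_array
CYP26C1	26	26C	17	17123846	17136305	1	7	on_array
CYP27A3	27	27A	9	22363398	22377078	1	10	on_array
CYP27A4	27	27A	9	39232071	39242971	1	9	on_array
CYP27A5	27	27A	9	39213139	39219475	1	9	on_array
CYP27A6	27	27A	9	39205591	39211049	1	9	on_array
CYP27A7	27	27A	9	39194558	39204706	1	9	on_array
CYP27B1	27	27B	11	460256	466291	-1	11	on_array
CYP27C1	27	27C	6	10507141	10520886	-1	9	on_array
CYP39A1	39	39A	20	39084490	39112294	-1	12	on_array
CYP46A1	46	46A	20	4947206	4961574	1	15	on_array
CYP46A2	46	46A	5	73217357	73226060	-1	15	on_array
CYP46A4	46	46A	5	73235710	73241459	-1	15	on_array
CYP46A5	46	46A						missing_from_assembly
CYP51A1	51	51A	19	486980	505501	1	10	on_array
CYP1A	1	1A	18	3972990	3983879	-1	7	on_array
CYP1B1	1	1B	13	42451108	42458759	-1	2	on_array
CYP1C1	1	1C	Zv8_scaf3050	158017	161082	1	1	on_array
CYP1C2	1	1C	Zv8_scaf3050	152452	154638	1	1	on_array
CYP1D1	1	1D	5	23578519	23593172	-1	7	on_array
CYP2AA1	2	2AA	23	39112545	39130047	1	9	on_array
CYP2AA2	2	2AA	23	39132514	39145108	1	9	on_array
CYP2AA3	2	2AA	23	39160334	39172075	1	9	on_array
CYP2AA4	2	2AA	23	39040573	39050888	1	9	on_array
CYP2AA6	2	2AA	23	38994308	39009052	1	9	
CYP2AA7	2	2AA	23	39014695	39036855	1	9	on_array
CYP2AA8	2	2AA	23	39075131	39083899	1	9	on_array
CYP2AA9	2	2AA	23	39092849	39106493	1	9	on_array
CYP2AA11	2	2AA	23	39025380	39036455	1	9	on_array
CYP2AA12	2	2AA	23	38971320	38984900	1	9	on_array
CYP2AA13	2	2AA						missing_from_assembly
CYP2AD2	2	2AD	20	25174055	25181567	-1	9	on_array
CYP2AD3	2	2AD	20	25187810	25191060	-1	9	on_array
CYP2AD6	2	2AD	20	25165262	25173123	-1	9	on_array
CYP2AE1	2	2AE	23	39385086	39398666	1	10	on_array
CYP2AE2	2	2AE	23	39438355	39465937	1	10	on_array
CYP2K6	2	2K	3	8561027	8571051	-1	10	on_array
CYP2K7	2	2K	3	6855362	6872308	-1	10	on_array
CYP2K8	2	2K	3	8585106	8602953	-1	9	on_array
CYP2K16	2	2K	3	8606661	8622465	-1	9	on_array
CYP2K17	2	2K	3	8624449	8631739	-1	9	on_array
CYP2K18	2	2K	3	8671991	8677064	-1	9	on_array
CYP2K19	2	2K	3	8647105	8654962	-1	9	on_array
CYP2K20	2	2K	3	8657079	8669242	-1	9	on_array
CYP2K21	2	2K	3	8638383	8643321	-1	9	on_array
CYP2K22	2	2K	3	6809065	6872358	-1	9	on_array
CYP2K31	2	2K	3	6887113	6898613	-1	9	on_array
CYP2N13	2	2N	20	25154644	25162165	-1	9	on_array
CYP2P6	2	2P	20	25202489	25207822	1	9	on_array
CYP2P7	2	2P	20	25208167	25213192	1	9	on_array
CYP2P8	2	2P	20	25214780	25219066	1	9	
CYP2P9	2	2P	20	25221011	25224248	1	9	on_array
CYP2P10	2	2P	20	25225641	25232985	1	9	on_array
CYP2P14	2	2P	20	25250397	25255115	1	8	on_array
CYP2R1	2	2R	7	27793618	27799151	1	5	on_array
CYP2U1	2	2U	1	49893260	49901816	-1	6	on_array
CYP2V1	2	2V	20	25191510	25197554	1	9	on_array
CYP2X6	2	2X	25	13917523	13924246	1	9	
CYP2X7	2	2X	25	13906315	13912802	1	9	on_array
CYP2X8	2	2X	25	13889786	13898258	1	9	on_array
CYP2X9	2	2X	25	13881532	13888365	1	9	
CYP2X10c1	2	2X	7	52828535	52831744	-1	9	assembly_duplicate,on_array
CYP2X10c2	2	2X	7	52971112	52974318	-1	9	assembly_duplicate,on_array
CYP2X11	2	2X	7	53000061	53012216	1	9	on_array
CYP2X12c1	2	2X	7	53013611	53022923	1	9	assembly_duplicate,on_array
CYP2X12c2	2	2X	7	54082352	54244690	-1	10	assembly_duplicate,on_array
CYP2Y3	2	2Y	15	59576	64111	-1	9	on_array
CYP2Y4	2	2Y	15	70518	76649	-1	9	on_array
CYP3A65	3	3A	1	59169705	59179378	-1	13	on_array
CYP3C1	3	3C	3	38092409	38099696	-1	13	on_array
CYP3C2	3	3C	3	38082058	38088687	-1	13	on_array
CYP3C3	3	3C	3	38071126	38078946	-1	13	on_array
CYP3C4	3	3C	3	38059261	38068888	-1	13	on_array
CYP4F43	4	4F	12	46414253	46432708	1	12	on_array
CYP4T8	4	4T	16	3042131	3063539	-1	12	on_array
CYP4V7	4	4V	Zv8_NA9570	11333	19450	1	11	on_array
CYP4V8	4	4V	1	17310768	17323080	1	11	on_array
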